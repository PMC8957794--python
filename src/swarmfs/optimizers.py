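"""Population-based binary feature-subset search.

Four swarm optimizers share one framework: agents live in the continuous
box [0, 1]^d, every position is thresholded into a binary feature mask
(strictly greater than 0.5 selects a feature), the mask is scored by the
cross-validated fitness, and the best mask ever seen is retained outside
the population (elitism), which makes the best-so-far trace monotone
non-increasing by construction.

Update rules follow the algorithms' original publications:

* SMA  — slime mould: ranked-fitness weights, oscillation coefficients
  ``vb`` in [-a, a] with a = arctanh(1 - t/T) and ``vc`` in [-b, b] with
  b shrinking linearly to 0, plus a small random-restart probability ``z``.
* PFA  — pathfinder: the best agent moves by momentum plus a decaying
  perturbation; followers are attracted to a random companion and to the
  pathfinder with coefficients drawn from [1, 2], plus a distance-scaled
  perturbation decaying as (1 - t/T).
* HGSO — Henry gas solubility: agents grouped into gas clusters whose
  Henry coefficients decay on an exponential temperature schedule;
  solubility scales attraction to the global best, a fitness-ratio factor
  scales attraction to the cluster best; a random fraction of the worst
  agents is reinitialised each iteration.
* PSO  — canonical particle swarm with linearly decaying inertia
  (0.9 -> 0.4), cognitive/social coefficients of 2 and a velocity clamp.

Additional update rules can be plugged in through :func:`register_algorithm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .classify_eval import FitnessConfig, FitnessEvaluator
from .data_io import FeatureMatrix, ValidationError


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SMAParams:
    z: float = 0.03           # random-restart probability


@dataclass(frozen=True)
class PFAParams:
    alpha_range: tuple[float, float] = (1.0, 2.0)   # companion attraction
    beta_range: tuple[float, float] = (1.0, 2.0)    # pathfinder attraction
    u_range: tuple[float, float] = (-1.0, 1.0)      # perturbation draws


@dataclass(frozen=True)
class HGSOParams:
    n_clusters: int = 5
    l1: float = 5.0e-2        # Henry-constant initial scale
    l2: float = 1.0e2         # partial-pressure initial scale
    l3: float = 1.0e-2        # temperature-rate initial scale
    K: float = 1.0            # solubility constant
    alpha: float = 1.0        # influence of the global best
    beta_h: float = 1.0       # gamma scale (exploitation strength)
    eps: float = 0.05         # guard in the fitness-ratio factor
    t_theta: float = 298.15   # reference temperature
    c1: float = 0.1           # lower bound on the reinitialised worst fraction
    c2: float = 0.2           # upper bound on the reinitialised worst fraction

    def __post_init__(self) -> None:
        if not self.c1 < self.c2:
            raise ValidationError("HGSO requires c1 < c2")


@dataclass(frozen=True)
class PSOParams:
    w_start: float = 0.9
    w_end: float = 0.4
    c1: float = 2.0           # cognitive coefficient
    c2: float = 2.0           # social coefficient
    v_max: float = 0.6        # velocity clamp on the unit cube


_DEFAULT_PARAMS = {
    "sma": SMAParams,
    "pfa": PFAParams,
    "hgso": HGSOParams,
    "pso": PSOParams,
}


@dataclass(frozen=True)
class OptimizerConfig:
    """Framework settings shared by all algorithms.

    ``pop_size`` and ``max_iter`` default to 10 agents and 100 iterations;
    on the omics matrices targeted here convergence typically occurs within
    the first 10-25 iterations, so 100 leaves ample headroom.
    """

    algorithm: str = "sma"
    pop_size: int = 10
    max_iter: int = 100
    seed: int = 0
    binarize_threshold: float = 0.5
    params: object | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValidationError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValidationError("binarize_threshold must be in (0, 1)")
        if self.algorithm not in _ALGORITHMS:
            raise ValidationError(
                f"unknown algorithm {self.algorithm!r}; "
                f"registered: {sorted(_ALGORITHMS)}"
            )

    def resolved_params(self):
        if self.params is not None:
            return self.params
        factory = _DEFAULT_PARAMS.get(self.algorithm)
        return factory() if factory is not None else None


@dataclass
class OptRun:
    """Result of one optimizer run."""

    best_mask: np.ndarray
    best_fitness: float
    trace: np.ndarray            # best-so-far fitness, length max_iter
    n_selected_trace: np.ndarray  # selected-feature count of the incumbent
    n_evaluations: int
    seed: int
    algorithm: str


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a continuous position into a feature mask.

    A component strictly greater than ``threshold`` selects the feature.
    An all-zero outcome is repaired by promoting the single largest
    component, so every evaluated agent encodes a valid subset.
    """
    position = np.asarray(position, dtype=float)
    bits = position > threshold
    if not bits.any():
        bits = np.zeros_like(bits)
        bits[int(np.argmax(position))] = True
    return bits


# ---------------------------------------------------------------------------
# update rules
# ---------------------------------------------------------------------------

def update_sma(
    positions: np.ndarray,
    fitnesses: np.ndarray,
    best_position: np.ndarray,
    best_fitness: float,
    t: int,
    T: int,
    params: SMAParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One slime-mould iteration over the whole population."""
    n, d = positions.shape
    order = np.argsort(fitnesses, kind="stable")
    bf, wf = fitnesses[order[0]], fitnesses[order[-1]]
    spread = bf - wf
    if spread == 0:
        spread = -np.finfo(float).eps

    # ranked weights: top half amplified, bottom half damped
    weights = np.empty((n, d))
    ratio = np.log10((bf - fitnesses) / spread + 1.0)
    for rank, i in enumerate(order):
        r = rng.random(d)
        if rank < n // 2:
            weights[i] = 1.0 + r * ratio[i]
        else:
            weights[i] = 1.0 - r * ratio[i]

    a = np.arctanh(max(1.0 - t / T, np.finfo(float).eps))
    b = max(1.0 - t / T, 0.0)
    new = np.empty_like(positions)
    for i in range(n):
        if rng.random() < params.z:
            new[i] = rng.random(d)
            continue
        p = np.tanh(abs(fitnesses[i] - best_fitness))
        vb = rng.uniform(-a, a, d)
        vc = rng.uniform(-b, b, d)
        ia, ib = rng.integers(0, n, 2)
        r = rng.random(d)
        approach = best_position + vb * (weights[i] * positions[ia] - positions[ib])
        wander = vc * positions[i]
        new[i] = np.where(r < p, approach, wander)
    return new


def update_pfa(
    positions: np.ndarray,
    fitnesses: np.ndarray,
    pathfinder: np.ndarray,
    pathfinder_prev: np.ndarray,
    t: int,
    T: int,
    params: PFAParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One pathfinder iteration: leader momentum plus follower attraction."""
    n, d = positions.shape
    lo, hi = params.u_range
    leader_idx = int(np.argmin(fitnesses))

    new = np.empty_like(positions)
    # leader: momentum toward its previous displacement + decaying noise
    r3 = rng.random(d)
    A = rng.uniform(lo, hi, d) * np.exp(-2.0 * t / T)
    new[leader_idx] = pathfinder + 2.0 * r3 * (pathfinder - pathfinder_prev) + A

    alpha = rng.uniform(*params.alpha_range)
    beta = rng.uniform(*params.beta_range)
    for i in range(n):
        if i == leader_idx:
            continue
        j = int(rng.integers(0, n - 1))
        if j >= i:
            j += 1
        r1 = rng.random(d)
        r2 = rng.random(d)
        dist = float(np.linalg.norm(positions[i] - positions[j]))
        eps = (1.0 - t / T) * rng.uniform(lo, hi, d) * dist
        new[i] = (
            positions[i]
            + alpha * r1 * (positions[j] - positions[i])
            + beta * r2 * (pathfinder - positions[i])
            + eps
        )
    return new


def update_hgso(
    positions: np.ndarray,
    fitnesses: np.ndarray,
    best_position: np.ndarray,
    best_fitness: float,
    clusters: np.ndarray,
    henry: np.ndarray,
    pressure: np.ndarray,
    temp_rate: np.ndarray,
    t: int,
    T: int,
    params: HGSOParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One Henry-gas iteration; returns (positions, updated henry constants).

    ``clusters`` assigns each agent a gas type; ``henry``/``temp_rate`` are
    per-cluster, ``pressure`` per-agent.
    """
    n, d = positions.shape
    n_clusters = henry.size
    if n_clusters > n:
        raise ValidationError("n_clusters cannot exceed population size")

    temperature = np.exp(-t / T)
    henry = henry * np.exp(-temp_rate * (1.0 / temperature - 1.0 / params.t_theta))
    solubility = params.K * henry[clusters] * pressure

    new = np.empty_like(positions)
    for c in range(n_clusters):
        members = np.flatnonzero(clusters == c)
        if members.size == 0:
            continue
        c_best = members[np.argmin(fitnesses[members])]
        for i in members:
            gamma = params.beta_h * np.exp(
                -(best_fitness + params.eps) / (fitnesses[i] + params.eps)
            )
            flag = 1.0 if rng.random() < 0.5 else -1.0
            r = rng.random(d)
            new[i] = (
                positions[i]
                + flag * r * gamma * (positions[c_best] - positions[i])
                + flag * r * params.alpha
                * (solubility[i] * best_position - positions[i])
            )
    return new, henry


def update_pso(
    positions: np.ndarray,
    velocities: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    t: int,
    T: int,
    params: PSOParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One particle-swarm iteration; returns (positions, velocities)."""
    n, d = positions.shape
    w = inertia_weight(t, T, params.w_start, params.w_end)
    r1 = rng.random((n, d))
    r2 = rng.random((n, d))
    velocities = (
        w * velocities
        + params.c1 * r1 * (pbest - positions)
        + params.c2 * r2 * (gbest - positions)
    )
    np.clip(velocities, -params.v_max, params.v_max, out=velocities)
    return positions + velocities, velocities


def inertia_weight(
    t: int, T: int, w_start: float = 0.9, w_end: float = 0.4
) -> float:
    """Linear inertia schedule: w(0) = w_start, w(T) = w_end."""
    return w_start + (w_end - w_start) * (t / T)


# ---------------------------------------------------------------------------
# per-algorithm strategy wrappers
# ---------------------------------------------------------------------------

class _Strategy:
    """One algorithm's state and per-iteration step within the framework."""

    def init(self, positions, fitnesses, rng):  # pragma: no cover - interface
        pass

    def step(self, positions, fitnesses, best_pos, best_fit, t, T, rng):
        raise NotImplementedError


class _SMAStrategy(_Strategy):
    def __init__(self, params: SMAParams):
        self.params = params

    def step(self, positions, fitnesses, best_pos, best_fit, t, T, rng):
        return update_sma(
            positions, fitnesses, best_pos, best_fit, t, T, self.params, rng
        )


class _PFAStrategy(_Strategy):
    def __init__(self, params: PFAParams):
        self.params = params
        self.prev_pathfinder: np.ndarray | None = None

    def init(self, positions, fitnesses, rng):
        self.prev_pathfinder = positions[int(np.argmin(fitnesses))].copy()

    def step(self, positions, fitnesses, best_pos, best_fit, t, T, rng):
        new = update_pfa(
            positions,
            fitnesses,
            best_pos,
            self.prev_pathfinder,
            t,
            T,
            self.params,
            rng,
        )
        self.prev_pathfinder = best_pos.copy()
        return new


class _HGSOStrategy(_Strategy):
    def __init__(self, params: HGSOParams):
        self.params = params

    def init(self, positions, fitnesses, rng):
        n = positions.shape[0]
        p = self.params
        if p.n_clusters > n:
            raise ValidationError("n_clusters cannot exceed population size")
        # contiguous equal blocks, fixed for the run
        self.clusters = np.minimum(
            np.arange(n) * p.n_clusters // n, p.n_clusters - 1
        )
        self.henry = p.l1 * rng.random(p.n_clusters)
        self.pressure = p.l2 * rng.random(n)
        self.temp_rate = p.l3 * rng.random(p.n_clusters)

    def step(self, positions, fitnesses, best_pos, best_fit, t, T, rng):
        p = self.params
        n, d = positions.shape
        new, self.henry = update_hgso(
            positions,
            fitnesses,
            best_pos,
            best_fit,
            self.clusters,
            self.henry,
            self.pressure,
            self.temp_rate,
            t,
            T,
            p,
            rng,
        )
        # reinitialise a random fraction of the worst agents
        frac = rng.uniform(p.c1, p.c2)
        n_worst = int(round(n * frac))
        if n_worst > 0:
            worst = np.argsort(fitnesses, kind="stable")[-n_worst:]
            for i in worst:
                new[i] = rng.random(d)
        return new


class _PSOStrategy(_Strategy):
    def __init__(self, params: PSOParams):
        self.params = params

    def init(self, positions, fitnesses, rng):
        self.velocities = np.zeros_like(positions)
        self.pbest = positions.copy()
        self.pbest_fit = fitnesses.copy()

    def step(self, positions, fitnesses, best_pos, best_fit, t, T, rng):
        improved = fitnesses < self.pbest_fit
        self.pbest[improved] = positions[improved]
        self.pbest_fit[improved] = fitnesses[improved]
        new, self.velocities = update_pso(
            positions,
            self.velocities,
            self.pbest,
            best_pos,
            t,
            T,
            self.params,
            rng,
        )
        return new


_ALGORITHMS: dict[str, Callable[[object], _Strategy]] = {
    "sma": lambda p: _SMAStrategy(p),
    "pfa": lambda p: _PFAStrategy(p),
    "hgso": lambda p: _HGSOStrategy(p),
    "pso": lambda p: _PSOStrategy(p),
}


def register_algorithm(name: str, factory: Callable[[object], _Strategy]) -> None:
    """Register an additional update rule under ``name``.

    The factory receives the algorithm-params object from the config and
    must return an object with ``init`` and ``step`` methods matching
    :class:`_Strategy`.
    """
    _ALGORITHMS[name.lower()] = factory


def available_algorithms() -> list[str]:
    return sorted(_ALGORITHMS)


# ---------------------------------------------------------------------------
# framework
# ---------------------------------------------------------------------------

def optimize(
    m: FeatureMatrix,
    fit_cfg: FitnessConfig,
    opt_cfg: OptimizerConfig,
    position_callback: Callable[[int, np.ndarray], None] | None = None,
) -> OptRun:
    """Run one binary feature-subset search.

    The population is initialised uniformly in [0, 1]^d from the run seed;
    each iteration applies the configured update rule, clips to the unit
    cube, binarizes, evaluates fitness (memoised per mask) and updates the
    globally retained best.  All stochastic draws come from a single seeded
    generator in a fixed order, so identical configs reproduce identical
    runs.  ``position_callback(iteration, positions)`` is invoked after
    every iteration's clipping step, for instrumentation.
    """
    if np.unique(m.labels.astype(str)).size < 2:
        raise ValidationError("dataset must contain at least 2 classes")
    if m.missing_mask.any():
        raise ValidationError("matrix contains missing values; preprocess first")

    d = m.n_features
    n = opt_cfg.pop_size
    T = opt_cfg.max_iter
    rng = np.random.default_rng(opt_cfg.seed)
    evaluator = FitnessEvaluator(m, fit_cfg)
    strategy = _ALGORITHMS[opt_cfg.algorithm](opt_cfg.resolved_params())

    positions = rng.random((n, d))
    masks = [binarize(pos, opt_cfg.binarize_threshold) for pos in positions]
    fitnesses = np.array([evaluator(msk) for msk in masks])

    best_i = int(np.argmin(fitnesses))
    best_fit = float(fitnesses[best_i])
    best_mask = masks[best_i].copy()
    best_pos = positions[best_i].copy()

    strategy.init(positions, fitnesses, rng)
    if position_callback is not None:
        position_callback(0, positions)

    trace = np.empty(T)
    n_sel_trace = np.empty(T, dtype=int)
    trace[0] = best_fit
    n_sel_trace[0] = int(best_mask.sum())

    for t in range(1, T):
        positions = strategy.step(
            positions, fitnesses, best_pos, best_fit, t, T, rng
        )
        np.clip(positions, 0.0, 1.0, out=positions)
        if position_callback is not None:
            position_callback(t, positions)
        masks = [binarize(pos, opt_cfg.binarize_threshold) for pos in positions]
        fitnesses = np.array([evaluator(msk) for msk in masks])
        i = int(np.argmin(fitnesses))
        if fitnesses[i] < best_fit:
            best_fit = float(fitnesses[i])
            best_mask = masks[i].copy()
            best_pos = positions[i].copy()
        trace[t] = best_fit
        n_sel_trace[t] = int(best_mask.sum())

    return OptRun(
        best_mask=best_mask,
        best_fitness=best_fit,
        trace=trace,
        n_selected_trace=n_sel_trace,
        n_evaluations=evaluator.n_evaluations,
        seed=opt_cfg.seed,
        algorithm=opt_cfg.algorithm,
    )


def write_trace(run: OptRun, path) -> None:
    """Write the convergence trace as TSV (iteration, best_fitness, n_selected)."""
    with open(path, "w") as fh:
        fh.write("iteration\tbest_fitness\tn_selected\n")
        for i, (f, s) in enumerate(zip(run.trace, run.n_selected_trace), start=1):
            fh.write(f"{i}\t{f:.10g}\t{s}\n")
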
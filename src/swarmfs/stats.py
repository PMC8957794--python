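"""Nonparametric comparison machinery for method benchmarking.

Paired method comparisons across datasets use the Wilcoxon signed-rank
test (exact null distribution for small samples, normal approximation
with tie and continuity corrections otherwise) and the Friedman test
(within-dataset ranks, chi-squared statistic with tie correction).
Also provides descriptive statistics and the rules used to pick the best
classifier and the top-scoring algorithms from a benchmark table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata

from .data_io import ValidationError


@dataclass
class StatTestResult:
    test: str                      # "wilcoxon" or "friedman"
    statistic: float               # Wilcoxon: min(R+, R-); Friedman: chi-squared
    p_value: float
    r_plus: float | None = None    # rank sum of positive differences
    r_minus: float | None = None   # rank sum of negative differences
    df: int | None = None          # Friedman only
    n_nonzero: int | None = None   # pairs remaining after dropping zeros
    degenerate: bool = False       # all differences zero / all methods equal
    method: str | None = None      # "exact" or "normal-approx"


@dataclass
class DescriptiveStats:
    n: int
    mean: float
    sd: float        # sample standard deviation (n-1 denominator)
    min: float
    max: float


def describe(values: Sequence[float] | np.ndarray) -> DescriptiveStats:
    """n, mean, sample sd, min and max of a vector."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("describe requires at least one value")
    if v.size == 1:
        warnings.warn("sd of a single value reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(v, ddof=1))
    return DescriptiveStats(
        n=int(v.size),
        mean=float(np.mean(v)),
        sd=sd,
        min=float(np.min(v)),
        max=float(np.max(v)),
    )


def _exact_signed_rank_p(doubled_ranks: np.ndarray, r_lo: float, r_hi: float) -> float:
    """Two-sided exact p over all 2^m sign assignments.

    Uses the polynomial (distribution-convolution) form of the null
    distribution of W+; ranks are doubled so tied average ranks become
    integers.  p = P(W+ <= min(R+,R-)) + P(W+ >= max(R+,R-)).
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    n_assign = counts.sum()
    lo = int(round(2 * r_lo))
    hi = int(round(2 * r_hi))
    p = (counts[: lo + 1].sum() + counts[hi:].sum()) / n_assign
    return min(1.0, float(p))


def wilcoxon_signed_rank(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    mode: str = "auto",
) -> StatTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original treatment); tied
    absolute differences receive average ranks.  The reported statistic
    is min(R+, R-).  ``mode`` selects the p-value computation: "exact"
    enumerates the sign-assignment null distribution, "normal-approx"
    uses the large-sample normal with tie and continuity corrections,
    "auto" picks exact for up to 25 nonzero pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired vectors must have equal length")
    if x.size < 2:
        raise ValidationError("need at least 2 pairs")
    if mode not in ("exact", "normal-approx", "auto"):
        raise ValidationError(f"unknown mode {mode!r}")

    diffs = x - y
    nonzero = diffs[diffs != 0]
    m = nonzero.size
    if m == 0:
        return StatTestResult(
            test="wilcoxon",
            statistic=0.0,
            p_value=1.0,
            r_plus=0.0,
            r_minus=0.0,
            n_nonzero=0,
            degenerate=True,
        )
    ranks = rankdata(np.abs(nonzero))
    r_plus = float(ranks[nonzero > 0].sum())
    r_minus = float(ranks[nonzero < 0].sum())
    stat = min(r_plus, r_minus)

    if mode == "auto":
        mode = "exact" if m <= 25 else "normal-approx"
    if mode == "exact":
        doubled = np.round(2 * ranks).astype(int)
        p = _exact_signed_rank_p(
            doubled, min(r_plus, r_minus), max(r_plus, r_minus)
        )
    else:
        mean = m * (m + 1) / 4.0
        # tie correction on the variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
        if var <= 0:
            p = 1.0
        else:
            # continuity correction of 0.5 toward the mean
            z = (stat - mean + 0.5) / np.sqrt(var)
            p = min(1.0, 2.0 * float(norm.cdf(z)))
    return StatTestResult(
        test="wilcoxon",
        statistic=stat,
        p_value=p,
        r_plus=r_plus,
        r_minus=r_minus,
        n_nonzero=m,
        method=mode,
    )


def friedman(results: np.ndarray) -> StatTestResult:
    """Friedman rank test over a k-methods × b-blocks matrix.

    Values are ranked within each block (average ranks for ties); the
    chi-squared statistic uses the tie-corrected general form, df = k-1,
    and the p-value comes from the chi-squared upper tail.  When every
    method is identical in every block the statistic is 0 and p = 1.
    """
    results = np.asarray(results, dtype=float)
    if results.ndim != 2:
        raise ValidationError("results must be a 2-D matrix (methods × blocks)")
    k, b = results.shape
    if k < 2 or b < 2:
        raise ValidationError("need at least 2 methods and 2 blocks")

    ranks = np.empty_like(results)
    for j in range(b):
        ranks[:, j] = rankdata(results[:, j])
    r_sums = ranks.sum(axis=1)
    a_stat = float(np.sum(ranks**2))
    correction = a_stat - b * k * (k + 1) ** 2 / 4.0
    if correction <= 0:  # all methods tied in every block
        stat = 0.0
        p = 1.0
        degenerate = True
    else:
        stat = (k - 1) * float(np.sum((r_sums - b * (k + 1) / 2.0) ** 2)) / correction
        p = float(chi2.sf(stat, k - 1))
        degenerate = False
    return StatTestResult(
        test="friedman",
        statistic=stat,
        p_value=p,
        df=k - 1,
        degenerate=degenerate,
    )


@dataclass
class SelectionResult:
    best_classifier: str
    classifier_counts: dict[str, int]
    top_algorithms: list[str]
    algorithm_counts: dict[str, int]


def select_best(
    accuracies: Mapping[str, Mapping[str, Mapping[str, float]]],
    avg_feature_counts: Mapping[str, float] | None = None,
    n_top: int = 3,
) -> SelectionResult:
    """Pick the best classifier and the top algorithms from a benchmark.

    ``accuracies`` maps algorithm -> dataset -> classifier -> accuracy and
    must be complete (same datasets and classifiers everywhere).  The best
    classifier is the one that attains the per-cell maximum accuracy most
    often over algorithm × dataset cells (ties credit all tied
    classifiers).  Algorithms are then ranked by how many datasets they
    win under that classifier; ties are broken by smaller average
    selected-feature count (``avg_feature_counts``), then lexicographically.
    """
    algorithms = sorted(accuracies)
    if not algorithms:
        raise ValidationError("empty accuracy table")
    datasets = sorted(accuracies[algorithms[0]])
    classifiers = sorted(accuracies[algorithms[0]][datasets[0]])
    missing = [
        f"{alg}/{ds}/{clf}"
        for alg in algorithms
        for ds in datasets
        for clf in classifiers
        if clf not in accuracies.get(alg, {}).get(ds, {})
    ]
    if missing:
        raise ValidationError(f"incomplete accuracy table; missing: {missing}")

    clf_counts = {c: 0 for c in classifiers}
    for alg in algorithms:
        for ds in datasets:
            cell = accuracies[alg][ds]
            best = max(cell[c] for c in classifiers)
            for c in classifiers:
                if cell[c] == best:
                    clf_counts[c] += 1
    best_clf = max(classifiers, key=lambda c: (clf_counts[c], c))
    # deterministic final tie-break: lexicographically smallest among tied
    tied = [c for c in classifiers if clf_counts[c] == clf_counts[best_clf]]
    best_clf = min(tied)

    alg_counts = {a: 0 for a in algorithms}
    for ds in datasets:
        best = max(accuracies[a][ds][best_clf] for a in algorithms)
        for a in algorithms:
            if accuracies[a][ds][best_clf] == best:
                alg_counts[a] += 1

    def sort_key(a: str):
        feat = (
            avg_feature_counts.get(a, float("inf"))
            if avg_feature_counts is not None
            else float("inf")
        )
        return (-alg_counts[a], feat, a)

    top = sorted(algorithms, key=sort_key)[:n_top]
    return SelectionResult(
        best_classifier=best_clf,
        classifier_counts=clf_counts,
        top_algorithms=top,
        algorithm_counts=alg_counts,
    )
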
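"""Synthetic omics datasets with planted informative features.

Two value models mirror the two data families the pipeline targets:

* ``gaussian`` — transcriptome-like: unbounded real values, features drawn
  from normal distributions; informative features carry a between-class
  mean shift of ``effect_size`` standard deviations.
* ``beta`` — methylation-like: values bounded in [0, 1] like CpG beta
  values, drawn from beta distributions with a per-feature baseline mean;
  informative features shift the class-1 mean by ``effect_size`` times the
  beta standard deviation (clipped away from the bounds).

The planted informative mask is returned as ground truth so selection
methods can be scored by recovery.  Default shapes are desk-scale
(60 samples × 2,000 genes for expression, 60 × 20,000 CpGs for
methylation): large enough to show the "large p, small n" geometry of
real series, small enough for routine runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import FeatureMatrix, ValidationError


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic dataset.

    ``n_per_class`` samples per class, ``n_features`` total features of
    which ``n_informative`` are class-associated with standardized shift
    ``effect_size``; ``missing_rate`` entries are masked uniformly at
    random.
    """

    n_per_class: int = 30
    n_features: int = 2000
    n_informative: int = 5
    effect_size: float = 3.0
    noise_sd: float = 1.0
    value_model: str = "gaussian"   # "gaussian" or "beta"
    missing_rate: float = 0.0
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_features < 1:
            raise ValidationError("n_per_class and n_features must be >= 1")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValidationError("n_informative must be in [0, n_features]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.value_model not in ("gaussian", "beta"):
            raise ValidationError(f"unknown value_model {self.value_model!r}")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


def generate(spec: SynthSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Draw one dataset; returns (matrix, planted informative mask).

    Deterministic given ``spec.seed``.  Informative feature indices are
    drawn without replacement; class labels are "c0", "c1", ....
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class * spec.n_classes
    d = spec.n_features
    labels = np.repeat([f"c{i}" for i in range(spec.n_classes)], spec.n_per_class)
    class_idx = np.repeat(np.arange(spec.n_classes), spec.n_per_class)

    informative = np.zeros(d, dtype=bool)
    informative[rng.choice(d, size=spec.n_informative, replace=False)] = True

    if spec.value_model == "gaussian":
        values = rng.normal(0.0, spec.noise_sd, size=(n, d))
        # symmetric class offsets around 0, spaced effect_size * sd apart
        offsets = (
            np.arange(spec.n_classes) - (spec.n_classes - 1) / 2.0
        ) * spec.effect_size * spec.noise_sd
        values[:, informative] += offsets[class_idx][:, None]
    else:
        concentration = 20.0  # beta a+b; sets within-class spread
        base_mean = rng.uniform(0.2, 0.8, size=d)
        values = np.empty((n, d))
        beta_sd = np.sqrt(
            base_mean * (1 - base_mean) / (concentration + 1.0)
        )
        offsets = (
            np.arange(spec.n_classes) - (spec.n_classes - 1) / 2.0
        ) * spec.effect_size
        for c in range(spec.n_classes):
            mean = np.array(base_mean)
            mean[informative] = np.clip(
                base_mean[informative] + offsets[c] * beta_sd[informative],
                0.02,
                0.98,
            )
            a = mean * concentration
            b = (1.0 - mean) * concentration
            rows = class_idx == c
            values[rows] = rng.beta(a, b, size=(int(rows.sum()), d))

    missing = np.zeros((n, d), dtype=bool)
    if spec.missing_rate > 0:
        missing = rng.random((n, d)) < spec.missing_rate
        values = np.where(missing, np.nan, values)

    m = FeatureMatrix(
        values=values,
        labels=labels,
        feature_ids=np.array([f"f{i}" for i in range(d)], dtype=object),
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        missing_mask=missing,
    )
    return m, informative


def recovery_score(
    selected: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """Overlap of a selected mask with the planted mask.

    Returns (Jaccard index, recall of planted features).  Two empty masks
    give (0, 0) by convention.
    """
    selected = np.asarray(selected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if selected.shape != truth.shape:
        raise ValidationError("masks must have equal length")
    inter = int((selected & truth).sum())
    union = int((selected | truth).sum())
    jaccard = inter / union if union else 0.0
    recall = inter / int(truth.sum()) if truth.any() else 0.0
    return jaccard, recall
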
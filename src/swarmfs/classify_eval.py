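"""Objective function and classifier-based evaluation.

Wrapper feature selection scores a candidate feature subset by the
cross-validated error of a classifier restricted to those features.  The
scalar objective minimised by the optimizers is

    fit = beta * ER + (1 - beta) * |SF| / |AF|

where ``ER`` is the k-nearest-neighbour (k = 5) classification error under
stratified 5-fold cross-validation, ``|SF|`` the number of selected features,
``|AF|`` the total feature count, and ``beta`` (default 0.99) weights
classification performance far above subset size.  An empty subset scores the
worst possible fitness of 1.0 so optimizers are repelled from it.

Final subsets are additionally reported with a panel of five classifier
families (SVM, KNN, discriminant analysis, an ensemble of bagged trees, and
Gaussian naive Bayes) with accuracy, precision, recall, F1 and AUC ROC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_io import FeatureMatrix, ValidationError

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("SVM", "KNN", "DA", "EoL", "NB")


@dataclass(frozen=True)
class FitnessConfig:
    """Parameters of the selection objective.

    beta
        Weight of the classification error term, in [0, 1].  0.99 puts
        almost all weight on accuracy, with a small pressure toward
        smaller subsets.
    knn_k
        Neighbour count of the internal KNN used for the error term.
    n_folds
        Folds of the internal cross-validation.
    fold_seed
        Seed of the fold assignment; the folds are drawn once per optimizer
        run and reused for every fitness call, so fitness is a deterministic
        function of the mask within a run.
    stratified
        Preserve per-class proportions across folds.
    """

    beta: float = 0.99
    knn_k: int = 5
    n_folds: int = 5
    fold_seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValidationError("beta must be in [0, 1]")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with respect to a designated positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


@dataclass
class ClassifierMetrics:
    """Pooled cross-validated metrics for one classifier."""

    accuracy: float
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    auc_roc: float | None = None
    confusion: ConfusionCounts | None = None
    per_fold_accuracy: list[float] = field(default_factory=list)
    skipped_folds: list[int] = field(default_factory=list)


@dataclass
class EvaluationReport:
    """Metrics per classifier, plus the positive class used for binary tasks."""

    metrics: dict[str, ClassifierMetrics]
    positive_label: str | None
    binary: bool


def kfold_split(
    n_samples: int,
    labels: Sequence | np.ndarray,
    k: int,
    seed: int,
    stratified: bool = True,
) -> list[np.ndarray]:
    """Random k-fold partition of ``range(n_samples)`` into test-index sets.

    Fold sizes differ by at most one; with ``stratified`` the per-class
    counts across folds also differ by at most one (classes smaller than k
    are spread round-robin with a warning).  Deterministic given ``seed``.
    """
    if k > n_samples:
        raise ValidationError(f"k={k} exceeds n_samples={n_samples}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratified:
        start = 0
        for cls in np.unique(labels.astype(str)):
            idx = np.flatnonzero(labels.astype(str) == cls)
            if len(idx) < k:
                warnings.warn(
                    f"class {cls!r} has {len(idx)} members for {k} folds; "
                    "spreading round-robin",
                    stacklevel=2,
                )
            idx = rng.permutation(idx)
            for j, i in enumerate(idx):
                folds[(start + j) % k].append(int(i))
            start = (start + len(idx)) % k
    else:
        perm = rng.permutation(n_samples)
        for part, chunk in zip(folds, np.array_split(perm, k)):
            part.extend(int(i) for i in chunk)
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def loocv_split(n_samples: int) -> list[np.ndarray]:
    """Leave-one-out partition: n singleton test sets."""
    if n_samples < 2:
        raise ValidationError("LOOCV needs at least 2 samples")
    return [np.asarray([i]) for i in range(n_samples)]


def _knn_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, k: int
) -> np.ndarray:
    """KNN with fully specified tie-breaks.

    Distance ties are broken by lowest training-sample index (stable sort);
    vote ties go to the class whose nearest representative among the k
    neighbours comes first in that order.
    """
    k = min(k, x_train.shape[0])
    dist = cdist(x_test, x_train)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    preds = np.empty(x_test.shape[0], dtype=y_train.dtype)
    for i, nbrs in enumerate(order):
        votes: dict = {}
        first_seen: dict = {}
        for rank, j in enumerate(nbrs):
            lab = y_train[j]
            votes[lab] = votes.get(lab, 0) + 1
            first_seen.setdefault(lab, rank)
        best = max(votes, key=lambda lab: (votes[lab], -first_seen[lab]))
        preds[i] = best
    return preds


def error_rate(
    mask: np.ndarray,
    m: FeatureMatrix,
    cfg: FitnessConfig,
    folds: list[np.ndarray] | None = None,
) -> float:
    """Mean KNN misclassification rate over cross-validation folds.

    Only the columns selected by ``mask`` enter the Euclidean distance.
    ``folds`` may be precomputed (one draw per optimizer run); otherwise
    they are derived from ``cfg.fold_seed``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != m.n_features:
        raise ValidationError("mask length != n_features")
    if not mask.any():
        raise ValidationError("error_rate requires a non-empty mask")
    if folds is None:
        folds = kfold_split(
            m.n_samples, m.labels, cfg.n_folds, cfg.fold_seed, cfg.stratified
        )
    x = m.values[:, mask]
    y = m.labels
    all_idx = np.arange(m.n_samples)
    rates = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=True)
        preds = _knn_predict(x[train_idx], y[train_idx], x[test_idx], cfg.knn_k)
        rates.append(float(np.mean(preds != y[test_idx])))
    return float(np.mean(rates))


def fitness_from_error(
    er: float, n_selected: int, n_total: int, beta: float = 0.99
) -> float:
    """The selection objective as a pure formula of its ingredients."""
    if n_selected == 0:
        return 1.0
    return beta * er + (1.0 - beta) * (n_selected / n_total)


def fitness(
    mask: np.ndarray,
    m: FeatureMatrix,
    cfg: FitnessConfig,
    folds: list[np.ndarray] | None = None,
) -> float:
    """Fitness of a feature mask; empty masks receive the 1.0 penalty."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size != m.n_features:
        raise ValidationError("mask length != n_features")
    n_sel = int(mask.sum())
    if n_sel == 0:
        return 1.0
    er = error_rate(mask, m, cfg, folds=folds)
    return fitness_from_error(er, n_sel, m.n_features, cfg.beta)


class FitnessEvaluator:
    """Memoised fitness over a fixed fold assignment.

    Threshold binarization makes optimizers revisit the same mask often, so
    results are cached keyed by the mask bits.  The folds are drawn once at
    construction, making fitness a deterministic function of the mask for
    the lifetime of the evaluator.
    """

    def __init__(self, m: FeatureMatrix, cfg: FitnessConfig):
        self.m = m
        self.cfg = cfg
        self.folds = kfold_split(
            m.n_samples, m.labels, cfg.n_folds, cfg.fold_seed, cfg.stratified
        )
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        val = fitness(mask, self.m, self.cfg, folds=self.folds)
        self.n_evaluations += 1
        self._cache[key] = val
        return val


def _make_classifier(name: str, knn_k: int, seed: int):
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=knn_k)
    if name == "DA":
        return LinearDiscriminantAnalysis()
    if name == "EoL":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=50,
            random_state=seed,
        )
    if name == "NB":
        return GaussianNB()
    raise ValidationError(f"unknown classifier {name!r}")


def _positive_score(name: str, model, x: np.ndarray, positive: str) -> np.ndarray:
    """Continuous score for the positive class, used for the AUC rank statistic."""
    if name == "SVM":
        s = model.decision_function(x)
        return s if str(model.classes_[1]) == positive else -s
    proba = model.predict_proba(x)
    col = int(np.flatnonzero(model.classes_.astype(str) == positive)[0])
    return proba[:, col]


def evaluate_classifiers(
    mask: np.ndarray,
    m: FeatureMatrix,
    classifiers: Iterable[str] = CLASSIFIER_NAMES,
    cv: Sequence[np.ndarray] | None = None,
    knn_k: int = 5,
    positive_label: str | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Cross-validated metric panel for one feature subset.

    Per-fold test predictions are pooled, then binary confusion counts,
    accuracy, precision, recall, F1 and AUC are computed from the pool.
    The positive class is the lexicographically larger label unless
    overridden.  Multiclass inputs produce accuracy only.  Folds where the
    training set collapses to a single class are skipped with a warning and
    recorded in the report.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != m.n_features:
        raise ValidationError("mask length != n_features")
    if not mask.any():
        raise ValidationError("cannot evaluate an empty feature subset")
    names = list(classifiers)
    for name in names:
        if name not in CLASSIFIER_NAMES:
            raise ValidationError(f"unknown classifier {name!r}")
    if cv is None:
        cv = kfold_split(m.n_samples, m.labels, 5, seed, stratified=True)

    x = m.values[:, mask]
    y = m.labels.astype(str)
    classes = np.unique(y)
    binary = classes.size == 2
    if binary:
        positive = positive_label if positive_label is not None else str(
            max(classes)
        )
        if positive not in classes:
            raise ValidationError(f"positive label {positive!r} not in labels")
    else:
        positive = None

    all_idx = np.arange(m.n_samples)
    report = EvaluationReport(metrics={}, positive_label=positive, binary=binary)
    for name in names:
        pooled_true: list[str] = []
        pooled_pred: list[str] = []
        pooled_score: list[float] = []
        per_fold_acc: list[float] = []
        skipped: list[int] = []
        for fold_no, test_idx in enumerate(cv):
            train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=True)
            if np.unique(y[train_idx]).size < 2:
                warnings.warn(
                    f"fold {fold_no}: single-class training set, skipped",
                    stacklevel=2,
                )
                skipped.append(fold_no)
                continue
            model = _make_classifier(name, min(knn_k, len(train_idx)), seed)
            model.fit(x[train_idx], y[train_idx])
            pred = model.predict(x[test_idx]).astype(str)
            pooled_true.extend(y[test_idx])
            pooled_pred.extend(pred)
            per_fold_acc.append(float(np.mean(pred == y[test_idx])))
            if binary:
                pooled_score.extend(
                    _positive_score(name, model, x[test_idx], positive)
                )
        yt = np.asarray(pooled_true)
        yp = np.asarray(pooled_pred)
        acc = float(np.mean(yp == yt)) if yt.size else float("nan")
        cm = ClassifierMetrics(
            accuracy=acc, per_fold_accuracy=per_fold_acc, skipped_folds=skipped
        )
        if binary and yt.size:
            counts = ConfusionCounts(
                tp=int(np.sum((yp == positive) & (yt == positive))),
                fp=int(np.sum((yp == positive) & (yt != positive))),
                tn=int(np.sum((yp != positive) & (yt != positive))),
                fn=int(np.sum((yp != positive) & (yt == positive))),
            )
            cm.confusion = counts
            cm.precision = counts.precision
            cm.recall = counts.recall
            cm.f1 = counts.f1
            if np.unique(yt).size == 2:
                cm.auc_roc = float(
                    roc_auc_score((yt == positive).astype(int), pooled_score)
                )
        report.metrics[name] = cm
    return report
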
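import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swarmfs.classify_eval import (
    ConfusionCounts,
    FitnessConfig,
    FitnessEvaluator,
    error_rate,
    evaluate_classifiers,
    fitness,
    fitness_from_error,
    kfold_split,
    loocv_split,
)
from swarmfs.data_io import ValidationError
from .conftest import make_matrix


class TestKfoldSplit:
    def test_balanced_binary_stratified(self):
        labels = ["a"] * 5 + ["b"] * 5
        folds = kfold_split(10, labels, 5, seed=0)
        assert len(folds) == 5
        for f in folds:
            assert len(f) == 2
            assert sorted(np.array(labels)[f]) == ["a", "b"]

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n = int(rng.integers(6, 40))
            k = int(rng.integers(2, min(6, n) + 1))
            labels = rng.choice(["x", "y", "z"], size=n)
            folds = kfold_split(n, labels, k, seed=trial)
            flat = np.concatenate(folds)
            assert sorted(flat) == list(range(n))       # cover, disjoint
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_per_class_balance(self):
        labels = ["a"] * 7 + ["b"] * 13
        folds = kfold_split(20, labels, 5, seed=1)
        arr = np.array(labels)
        for cls in "ab":
            counts = [int((arr[f] == cls).sum()) for f in folds]
            assert max(counts) - min(counts) <= 1

    def test_singleton_folds_forced(self):
        folds = kfold_split(5, ["a", "a", "b", "b", "b"], 5, seed=0)
        assert sorted(len(f) for f in folds) == [1] * 5

    def test_deterministic(self):
        labels = ["a"] * 6 + ["b"] * 6
        f1 = kfold_split(12, labels, 4, seed=9)
        f2 = kfold_split(12, labels, 4, seed=9)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_small_class_degrades_with_warning(self):
        labels = ["a"] * 2 + ["b"] * 8
        with pytest.warns(UserWarning, match="members"):
            folds = kfold_split(10, labels, 5, seed=0)
        assert sorted(np.concatenate(folds)) == list(range(10))

    def test_k_too_large(self):
        with pytest.raises(ValidationError):
            kfold_split(4, ["a", "b", "a", "b"], 5, seed=0)


class TestLoocv:
    def test_singletons(self):
        folds = loocv_split(5)
        assert [list(f) for f in folds] == [[0], [1], [2], [3], [4]]

    def test_minimum(self):
        assert len(loocv_split(2)) == 2
        with pytest.raises(ValidationError):
            loocv_split(1)


class TestErrorRate:
    def test_separated_clusters_zero_error(self, two_cluster_matrix):
        cfg = FitnessConfig(fold_seed=1)
        mask = np.array([True, False, False])
        assert error_rate(mask, two_cluster_matrix, cfg) == 0.0

    def test_permuted_labels_near_half(self):
        # label permutation breaks any feature-label link; the mean error
        # over 20 permutations must sit in the chance band
        rng = np.random.default_rng(42)
        values = rng.normal(size=(60, 10))
        cfg = FitnessConfig(fold_seed=0)
        mask = np.ones(10, dtype=bool)
        ers = []
        for s in range(20):
            perm = np.random.default_rng(s).permutation(60)
            labels = np.array(["a"] * 30 + ["b"] * 30, dtype=object)[perm]
            m = make_matrix(values, labels)
            ers.append(error_rate(mask, m, cfg))
        assert 0.4 <= np.mean(ers) <= 0.6

    def test_reproducible_under_ties(self):
        # identical point sets with opposite labels force distance ties;
        # the documented tie-break keeps the result bit-stable
        values = np.vstack([np.eye(4), np.eye(4)])
        labels = ["a"] * 4 + ["b"] * 4
        m = make_matrix(values, labels)
        cfg = FitnessConfig(fold_seed=3, n_folds=4)
        mask = np.ones(4, dtype=bool)
        r = [error_rate(mask, m, cfg) for _ in range(3)]
        assert r[0] == r[1] == r[2]

    def test_empty_mask_rejected(self, two_cluster_matrix):
        with pytest.raises(ValidationError):
            error_rate(np.zeros(3, bool), two_cluster_matrix, FitnessConfig())


class TestFitness:
    def test_formula_hand_values(self):
        assert fitness_from_error(0.2, 50, 1000, beta=0.99) == pytest.approx(
            0.1985, abs=1e-12
        )
        assert fitness_from_error(0.0, 1000, 1000, beta=0.99) == pytest.approx(
            0.01, abs=1e-12
        )
        assert fitness_from_error(0.0, 0, 1000, beta=0.99) == 1.0

    def test_empty_mask_penalty(self, two_cluster_matrix):
        assert fitness(np.zeros(3, bool), two_cluster_matrix, FitnessConfig()) == 1.0

    def test_monotone_in_subset_size_at_fixed_error(self):
        f_small = fitness_from_error(0.1, 10, 100)
        f_large = fitness_from_error(0.1, 60, 100)
        assert f_small < f_large

    @given(
        er=st.floats(0, 1),
        n_sel=st.integers(0, 50),
        beta=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=100)
    def test_bounded_in_unit_interval(self, er, n_sel, beta):
        assert 0.0 <= fitness_from_error(er, n_sel, 50, beta) <= 1.0

    def test_length_mismatch(self, two_cluster_matrix):
        with pytest.raises(ValidationError):
            fitness(np.ones(5, bool), two_cluster_matrix, FitnessConfig())

    def test_evaluator_caches_and_matches_direct(self, two_cluster_matrix):
        cfg = FitnessConfig(fold_seed=11)
        ev = FitnessEvaluator(two_cluster_matrix, cfg)
        mask = np.array([True, True, False])
        v1 = ev(mask)
        v2 = ev(mask)
        assert v1 == v2 and ev.n_evaluations == 1
        assert v1 == fitness(mask, two_cluster_matrix, cfg, folds=ev.folds)


class TestEvaluateClassifiers:
    def test_confusion_arithmetic(self):
        c = ConfusionCounts(tp=50, fp=5, tn=40, fn=5)
        assert c.accuracy == pytest.approx(0.9)
        # everything predicted positive, half truly positive
        c2 = ConfusionCounts(tp=5, fp=5, tn=0, fn=0)
        assert c2.precision == pytest.approx(0.5)
        assert c2.recall == pytest.approx(1.0)
        # degenerate: nothing predicted or truly positive
        c3 = ConfusionCounts(tp=0, fp=0, tn=10, fn=0)
        assert c3.f1 == 0.0

    @pytest.mark.parametrize("clf", ["SVM", "KNN", "DA", "EoL", "NB"])
    def test_separable_data_perfect_metrics(self, separable_matrix, clf):
        report = evaluate_classifiers(
            np.ones(4, bool), separable_matrix, [clf], seed=0
        )
        cm = report.metrics[clf]
        assert cm.accuracy == 1.0
        assert cm.f1 == 1.0
        assert cm.auc_roc == 1.0

    def test_positive_class_defaults_to_lexicographically_larger(
        self, separable_matrix
    ):
        report = evaluate_classifiers(np.ones(4, bool), separable_matrix, ["NB"])
        assert report.positive_label == "pos"

    def test_multiclass_accuracy_only(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(18, 3))
        values[:6, 0] += 8
        values[6:12, 1] += 8
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        m = make_matrix(values, labels)
        report = evaluate_classifiers(np.ones(3, bool), m, ["KNN"], seed=1)
        cm = report.metrics["KNN"]
        assert cm.accuracy > 0.8
        assert cm.auc_roc is None and cm.precision is None

    def test_empty_mask_rejected(self, separable_matrix):
        with pytest.raises(ValidationError):
            evaluate_classifiers(np.zeros(4, bool), separable_matrix, ["KNN"])
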
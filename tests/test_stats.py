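import numpy as np
import pytest
from scipy.stats import friedmanchisquare, rankdata
from scipy.stats import wilcoxon as scipy_wilcoxon

from swarmfs.data_io import ValidationError
from swarmfs.stats import (
    describe,
    friedman,
    select_best,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank_p(diffs):
    """Independent oracle: enumerate all 2^m sign assignments directly."""
    nonzero = diffs[diffs != 0]
    m = nonzero.size
    ranks = rankdata(np.abs(nonzero))
    r_plus = ranks[nonzero > 0].sum()
    r_minus = ranks[nonzero < 0].sum()
    lo, hi = min(r_plus, r_minus), max(r_plus, r_minus)
    assignments = np.array(
        [[(code >> i) & 1 for i in range(m)] for code in range(2**m)]
    )
    w = assignments @ ranks
    hits = np.sum((w <= lo + 1e-9) | (w >= hi - 1e-9))
    return hits / 2**m


class TestDescribe:
    def test_hand_computation(self):
        s = describe([2, 4, 6])
        assert (s.n, s.mean, s.sd, s.min, s.max) == (3, 4.0, 2.0, 2.0, 6.0)

    def test_single_value_sd_zero_with_warning(self):
        with pytest.warns(UserWarning):
            s = describe([5.0])
        assert s.sd == 0.0 and s.min == s.max == 5.0

    def test_constant_vector(self):
        assert describe([3, 3, 3, 3]).sd == 0.0

    def test_permutation_invariance(self):
        a = describe([1.0, 5.0, 2.5, 9.0])
        b = describe([9.0, 2.5, 1.0, 5.0])
        assert (a.mean, a.min, a.max, a.sd) == (b.mean, b.min, b.max, b.sd)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            describe([])


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.degenerate and res.p_value == 1.0

    def test_three_positive_diffs_hand_enumeration(self):
        res = wilcoxon_signed_rank([2, 4, 6], [1, 2, 3])
        assert res.r_plus == 6.0 and res.r_minus == 0.0
        assert res.p_value == pytest.approx(0.25)

    def test_rank_sum_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 15))
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = wilcoxon_signed_rank(x, y)
            m = res.n_nonzero
            assert res.r_plus + res.r_minus == pytest.approx(m * (m + 1) / 2)

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(3, 13))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.3:  # inject ties in |differences|
                y[: n // 2] = x[: n // 2] - 1.0
            res = wilcoxon_signed_rank(x, y, mode="exact")
            assert res.p_value == pytest.approx(
                brute_force_signed_rank_p(x - y), abs=1e-12
            )

    def test_exact_p_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        ours = wilcoxon_signed_rank(x, y, mode="exact")
        ref = scipy_wilcoxon(x, y, mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_matches_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=40), rng.normal(size=40)
        ours = wilcoxon_signed_rank(x, y, mode="normal-approx")
        ref = scipy_wilcoxon(x, y, mode="approx", correction=True)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_auto_switches_by_sample_size(self):
        rng = np.random.default_rng(3)
        small = wilcoxon_signed_rank(rng.normal(size=10), rng.normal(size=10))
        large = wilcoxon_signed_rank(rng.normal(size=30), rng.normal(size=30))
        assert small.method == "exact" and large.method == "normal-approx"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestFriedman:
    def test_perfect_ranking_closed_form(self):
        # every block ranks the 3 methods identically; with b=10 blocks the
        # closed form 12b/(k(k+1)) * sum((Rbar-(k+1)/2)^2) gives 20
        results = np.tile([[1.0], [2.0], [3.0]], (1, 10))
        res = friedman(results)
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 2

    def test_identical_methods_zero_statistic(self):
        res = friedman(np.ones((3, 10)))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy_on_tie_free_inputs(self):
        rng = np.random.default_rng(4)
        results = rng.normal(size=(4, 12))
        ours = friedman(results)
        ref = friedmanchisquare(*results)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_invariance_under_block_permutation_and_relabeling(self):
        rng = np.random.default_rng(6)
        results = rng.normal(size=(3, 8))
        base = friedman(results).statistic
        assert friedman(results[:, rng.permutation(8)]).statistic == pytest.approx(base)
        assert friedman(results[[2, 0, 1]]).statistic == pytest.approx(base)

    def test_shape_validation(self):
        with pytest.raises(ValidationError):
            friedman(np.ones((1, 5)))


class TestSelectBest:
    @staticmethod
    def _table(winners, classifiers=("KNN", "SVM")):
        """One dataset per entry; the named algorithm wins it under KNN."""
        algorithms = sorted(set(winners))
        table = {}
        for alg in algorithms:
            table[alg] = {}
            for ds, win in enumerate(winners):
                acc = 0.95 if alg == win else 0.80
                table[alg][f"d{ds}"] = {"KNN": acc, "SVM": acc - 0.05}
        return table

    def test_dominant_classifier_selected_everywhere(self):
        table = self._table(["P", "S", "P"])
        res = select_best(table)
        assert res.best_classifier == "KNN"
        assert res.classifier_counts["KNN"] == 3 * 2  # every cell

    def test_tie_break_by_average_feature_count(self):
        winners = (
            ["P"] * 12 + ["S"] * 8 + ["A"] * 7 + ["G"] * 7 + ["Z"] * 7 + ["H"] * 7
        )
        feats = {"P": 100, "S": 90, "H": 5, "A": 10, "G": 20, "Z": 30}
        res = select_best(self._table(winners), avg_feature_counts=feats)
        assert res.algorithm_counts == {"P": 12, "S": 8, "A": 7, "G": 7,
                                        "Z": 7, "H": 7}
        assert res.top_algorithms == ["P", "S", "H"]

    def test_equal_counts_equal_features_lexicographic(self):
        res = select_best(
            self._table(["B", "A"]), avg_feature_counts={"A": 3, "B": 3}
        )
        assert res.top_algorithms[:2] == ["A", "B"]

    def test_incomplete_table_rejected(self):
        table = self._table(["P", "S"])
        del table["P"]["d1"]["SVM"]
        with pytest.raises(ValidationError, match="missing"):
            select_best(table)
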
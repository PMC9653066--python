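import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paircomm.containers import FunctionTable
from paircomm.groupstats import (
    auto_group_test,
    bh_adjust,
    distance_matrix,
    permanova,
    rf_screen,
    venn_partition,
    welch_compare,
)
from paircomm.synthetic import SyntheticConfig, generate_paired_counts

from conftest import make_counts


class TestAutoGroupTest:
    def test_identical_groups_near_zero_statistic(self):
        res = auto_group_test([1.0, 2, 3, 1, 2, 3], ["A"] * 3 + ["B"] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p > 0.99

    def test_gaussian_data_uses_t(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, 16)
        res = auto_group_test(vals, ["A"] * 8 + ["B"] * 8)
        assert res.method_used == "t"
        assert res.normality_p > 0.05
        assert res.homoscedasticity_p > 0.05

    def test_heavy_tailed_data_falls_back_to_wilcoxon(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_cauchy(30) ** 3
        res = auto_group_test(vals, ["A"] * 15 + ["B"] * 15)
        assert res.method_used == "wilcoxon"
        assert res.normality_p <= 0.05

    def test_three_groups_parametric_is_anova(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 24)
        res = auto_group_test(vals, ["A"] * 8 + ["B"] * 8 + ["C"] * 8)
        assert res.method_used in {"anova", "kruskal_wallis"}

    def test_constant_everywhere_raises(self):
        with pytest.raises(ValueError, match="constant"):
            auto_group_test([2.0, 2, 2, 2], ["A", "A", "B", "B"])


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3] * 5), [0.3] * 5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_bounded_monotone_and_dominates_raw(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj <= 1.0 + 1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestDistances:
    def test_identical_samples_zero(self):
        d = distance_matrix(make_counts([[3, 3], [1, 1]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_one_for_both_metrics(self):
        cm = make_counts([[4, 0], [0, 9]])
        for metric in ("bray_curtis", "jaccard"):
            assert distance_matrix(cm, metric).iloc[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_hand_value(self):
        d = distance_matrix(make_counts([[1, 1], [0, 2]]))
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            distance_matrix(make_counts([[1, 0], [1, 0]]))


class TestPermanova:
    @staticmethod
    def _separated():
        d = np.ones((6, 6))
        d[np.ix_(range(3), range(3))] = 0
        d[np.ix_(range(3, 6), range(3, 6))] = 0
        np.fill_diagonal(d, 0)
        return d

    def test_exhaustive_two_block_design(self):
        """3v3 with maximal separation: only the observed split and its mirror
        reach the observed F among the 20 assignments, so p = 0.1."""
        res = permanova(self._separated(), ["A"] * 3 + ["B"] * 3, 999, seed=0)
        assert res.n_permutations == 20
        assert res.p == pytest.approx(0.1)
        assert res.R2 == pytest.approx(1.0)

    def test_matches_reference_permanova(self):
        """Cross-check pseudo-F against the scikit-bio implementation."""
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        labels = ["A"] * 5 + ["B"] * 5
        ours = permanova(d, labels, n_permutations=99, seed=1)
        ref = skbio_permanova(DistanceMatrix(d), labels, permutations=99)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_degenerate_identical_samples(self):
        res = permanova(np.zeros((6, 6)), ["A"] * 3 + ["B"] * 3, 99, seed=0)
        assert res.pseudo_F == 0.0
        assert res.p == 1.0

    def test_label_permutation_invariance_of_r2_bounds(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(12, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        res = permanova(d, ["A"] * 6 + ["B"] * 6, 99, seed=0)
        assert 0.0 <= res.R2 <= 1.0
        assert res.p >= 1.0 / (res.n_permutations + 1)

    def test_rejects_asymmetric_matrix(self):
        d = np.eye(4) + np.triu(np.ones((4, 4)), 1)
        with pytest.raises(ValueError, match="symmetric"):
            permanova(d, ["A", "A", "B", "B"], 99)


class TestVenn:
    def test_hand_partition(self):
        cm = make_counts(
            [[9, 0], [1, 5]], groups=["A", "B"], pairs=["p", "p"],
            taxa=["t1", "t2"],
        )
        v = venn_partition(cm)
        assert v.unique_to_a == {"t1"}
        assert v.unique_to_b == set()
        assert v.shared == {"t2"}
        assert v.fraction_a == pytest.approx(0.9)
        assert v.fraction_b == pytest.approx(0.0)

    def test_identical_groups_nothing_unique(self):
        cm = make_counts([[2, 2], [3, 3]], groups=["A", "B"], pairs=["p", "p"])
        v = venn_partition(cm)
        assert v.unique_to_a == set() and v.unique_to_b == set()

    def test_three_groups_rejected(self):
        cm = make_counts([[1, 1, 1]], groups=["A", "B", "C"], pairs=["p"] * 3)
        with pytest.raises(ValueError, match="2 groups"):
            venn_partition(cm)


class TestRFScreen:
    def test_deterministic_ranking(self):
        cfg = SyntheticConfig(
            n_taxa=20, n_pairs=5, depth_mean=20000, abundance_shape=1.0,
            diff_taxa=[(2, 4.0, "camping")], seed=0,
        )
        cm, _ = generate_paired_counts(cfg)
        a = rf_screen(cm, n_trees=200, seed=1)
        b = rf_screen(cm, n_trees=200, seed=1)
        assert list(a.index) == list(b.index)
        assert sorted(a["rank"]) == list(range(1, 21))

    def test_separating_taxon_ranks_first(self):
        hits = 0
        for rep in range(20):
            cfg = SyntheticConfig(
                n_taxa=30, n_pairs=15, depth_mean=100000, abundance_shape=1.0,
                diff_taxa=[(4, 5.0, "camping")], seed=rep,
            )
            cm, _ = generate_paired_counts(cfg)
            imp = rf_screen(cm, n_trees=500, seed=rep)
            hits += imp.index[0] == "OTU_5"
        assert hits >= 19

    def test_single_class_rejected(self):
        cm = make_counts(np.ones((5, 4), int), groups=["A"] * 4, pairs=["p"] * 4)
        with pytest.raises(ValueError):
            rf_screen(cm, n_trees=10)


class TestWelch:
    def test_hand_computation(self):
        tab = FunctionTable(["f"], [f"s{i}" for i in range(6)],
                            np.array([[1.0, 2, 3, 4, 5, 6]]))
        res = welch_compare(tab, ["A"] * 3 + ["B"] * 3)[0]
        assert res.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))

    def test_label_swap_flips_sign_keeps_p(self):
        rng = np.random.default_rng(2)
        tab = FunctionTable(["f"], [f"s{i}" for i in range(10)],
                            rng.random((1, 10)))
        r1 = welch_compare(tab, ["A"] * 5 + ["B"] * 5)[0]
        r2 = welch_compare(tab, ["B"] * 5 + ["A"] * 5)[0]
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_flat_function_reported_missing(self):
        tab = FunctionTable(["f"], [f"s{i}" for i in range(6)],
                            np.full((1, 6), 0.25))
        res = welch_compare(tab, ["A"] * 3 + ["B"] * 3)[0]
        assert np.isnan(res.p)

    def test_equal_groups_large_p(self):
        tab = FunctionTable(["f"], [f"s{i}" for i in range(8)],
                            np.array([[0.1, 0.2, 0.3, 0.4, 0.1, 0.2, 0.3, 0.4]]))
        res = welch_compare(tab, ["A"] * 4 + ["B"] * 4)[0]
        assert res.p > 0.95
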
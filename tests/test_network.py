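import networkx as nx
import numpy as np
import pytest
from scipy.linalg import expm

from paircomm.network import (
    bootstrap_node_attributes,
    build_network,
    degree_class_partition,
    filter_otus,
    ks_compare,
    natural_connectivity,
    network_properties,
    robustness_sweep,
    stability_after_removal,
)
from paircomm.synthetic import SyntheticConfig, generate_paired_counts

from conftest import make_counts


def nc_oracle(g):
    """Independent natural-connectivity route: trace of the matrix exponential."""
    n = g.number_of_nodes()
    a = nx.to_numpy_array(g, weight=None)
    return float(np.log(np.trace(expm(a)) / n))


class TestFilterOtus:
    def test_prevalence_rule(self):
        cm = make_counts([[10, 0, 0, 0], [5, 5, 5, 5]])
        out = filter_otus(cm)
        assert out.taxon_ids == ["t2"]

    def test_total_share_rule(self):
        # grand total 10,000: 5 reads < 0.1%, 20 reads >= 0.1% (after the
        # abundant filler taxon)
        cm = make_counts([[4975, 5000], [10, 10], [3, 2]])
        out = filter_otus(cm)
        assert "t3" not in out.taxon_ids  # 5/10000 < 0.001
        assert "t2" in out.taxon_ids  # 20/10000 >= 0.001

    def test_everything_kept_when_abundant(self):
        cm = make_counts([[50, 60], [70, 80]])
        assert filter_otus(cm) == cm

    def test_empty_result_warns(self):
        cm = make_counts([[1, 0], [0, 1]])
        with pytest.warns(UserWarning, match="every taxon"):
            out = filter_otus(cm)
        assert out.n_taxa == 0


class TestBuildNetwork:
    def test_identical_profiles_give_positive_unit_edge(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 50, size=10)
        mat = np.vstack([base, base, rng.integers(1, 50, size=10)])
        # make total per sample constant so proportions track counts
        cm = make_counts(mat)
        net = build_network(cm, r_threshold=0.8)
        assert net.has_edge("t1", "t2")
        e = net.edges["t1", "t2"]
        assert e["r"] == pytest.approx(1.0, abs=1e-9)
        assert e["sign"] == "positive"

    def test_mirrored_profiles_give_negative_edge(self):
        up = np.arange(1, 11)
        mat = np.vstack([up, up[::-1], np.full(10, 30)])
        cm = make_counts(mat * 100)
        net = build_network(cm)
        assert net.has_edge("t1", "t2")
        assert net.edges["t1", "t2"]["sign"] == "negative"

    def test_order_invariance(self):
        cfg = SyntheticConfig(
            n_taxa=25, n_pairs=10, depth_mean=30000, abundance_shape=1.0,
            corr_blocks=[([0, 1, 2], 1.0, "positive")], seed=4,
        )
        cm, _ = generate_paired_counts(cfg)
        net = build_network(cm)
        perm_t = np.random.default_rng(1).permutation(cm.n_taxa)
        perm_s = np.random.default_rng(2).permutation(cm.n_samples)
        shuffled = cm.select_taxa(perm_t).select_samples(perm_s)
        net2 = build_network(shuffled)
        assert {frozenset(e) for e in net.edges} == {
            frozenset(e) for e in net2.edges
        }

    def test_too_few_samples_rejected(self):
        cm = make_counts([[1, 2, 3], [3, 2, 1]], groups=["A"] * 3, pairs=["p"] * 3)
        with pytest.raises(ValueError, match="4 samples"):
            build_network(cm)

    def test_isolated_nodes_retained(self):
        rng = np.random.default_rng(5)
        cm = make_counts(rng.integers(1, 100, size=(6, 8)))
        net = build_network(cm)
        assert net.number_of_nodes() == 6


class TestNaturalConnectivity:
    def test_empty_graph_zero(self):
        assert natural_connectivity(nx.empty_graph(7)) == pytest.approx(0.0)

    def test_k2_closed_form(self):
        assert natural_connectivity(nx.complete_graph(2)) == pytest.approx(
            np.log(np.cosh(1)), abs=1e-12
        )

    def test_k3_closed_form(self):
        expected = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
        assert natural_connectivity(nx.complete_graph(3)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_agrees_with_expm_oracle_on_random_graphs(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(2, 51))
            g = nx.gnp_random_graph(n, rng.uniform(0.05, 0.5), seed=int(rng.integers(1e6)))
            assert natural_connectivity(g) == pytest.approx(nc_oracle(g), abs=1e-9)

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(1e6)))
            before = natural_connectivity(g)
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            u, v = non_edges[rng.integers(len(non_edges))]
            g.add_edge(u, v)
            assert natural_connectivity(g) >= before - 1e-12


class TestNetworkProperties:
    def test_complete_graph_regularity(self):
        p = network_properties(nx.complete_graph(4))
        assert p.connectance == pytest.approx(1.0)
        assert p.average_degree == pytest.approx(3.0)
        assert p.degree_centralization == pytest.approx(0.0)
        assert p.n_clusters == 1

    def test_star_centralization_and_vulnerability(self):
        p = network_properties(nx.star_graph(3))  # hub + 3 leaves
        assert p.degree_centralization == pytest.approx(1.0)
        assert p.vulnerability == pytest.approx(1.0)

    def test_two_triangle_modularity(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        p = network_properties(g)
        assert p.modularity == pytest.approx(0.5)
        assert p.n_clusters == 2

    def test_degree_sum_identity(self):
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        p = network_properties(g)
        assert sum(d for _, d in g.degree()) == 2 * p.n_edges
        assert 0.0 <= p.connectance <= 1.0

    def test_tiny_graph_centralization_missing(self):
        p = network_properties(nx.complete_graph(2))
        assert np.isnan(p.degree_centralization)


class TestBootstrapAndKS:
    def test_single_bootstrap_is_node_multiset(self):
        g = nx.path_graph(5)
        out = bootstrap_node_attributes(g, n_boot=1, seed=0)
        assert len(out["degree"]) == 5
        assert set(out["degree"]).issubset({1.0, 2.0})

    def test_bootstrap_mean_converges_to_graph_mean(self):
        g = nx.gnp_random_graph(100, 0.1, seed=1)
        out = bootstrap_node_attributes(g, n_boot=20000, seed=2)
        true_mean = np.mean([d for _, d in g.degree()])
        assert abs(out["degree"].mean() - true_mean) / true_mean < 0.01

    def test_identical_graphs_ks_zero(self):
        g = nx.gnp_random_graph(40, 0.2, seed=4)
        a = bootstrap_node_attributes(g, n_boot=100, seed=5)
        b = bootstrap_node_attributes(g, n_boot=100, seed=5)
        res = ks_compare(a["degree"], b["degree"])
        assert res.D == pytest.approx(0.0)

    def test_ks_disjoint_supports(self):
        res = ks_compare([1, 2, 3], [10, 11, 12])
        assert res.D == pytest.approx(1.0)

    def test_ks_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])


class TestRemovalStability:
    def test_complete_graph_closure(self):
        """K10 minus any 5 nodes is K5, so average degree is exactly 4."""
        out = stability_after_removal(
            nx.complete_graph(10), fraction=0.5, n_replicates=50, seed=0
        )
        assert set(out["average_degree"]) == {4.0}

    def test_empty_graph_all_zero(self):
        out = stability_after_removal(
            nx.empty_graph(8), fraction=0.5, n_replicates=10, seed=0
        )
        assert set(out["average_degree"]) == {0.0}
        assert set(out["natural_connectivity"]) == {0.0}

    def test_density_separation_detected_by_ks(self):
        dense = nx.gnp_random_graph(100, 0.3, seed=1)
        sparse = nx.gnp_random_graph(100, 0.1, seed=2)
        a = stability_after_removal(dense, 0.5, n_replicates=200, seed=3)
        b = stability_after_removal(sparse, 0.5, n_replicates=200, seed=4)
        res = ks_compare(a["average_degree"], b["average_degree"])
        assert res.p < 1e-4

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            stability_after_removal(nx.complete_graph(5), fraction=1.5)


class TestRobustnessSweep:
    def test_complete_graph_closed_form(self):
        n = 12
        curve = robustness_sweep(
            nx.complete_graph(n), fractions=[0.0, 0.1, 0.25, 0.5, 0.75],
            n_replicates=5, seed=0,
        )
        for f in curve.fractions:
            k = n - int(np.floor(f * n))
            assert curve.mean.loc[f, "average_degree"] == pytest.approx(k - 1)

    def test_fraction_zero_is_intact_value(self):
        g = nx.gnp_random_graph(40, 0.2, seed=9)
        curve = robustness_sweep(g, fractions=[0.0, 0.3], n_replicates=10, seed=1)
        assert curve.mean.loc[0.0, "natural_connectivity"] == pytest.approx(
            natural_connectivity(g)
        )
        assert curve.sd.loc[0.0, "average_degree"] == pytest.approx(0.0, abs=1e-12)

    def test_mean_curves_non_increasing(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            g = nx.gnp_random_graph(40, rng.uniform(0.1, 0.4),
                                    seed=int(rng.integers(1e6)))
            curve = robustness_sweep(
                g, fractions=np.arange(0, 0.9, 0.2), n_replicates=40, seed=2
            )
            vals = curve.mean["average_degree"].to_numpy()
            assert np.all(np.diff(vals) <= 0.15 * max(1.0, vals[0]))


class TestDegreeClasses:
    @staticmethod
    def _hub_graph(hub, other, n_leaves=10, prefix="x"):
        g = nx.Graph()
        g.add_edges_from((hub, f"{prefix}{i}") for i in range(n_leaves))
        g.add_edge(other, f"{prefix}0")
        return g

    def test_identical_networks_fully_shared(self):
        g = nx.gnp_random_graph(30, 0.2, seed=5)
        dc = degree_class_partition(g, g.copy())
        assert dc.transitions == {}
        assert dc.summary.loc["high", "pct_shared"] == pytest.approx(100.0)

    def test_swapped_hubs_transition_both_ways(self):
        a = self._hub_graph("a", "b", prefix="xa_")
        b = self._hub_graph("b", "a", prefix="xb_")
        dc = degree_class_partition(a, b, high_q=0.9, low_q=0.1)
        assert dc.transitions["a"] == "high->low"
        assert dc.transitions["b"] == "low->high"
        assert dc.degree_pairs.loc["a", "degree_a"] == 10
        assert dc.degree_pairs.loc["a", "degree_b"] == 1

    def test_disjoint_node_sets_fully_specific(self):
        a = nx.relabel_nodes(nx.path_graph(6), lambda v: f"a{v}")
        b = nx.relabel_nodes(nx.path_graph(6), lambda v: f"b{v}")
        dc = degree_class_partition(a, b)
        assert dc.shared_nodes == set()
        assert dc.summary.loc["high", "pct_specific"] == pytest.approx(100.0)

    def test_collapsed_classes_rejected(self):
        g = nx.complete_graph(6)  # every degree identical
        with pytest.raises(ValueError, match="collapse"):
            degree_class_partition(g, g.copy())
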
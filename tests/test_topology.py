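"""Graph-metric conventions, merging, and power-law fitting."""

import numpy as np
import pytest

from interolink import (
    DegreeDistribution,
    InteractionNetwork,
    UndefinedFitError,
    betweenness_centrality,
    closeness_centrality,
    clustering_coefficient,
    degree_distribution,
    fit_power_law,
    generate_scale_free_graph,
    merge_networks,
    path_statistics,
    topological_coefficient,
)

from tests.conftest import adjacency, random_network
from tests._oracles import (
    betweenness_brute,
    closeness_brute,
    clustering_brute,
    path_stats_brute,
    topological_coeff_brute,
)


def _net(pairs):
    return InteractionNetwork.from_pairs(pairs, label="t")


PATH3 = _net([("a", "b"), ("b", "c")])
TRIANGLE = _net([("a", "b"), ("b", "c"), ("a", "c")])
STAR4 = _net([("hub", f"leaf{i}") for i in range(4)])
K4 = _net([(a, b) for i, a in enumerate("abcd") for b in "abcd"[i + 1 :]])
CYCLE4 = _net([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])


class TestMerge:
    def test_union_with_support_counts(self):
        n1 = InteractionNetwork.from_pairs([("a", "b"), ("b", "c")], "interolog")
        n2 = InteractionNetwork.from_pairs([("b", "c"), ("c", "d")], "dmist")
        n3 = InteractionNetwork.from_pairs([("a", "b")], "mmist")
        merged = merge_networks([n1, n2, n3])
        assert merged.edge_set() == {("a", "b"), ("b", "c"), ("c", "d")}
        assert merged.support("a", "b") == {"interolog", "mmist"}
        assert merged.support("b", "c") == {"interolog", "dmist"}
        assert merged.support("c", "d") == {"dmist"}

    def test_merge_idempotent(self):
        n1 = InteractionNetwork.from_pairs([("a", "b")], "interolog")
        merged = merge_networks([n1, n1, n1])
        assert merged.edge_set() == n1.edge_set()
        assert merged.support("a", "b") == {"interolog"}

    def test_inclusion_exclusion_on_random_networks(self, rng):
        nets = [random_network(rng, 15, 0.2) for _ in range(3)]
        sets = [n.edge_set() for n in nets]
        merged = merge_networks(nets)
        union = (
            sum(len(s) for s in sets)
            - len(sets[0] & sets[1])
            - len(sets[0] & sets[2])
            - len(sets[1] & sets[2])
            + len(sets[0] & sets[1] & sets[2])
        )
        assert merged.n_edges == union


class TestDegreeDistribution:
    @pytest.mark.parametrize(
        "net,expected",
        [(TRIANGLE, {2: 3}), (STAR4, {4: 1, 1: 4})],
    )
    def test_known_graphs(self, net, expected):
        assert degree_distribution(net).counts == expected

    def test_handshake_lemma_random(self, rng):
        net = random_network(rng, 20, 0.25)
        dist = degree_distribution(net)
        assert sum(k * n for k, n in dist.counts.items()) == 2 * net.n_edges
        assert dist.total_nodes == net.n_nodes


class TestPowerLawFit:
    def test_exact_k_minus_two_histogram(self):
        counts = {k: 256 // (k * k) for k in (1, 2, 4, 8, 16)}
        fit = fit_power_law(DegreeDistribution(counts))
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_uniform_distribution_zero_exponent(self):
        fit = fit_power_law(DegreeDistribution({k: 7 for k in range(1, 9)}))
        assert fit.exponent == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_planted_exponent_recovered(self, rng):
        ks = np.arange(1, 21)
        base = 1e6 * ks**-1.5
        noisy = np.maximum(1, np.round(base * rng.lognormal(0, 0.05, size=len(ks)))).astype(int)
        fit = fit_power_law(DegreeDistribution(dict(zip(ks.tolist(), noisy.tolist()))))
        assert fit.exponent == pytest.approx(1.5, abs=0.15)

    def test_single_point_is_undefined(self):
        with pytest.raises(UndefinedFitError):
            fit_power_law(DegreeDistribution({3: 10}))


class TestHandValues:
    def test_betweenness_path(self):
        cb = betweenness_centrality(PATH3)
        assert cb["b"] == pytest.approx(1.0)
        assert cb["a"] == cb["c"] == 0.0

    def test_betweenness_complete_graph_zero(self):
        assert all(v == 0.0 for v in betweenness_centrality(K4).values())

    def test_closeness_path_and_complete(self):
        cc = closeness_centrality(PATH3)
        assert cc["b"] == pytest.approx(1.0)
        assert cc["a"] == pytest.approx(2 / 3)
        k5 = _net([(a, b) for i, a in enumerate("abcde") for b in "abcde"[i + 1 :]])
        assert all(v == pytest.approx(1.0) for v in closeness_centrality(k5).values())

    def test_clustering_triangle_and_star(self):
        assert all(v == pytest.approx(1.0) for v in clustering_coefficient(TRIANGLE).values())
        assert clustering_coefficient(STAR4)["hub"] == 0.0

    def test_topological_coefficient_cycle_and_k3(self):
        assert topological_coefficient(CYCLE4)["a"] == pytest.approx(1.0)
        assert topological_coefficient(TRIANGLE)["a"] == pytest.approx(1.0)

    def test_path_statistics_path3(self):
        summary = path_statistics(PATH3)
        assert summary.diameter == 2
        assert summary.characteristic_path_length == pytest.approx(4 / 3)
        assert summary.connected_pair_fraction == pytest.approx(1.0)

    def test_path_statistics_two_disjoint_edges(self):
        summary = path_statistics(_net([("a", "b"), ("c", "d")]))
        assert summary.diameter == 1
        assert summary.connected_pair_fraction == pytest.approx(2 / 6)

    def test_centrality_ranges(self, rng):
        net = random_network(rng, 25, 0.15)
        for metric in (betweenness_centrality, closeness_centrality, clustering_coefficient):
            assert all(0.0 <= v <= 1.0 for v in metric(net).values())


class TestOracleEquivalence:
    """Spot equivalence on a handful of random graphs (the acceptance suite
    runs the full 200-graph sweep)."""

    @pytest.mark.parametrize("seed,n,p", [(0, 12, 0.2), (1, 18, 0.1), (2, 25, 0.3)])
    def test_all_metrics_match_bruteforce(self, seed, n, p):
        net = random_network(np.random.default_rng(seed), n, p)
        adj = adjacency(net)
        for ours, brute in (
            (betweenness_centrality(net), betweenness_brute(adj)),
            (closeness_centrality(net), closeness_brute(adj)),
            (clustering_coefficient(net), clustering_brute(adj)),
            (topological_coefficient(net), topological_coeff_brute(adj)),
        ):
            for node in adj:
                assert ours[node] == pytest.approx(brute[node], abs=1e-9)
        summary = path_statistics(net)
        expected = path_stats_brute(adj)
        assert summary.diameter == expected["diameter"]
        assert summary.radius == expected["radius"]
        assert summary.characteristic_path_length == pytest.approx(
            expected["characteristic_path_length"], abs=1e-9
        )
        assert summary.connected_pair_fraction == pytest.approx(
            expected["connected_pair_fraction"], abs=1e-9
        )
        assert summary.path_length_histogram == expected["histogram"]


class TestScaleFreeGenerator:
    def test_deterministic_per_seed_and_handshake(self):
        net1 = generate_scale_free_graph(100, 2.2, seed=5)
        net2 = generate_scale_free_graph(100, 2.2, seed=5)
        assert net1.edge_set() == net2.edge_set()
        dist = degree_distribution(net1)
        assert sum(k * n for k, n in dist.counts.items()) == 2 * net1.n_edges

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_scale_free_graph(5, 2.0)
        with pytest.raises(ValueError):
            generate_scale_free_graph(50, 0.9)
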
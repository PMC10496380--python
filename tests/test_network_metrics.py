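"""Statistics suite: degrees, density, paths, clustering, centralities,
power-law fit, ranking — checked against closed forms, a brute-force
geodesic-enumeration oracle, and networkx as an independent library."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from phytonet import (
    INGREDIENT,
    PATHWAY,
    Network,
    centralities,
    clustering,
    compute_metrics,
    degree_stats,
    density,
    distance_metrics,
    powerlaw_gamma,
    rank_key_nodes,
)
from conftest import oracle_centralities, oracle_clustering, random_network


def complete_graph(n, node_type=INGREDIENT):
    nodes = {f"v{i}": node_type for i in range(n)}
    edges = set(itertools.combinations(sorted(nodes), 2))
    return Network("K", nodes, edges)


def path_graph(labels=("a", "b", "c")):
    nodes = {x: INGREDIENT for x in labels}
    edges = {(labels[i], labels[i + 1]) for i in range(len(labels) - 1)}
    return Network("P", nodes, edges)


class TestDegreeStats:
    def test_average_degree_is_2e_over_n(self, rng):
        net = random_network(rng, 30, 0.3)
        deg, avg, pk = degree_stats(net)
        assert avg == pytest.approx(2 * net.n_edges / net.n_nodes)
        assert sum(deg.values()) == 2 * net.n_edges
        assert sum(pk.values()) == pytest.approx(1.0)

    def test_complete_graph_all_degree_5(self):
        deg, avg, pk = degree_stats(complete_graph(6))
        assert set(deg.values()) == {5} and avg == 5 and pk == {5: pytest.approx(1.0)}

    def test_isolated_node(self):
        net = Network("X", {"a": INGREDIENT}, set())
        deg, avg, pk = degree_stats(net)
        assert deg == {"a": 0} and avg == 0 and pk == {0: pytest.approx(1.0)}

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            degree_stats(Network("X", {}, set()))


class TestDensity:
    def test_complete_graph_density_1(self):
        assert density(complete_graph(6)) == 1.0

    def test_bipartite_density(self):
        net = Network(
            "IPB",
            {"i1": INGREDIENT, "i2": INGREDIENT, "p1": PATHWAY, "p2": PATHWAY, "p3": PATHWAY},
            {("i1", "p1"), ("i1", "p2"), ("i2", "p3")},
        )
        assert density(net, "bipartite") == pytest.approx(3 / 6)

    def test_bipartite_mode_rejects_monopartite_edge(self):
        net = Network("X", {"i1": INGREDIENT, "i2": INGREDIENT, "p1": PATHWAY}, {("i1", "i2")})
        with pytest.raises(ValueError):
            density(net, "bipartite")


class TestDistanceMetrics:
    def test_complete_graph(self):
        avg_l, diam, _ = distance_metrics(complete_graph(6))
        assert avg_l == 1.0 and diam == 1

    def test_path_graph(self):
        avg_l, diam, dists = distance_metrics(path_graph())
        assert avg_l == pytest.approx(4 / 3)
        assert diam == 2 and dists["a"]["c"] == 2

    def test_diameter2_closed_form(self, rng):
        # in a diameter-2 graph L = 2 - 2E/(N(N-1)) exactly
        n = 40
        net = random_network(rng, n, 0.5)
        hub = "n00"
        edges = set(net.edges) | {(hub, v) for v in net.nodes if v != hub}
        net = Network("H", net.node_types, {tuple(sorted(e)) for e in edges})
        avg_l, diam, _ = distance_metrics(net)
        assert diam == 2
        assert avg_l == pytest.approx(2 - 2 * net.n_edges / (n * (n - 1)))

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            distance_metrics(Network("X", {"a": INGREDIENT, "b": INGREDIENT}, set()))

    def test_disconnected_averages_within_components(self):
        net = Network(
            "X",
            {x: INGREDIENT for x in "abcd"},
            {("a", "b"), ("c", "d")},
        )
        avg_l, diam, _ = distance_metrics(net)
        assert avg_l == 1.0 and diam == 1


class TestClustering:
    def test_triangle(self):
        ci, avg, spectrum = clustering(complete_graph(3))
        assert set(ci.values()) == {1.0} and avg == 1.0 and spectrum == {2: 1.0}

    def test_path_center_zero(self):
        ci, _, _ = clustering(path_graph())
        assert ci["b"] == 0.0 and ci["a"] == 0.0

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(20):
            net = random_network(rng, int(rng.integers(3, 15)), rng.uniform(0.2, 0.9))
            expected = oracle_clustering(net)
            ci, avg, _ = clustering(net)
            assert ci == pytest.approx(expected)
            assert avg == pytest.approx(sum(expected.values()) / len(expected))


class TestCentralities:
    def test_path_middle_betweenness(self):
        cent = centralities(path_graph())
        assert cent["b"][1] == pytest.approx(1.0)  # normalized
        assert cent["b"][2] == pytest.approx(1.0)  # raw: the single (a,c) pair
        assert cent["a"][1] == 0.0

    def test_complete_graph_extremes(self):
        cent = centralities(complete_graph(8))
        for c_d, c_b, _raw, c_c in cent.values():
            assert c_d == 1.0 and c_b == 0.0 and c_c == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            net = random_network(rng, int(rng.integers(3, 13)), rng.uniform(0.15, 0.9))
            oracle = oracle_centralities(net)
            cent = centralities(net)
            for v in net.nodes:
                assert cent[v][0] == pytest.approx(oracle[v][0], abs=1e-12)
                assert cent[v][1] == pytest.approx(oracle[v][1], abs=1e-9)
                assert cent[v][3] == pytest.approx(oracle[v][2], abs=1e-12)

    def test_matches_networkx(self, rng):
        for _ in range(15):
            net = random_network(rng, int(rng.integers(3, 20)), rng.uniform(0.1, 0.8))
            G = nx.Graph()
            G.add_nodes_from(net.nodes)
            G.add_edges_from(net.edges)
            cent = centralities(net)
            nb = nx.betweenness_centrality(G, normalized=True)
            ncl = nx.closeness_centrality(G, wf_improved=True)
            for v in net.nodes:
                assert cent[v][1] == pytest.approx(nb[v], abs=1e-9)
                assert cent[v][3] == pytest.approx(ncl[v], abs=1e-12)

    def test_isolated_node_closeness_zero(self):
        net = Network("X", {"a": INGREDIENT, "b": INGREDIENT, "c": INGREDIENT}, {("a", "b")})
        assert centralities(net)["c"][3] == 0.0


class TestPowerlawGamma:
    def test_exact_recovery_noise_free(self):
        spectrum = {k: k**-0.95 for k in range(72, 91)}
        assert powerlaw_gamma(spectrum, k_min=72) == pytest.approx(-0.95, abs=1e-9)

    def test_constant_spectrum_slope_zero(self):
        assert powerlaw_gamma({k: 0.5 for k in range(5, 20)}) == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_exponent_with_noise(self, rng):
        gamma = -1.3
        estimates = []
        for _ in range(20):
            spectrum = {
                k: k**gamma * (1 + rng.uniform(-0.02, 0.02)) for k in range(10, 101)
            }
            estimates.append(powerlaw_gamma(spectrum, k_min=10))
        assert np.mean(estimates) == pytest.approx(gamma, abs=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            powerlaw_gamma({80: 0.5}, k_min=72)


class TestRankKeyNodes:
    def test_hub_ranks_first_by_degree(self):
        pathways = {f"p{c:02d}": PATHWAY for c in range(5)}
        nodes = {"hub": INGREDIENT, "minor": INGREDIENT, **pathways}
        edges = {("hub", p) for p in pathways} | {("minor", "p00")}
        report = compute_metrics(Network("IPB", nodes, edges))
        order = rank_key_nodes(report, by="degree")
        assert order[0] == "hub"
        assert report.per_node["hub"].degree == 5

    def test_all_equal_falls_back_to_lexicographic(self):
        report = compute_metrics(complete_graph(5))
        for by in ("degree", "C_d", "C_b", "C_c", "composite"):
            assert rank_key_nodes(report, by=by) == sorted(report.per_node)

    def test_order_consistent_with_sorted_values(self, rng):
        net = random_network(rng, 12, 0.4)
        report = compute_metrics(net)
        order = rank_key_nodes(report, by="C_c")
        values = [report.per_node[v].closeness for v in order]
        assert values == sorted(values, reverse=True)

    def test_unknown_index_rejected(self):
        with pytest.raises(ValueError):
            rank_key_nodes(compute_metrics(complete_graph(4)), by="pagerank")


class TestComputeMetrics:
    def test_report_invariants(self, rng):
        net = random_network(rng, 25, 0.3)
        report = compute_metrics(net)
        assert set(report.per_node) == set(net.nodes)
        assert sum(report.degree_distribution.values()) == pytest.approx(1.0)
        assert report.avg_degree == pytest.approx(2 * net.n_edges / net.n_nodes)
        assert 0 <= report.density <= 1
        for m in report.per_node.values():
            assert 0 <= m.degree_centrality <= 1
            assert 0 <= m.betweenness <= 1
            assert 0 <= m.closeness <= 1
        if not math.isnan(report.avg_path_length):
            assert 1 <= report.avg_path_length <= report.diameter

    def test_powerlaw_skipped_with_warning_when_unfittable(self):
        report = compute_metrics(path_graph(), k_min=50)
        assert report.powerlaw_gamma is None
        assert any("power-law" in w for w in report.warnings)
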
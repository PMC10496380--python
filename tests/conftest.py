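"""Shared fixtures and independent oracles for the test suite.

The oracle functions deliberately avoid the package's algorithms:
distances come from Floyd-Warshall, geodesics are enumerated explicitly as
path lists, and centralities are assembled from those enumerations, so
they can arbitrate the package's BFS/Brandes implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from phytonet.network_build import Network


def random_network(rng: np.random.Generator, n: int, p: float, node_type: str = "ingredient") -> Network:
    nodes = {f"n{i:02d}": node_type for i in range(n)}
    edges = {
        (f"n{i:02d}", f"n{j:02d}")
        for i, j in itertools.combinations(range(n), 2)
        if rng.random() < p
    }
    return Network("random", nodes, edges)


def floyd_warshall(net: Network) -> dict[str, dict[str, float]]:
    nodes = net.nodes
    dist = {u: {v: (0 if u == v else float("inf")) for v in nodes} for u in nodes}
    for u, v in net.edges:
        dist[u][v] = dist[v][u] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return dist


def enumerate_geodesics(net: Network, dist=None) -> dict[tuple[str, str], list[tuple[str, ...]]]:
    """All shortest paths between every ordered pair, as explicit node
    tuples, built by backward recursion on Floyd-Warshall distances."""
    if dist is None:
        dist = floyd_warshall(net)
    adj = net.adjacency()
    paths: dict[tuple[str, str], list[tuple[str, ...]]] = {}

    def build(source: str, target: str) -> list[tuple[str, ...]]:
        if source == target:
            return [(source,)]
        key = (source, target)
        if key not in paths:
            result = []
            for mid in adj[target]:
                if dist[source][mid] == dist[source][target] - 1:
                    result.extend(p + (target,) for p in build(source, mid))
            paths[key] = result
        return paths[key]

    for s in net.nodes:
        for t in net.nodes:
            if s != t and dist[s][t] != float("inf"):
                build(s, t)
    return paths


def oracle_centralities(net: Network) -> dict[str, tuple[float, float, float]]:
    """(C_d, C_b normalized, C_c Wasserman-Faust) per node from explicit
    geodesic enumeration."""
    nodes = net.nodes
    n = len(nodes)
    dist = floyd_warshall(net)
    geodesics = enumerate_geodesics(net, dist)
    deg = net.degrees()
    out = {}
    for v in nodes:
        c_d = deg[v] / (n - 1)
        raw = 0.0
        for j, k in itertools.combinations([u for u in nodes if u != v], 2):
            g = geodesics.get((j, k), [])
            if g:
                raw += sum(1 for p in g if v in p[1:-1]) / len(g)
        c_b = raw / ((n - 1) * (n - 2) / 2) if n > 2 else 0.0
        finite = [dist[v][u] for u in nodes if u != v and dist[v][u] != float("inf")]
        if finite:
            r = len(finite)
            c_c = (r / sum(finite)) * (r / (n - 1))
        else:
            c_c = 0.0
        out[v] = (c_d, c_b, c_c)
    return out


def oracle_clustering(net: Network) -> dict[str, float]:
    adj = net.adjacency()
    out = {}
    for v, neigh in adj.items():
        k = len(neigh)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(sorted(neigh), 2) if net.has_edge(a, b))
        out[v] = 2 * links / (k * (k - 1))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
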
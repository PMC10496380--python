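"""Graph statistics for the interaction networks.

Implements the standard descriptive suite for undirected simple graphs:
degree statistics and degree distribution P(k), density (simple and
bipartite), shortest-path statistics (average path length L and diameter D
by breadth-first search), local clustering coefficients C_i = 2 e_i /
(k_i (k_i - 1)) with the clustering spectrum C(k), degree / betweenness /
closeness centralities, a log-log least-squares power-law fit of the
clustering spectrum (C(k) ~ k^gamma), and deterministic key-node ranking.

Conventions for disconnected graphs: L averages the finite distances
(ordered pairs within components), D is the largest finite distance, and
closeness uses the Wasserman-Faust correction — the raw closeness over
reachable nodes scaled by (number reachable)/(N-1) — so components of
different sizes stay comparable.  Betweenness uses Brandes' accumulation
and is reported both raw (sum over unordered pairs of the pair-dependency)
and normalized by (N-1)(N-2)/2 so it lies in [0, 1].
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .network_build import INGREDIENT, PATHWAY, Network

__all__ = [
    "NodeMetrics",
    "MetricsReport",
    "degree_stats",
    "density",
    "distance_metrics",
    "clustering",
    "centralities",
    "powerlaw_gamma",
    "rank_key_nodes",
    "compute_metrics",
]


@dataclass(frozen=True)
class NodeMetrics:
    degree: int
    clustering: float
    degree_centrality: float
    betweenness: float
    betweenness_raw: float
    closeness: float


@dataclass
class MetricsReport:
    """Per-network and per-node statistics."""

    network_name: str
    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    avg_path_length: float
    diameter: float
    avg_clustering: float
    avg_degree_centrality: float
    avg_betweenness: float
    avg_closeness: float
    per_node: dict[str, NodeMetrics]
    degree_distribution: dict[int, float]
    clustering_spectrum: dict[int, float]
    powerlaw_gamma: float | None = None
    bipartite_density: float | None = None
    warnings: list[str] = field(default_factory=list)


def degree_stats(net: Network) -> tuple[dict[str, int], float, dict[int, float]]:
    """Per-node degrees, average degree <k> = 2E/N, and P(k)."""
    if net.n_nodes == 0:
        raise ValueError("degree statistics undefined for an empty network")
    deg = net.degrees()
    n = net.n_nodes
    avg = sum(deg.values()) / n
    dist: dict[int, float] = {}
    for k in deg.values():
        dist[k] = dist.get(k, 0.0) + 1.0 / n
    return deg, avg, dict(sorted(dist.items()))


def density(net: Network, mode: str = "simple") -> float:
    """Edge density: 2E/(N(N-1)) for simple graphs, E/(n_ingredient *
    n_pathway) for bipartite ingredient-pathway graphs."""
    if mode == "simple":
        if net.n_nodes < 2:
            raise ValueError("simple density needs at least 2 nodes")
        return 2.0 * net.n_edges / (net.n_nodes * (net.n_nodes - 1))
    if mode == "bipartite":
        n_ing = sum(1 for t in net.node_types.values() if t == INGREDIENT)
        n_path = sum(1 for t in net.node_types.values() if t == PATHWAY)
        if n_ing == 0 or n_path == 0:
            raise ValueError("bipartite density needs both node parts non-empty")
        for u, v in net.edges:
            if net.node_types[u] == net.node_types[v]:
                raise ValueError("bipartite density on a non-bipartite network")
        return net.n_edges / (n_ing * n_path)
    raise ValueError(f"unknown density mode {mode!r}")


def _bfs_distances(adj: Mapping[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def distance_metrics(net: Network) -> tuple[float, int, dict[str, dict[str, int]]]:
    """Average path length L, diameter D, and all finite pairwise distances.

    L averages d_ij over ordered pairs i != j within connected components;
    D is the largest finite distance.  A network with no edges has no
    finite distances and raises ``ValueError``.
    """
    if net.n_nodes < 2:
        raise ValueError("path statistics need at least 2 nodes")
    if net.n_edges == 0:
        raise ValueError("path statistics undefined: network has no edges")
    adj = net.adjacency()
    all_dists: dict[str, dict[str, int]] = {}
    total = 0
    pairs = 0
    diameter = 0
    for source in net.nodes:
        dist = _bfs_distances(adj, source)
        all_dists[source] = dist
        for target, d in dist.items():
            if target != source:
                total += d
                pairs += 1
                if d > diameter:
                    diameter = d
    return total / pairs, diameter, all_dists


def clustering(net: Network) -> tuple[dict[str, float], float, dict[int, float]]:
    """Local clustering C_i = 2 e_i / (k_i (k_i - 1)) (0 when k_i < 2),
    the network average C, and the spectrum C(k) = mean C_i at degree k."""
    adj = net.adjacency()
    per_node: dict[str, float] = {}
    for node, neigh in adj.items():
        k = len(neigh)
        if k < 2:
            per_node[node] = 0.0
            continue
        ordered = sorted(neigh)
        e_i = sum(
            1
            for a_idx, a in enumerate(ordered)
            for b in ordered[a_idx + 1 :]
            if b in adj[a]
        )
        per_node[node] = 2.0 * e_i / (k * (k - 1))
    avg = sum(per_node.values()) / len(per_node) if per_node else 0.0
    by_degree: dict[int, list[float]] = {}
    for node, c in per_node.items():
        by_degree.setdefault(len(adj[node]), []).append(c)
    spectrum = {k: sum(vals) / len(vals) for k, vals in sorted(by_degree.items())}
    return per_node, avg, spectrum


def _brandes_betweenness(adj: Mapping[str, set[str]], nodes: list[str]) -> dict[str, float]:
    """Raw betweenness: for each node i, the sum over unordered pairs
    {j, k} (j, k != i) of g_jk(i)/g_jk (Brandes' dependency accumulation)."""
    betw = {v: 0.0 for v in nodes}
    for s in nodes:
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in nodes}
        sigma = {v: 0.0 for v in nodes}
        sigma[s] = 1.0
        dist = {v: -1 for v in nodes}
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {v: 0.0 for v in nodes}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                betw[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: b / 2.0 for v, b in betw.items()}


def centralities(
    net: Network,
) -> dict[str, tuple[float, float, float, float]]:
    """Per-node (C_d, C_b normalized, C_b raw, C_c).

    C_d = k_i/(N-1); C_b raw sums g_jk(i)/g_jk over unordered pairs not
    containing i, normalized by (N-1)(N-2)/2; C_c is Wasserman-Faust
    closeness (0 for isolated nodes).
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("centralities need at least 2 nodes")
    adj = net.adjacency()
    nodes = net.nodes
    deg = {v: len(adj[v]) for v in nodes}
    raw_betw = _brandes_betweenness(adj, nodes)
    betw_scale = (n - 1) * (n - 2) / 2.0
    result = {}
    for v in nodes:
        c_d = deg[v] / (n - 1)
        c_b_raw = raw_betw[v]
        c_b = c_b_raw / betw_scale if betw_scale > 0 else 0.0
        dist = _bfs_distances(adj, v)
        reachable = len(dist) - 1
        if reachable == 0:
            c_c = 0.0
        else:
            total = sum(dist.values())
            c_c = (reachable / total) * (reachable / (n - 1))
        result[v] = (c_d, c_b, c_b_raw, c_c)
    return result


def powerlaw_gamma(
    spectrum: Mapping[int, float],
    k_min: int = 1,
) -> float:
    """Exponent gamma of C(k) ~ k^gamma by ordinary least squares on the
    log-log spectrum restricted to k >= k_min with C(k) > 0."""
    pts = [(k, c) for k, c in spectrum.items() if k >= k_min and c > 0]
    if len(pts) < 2:
        raise ValueError(
            f"power-law fit needs >= 2 spectrum points with k >= {k_min} and C(k) > 0, "
            f"got {len(pts)}"
        )
    log_k = np.log([k for k, _ in pts])
    log_c = np.log([c for _, c in pts])
    slope, _intercept = np.polyfit(log_k, log_c, 1)
    return float(slope)


_RANK_KEYS = ("degree", "C_d", "C_b", "C_c", "composite")


def rank_key_nodes(report: MetricsReport, by: str = "degree") -> list[str]:
    """Node ids in descending order of the chosen importance index.

    ``composite`` is the mean of min-max-scaled C_d, C_b and C_c. Ties are
    broken lexicographically by node id so reports are reproducible.
    """
    if by not in _RANK_KEYS:
        raise ValueError(f"unknown ranking index {by!r}; choose from {_RANK_KEYS}")
    pn = report.per_node
    if by == "degree":
        score = {v: float(m.degree) for v, m in pn.items()}
    elif by == "C_d":
        score = {v: m.degree_centrality for v, m in pn.items()}
    elif by == "C_b":
        score = {v: m.betweenness for v, m in pn.items()}
    elif by == "C_c":
        score = {v: m.closeness for v, m in pn.items()}
    else:
        def scaled(values: dict[str, float]) -> dict[str, float]:
            lo, hi = min(values.values()), max(values.values())
            if math.isclose(lo, hi):
                return {v: 0.0 for v in values}
            return {v: (x - lo) / (hi - lo) for v, x in values.items()}

        c_d = scaled({v: m.degree_centrality for v, m in pn.items()})
        c_b = scaled({v: m.betweenness for v, m in pn.items()})
        c_c = scaled({v: m.closeness for v, m in pn.items()})
        score = {v: (c_d[v] + c_b[v] + c_c[v]) / 3.0 for v in pn}
    return sorted(pn, key=lambda v: (-score[v], v))


def compute_metrics(
    net: Network,
    k_min: int | None = None,
    node_filter: Iterable[str] | None = None,
) -> MetricsReport:
    """Full statistics report for one network.

    ``k_min`` enables the power-law fit of the clustering spectrum on
    degrees >= k_min (skipped with a warning when too few points qualify).
    ``node_filter`` restricts the per-node averages in the header block to
    a subset of nodes (all nodes by default); per_node always covers every
    node.
    """
    warnings: list[str] = []
    deg, avg_deg, p_k = degree_stats(net)
    dens = density(net, "simple") if net.n_nodes >= 2 else 0.0
    try:
        bip_dens = density(net, "bipartite")
    except ValueError:
        bip_dens = None
    if net.n_edges > 0 and net.n_nodes >= 2:
        avg_l, diam, _ = distance_metrics(net)
    else:
        avg_l, diam = float("nan"), 0
        warnings.append("no finite path lengths (edgeless network)")
    c_i, avg_c, spectrum = clustering(net)
    if net.n_nodes >= 2:
        cent = centralities(net)
    else:
        cent = {v: (0.0, 0.0, 0.0, 0.0) for v in net.nodes}
    per_node = {
        v: NodeMetrics(
            degree=deg[v],
            clustering=c_i[v],
            degree_centrality=cent[v][0],
            betweenness=cent[v][1],
            betweenness_raw=cent[v][2],
            closeness=cent[v][3],
        )
        for v in net.nodes
    }
    gamma: float | None = None
    if k_min is not None:
        try:
            gamma = powerlaw_gamma(spectrum, k_min)
        except ValueError as exc:
            warnings.append(str(exc))
    focus = list(node_filter) if node_filter is not None else net.nodes
    n_focus = max(len(focus), 1)
    return MetricsReport(
        network_name=net.name,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        avg_degree=avg_deg,
        density=dens,
        avg_path_length=avg_l,
        diameter=diam,
        avg_clustering=avg_c,
        avg_degree_centrality=sum(per_node[v].degree_centrality for v in focus) / n_focus,
        avg_betweenness=sum(per_node[v].betweenness for v in focus) / n_focus,
        avg_closeness=sum(per_node[v].closeness for v in focus) / n_focus,
        per_node=per_node,
        degree_distribution=p_k,
        clustering_spectrum=spectrum,
        powerlaw_gamma=gamma,
        bipartite_density=bip_dens,
        warnings=warnings,
    )
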
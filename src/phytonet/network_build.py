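"""Construction of ingredient-target-pathway interaction networks.

From two annotation relations — ingredient -> target proteins (e.g. SEA
predictions) and target -> pathways (e.g. DAVID/KEGG enrichment) — four
undirected simple graphs are built by shared-target rules:

* TTI: ingredient-ingredient; edge when two ingredients share >= 1 target.
* IPB: bipartite ingredient-pathway; edge when some target of the
  ingredient is annotated to the pathway.
* PPI: pathway-pathway; edge when two pathways share >= 1 target
  (a pathway-level projection, not protein-protein interaction).
* IPI: the merged network over ingredient and pathway nodes carrying all
  three edge classes; the subnetworks are exactly its restrictions by
  node-type signature, so |E(IPI)| = |E(TTI)| + |E(IPB)| + |E(PPI)|.

Target proteins never appear as nodes; they only induce edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Set

logger = logging.getLogger(__name__)

__all__ = [
    "INGREDIENT",
    "PATHWAY",
    "Network",
    "build_tti",
    "build_ipb",
    "build_ppi",
    "build_ipi",
    "prune_isolated",
]

INGREDIENT = "ingredient"
PATHWAY = "pathway"

#: ingredient id -> set of target ids (UniProt-style)
IngredientTargetMap = Mapping[str, Set[str]]
#: target id -> set of pathway ids (KEGG-style, e.g. "hsa05208")
TargetPathwayMap = Mapping[str, Set[str]]


def _edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u < v else (v, u)


@dataclass
class Network:
    """A labelled, typed-node, undirected simple graph.

    Edges are stored as sorted id pairs; self-loops and duplicate edges are
    rejected at construction.
    """

    name: str
    node_types: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r} in network {self.name!r}")
            if u not in self.node_types or v not in self.node_types:
                raise ValueError(f"edge ({u!r}, {v!r}) references undeclared node")
        self.edges = {_edge(u, v) for u, v in self.edges}

    @property
    def nodes(self) -> list[str]:
        """Node ids in lexicographic order (the canonical report order)."""
        return sorted(self.node_types)

    @property
    def n_nodes(self) -> int:
        return len(self.node_types)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return _edge(u, v) in self.edges

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {node: set() for node in self.node_types}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def degrees(self) -> dict[str, int]:
        adj = self.adjacency()
        return {node: len(neigh) for node, neigh in adj.items()}


def _check_itm(itm: IngredientTargetMap) -> None:
    if not itm:
        raise ValueError("ingredient->target map is empty")


def build_tti(itm: IngredientTargetMap) -> Network:
    """Ingredient-ingredient network: edge iff the two target sets intersect."""
    _check_itm(itm)
    node_types = {i: INGREDIENT for i in itm}
    edges = {
        _edge(i1, i2)
        for i1, i2 in combinations(sorted(itm), 2)
        if itm[i1] & itm[i2]
    }
    net = Network("TTI", node_types, edges)
    logger.info("TTI network: %d nodes, %d edges", net.n_nodes, net.n_edges)
    return net


def _warn_unmapped(itm: IngredientTargetMap, tpm: TargetPathwayMap) -> None:
    unmapped = set().union(*itm.values()) - set(tpm) if itm else set()
    if unmapped:
        logger.warning(
            "%d target(s) have no pathway annotation and contribute no "
            "ingredient-pathway edges: %s",
            len(unmapped),
            ", ".join(sorted(unmapped)[:10]) + ("..." if len(unmapped) > 10 else ""),
        )


def build_ipb(itm: IngredientTargetMap, tpm: TargetPathwayMap) -> Network:
    """Bipartite ingredient-pathway network: edge iff some target of the
    ingredient is annotated to the pathway.  Targets absent from the
    pathway map are tolerated (they simply contribute nothing)."""
    _check_itm(itm)
    _warn_unmapped(itm, tpm)
    node_types = {i: INGREDIENT for i in itm}
    node_types.update({p: PATHWAY for pathways in tpm.values() for p in pathways})
    edges = set()
    for ingredient, targets in itm.items():
        for target in targets:
            for pathway in tpm.get(target, ()):
                edges.add(_edge(ingredient, pathway))
    net = Network("IPB", node_types, edges)
    logger.info("IPB network: %d nodes, %d edges", net.n_nodes, net.n_edges)
    return net


def build_ppi(tpm: TargetPathwayMap) -> Network:
    """Pathway-pathway network: union over targets of the clique on each
    target's pathway set (edge iff two pathways share >= 1 target)."""
    if not tpm:
        raise ValueError("target->pathway map is empty")
    node_types = {p: PATHWAY for pathways in tpm.values() for p in pathways}
    edges = set()
    for pathways in tpm.values():
        for p1, p2 in combinations(sorted(pathways), 2):
            edges.add(_edge(p1, p2))
    net = Network("PPI", node_types, edges)
    logger.info("PPI network: %d nodes, %d edges", net.n_nodes, net.n_edges)
    return net


def build_ipi(itm: IngredientTargetMap, tpm: TargetPathwayMap) -> Network:
    """Merged ingredient-pathway interaction network: ingredient and pathway
    nodes with the union of TTI, IPB and PPI edges (disjoint classes by
    node-type signature)."""
    tti = build_tti(itm)
    node_types = dict(tti.node_types)
    edges = set(tti.edges)
    if tpm:
        ipb = build_ipb(itm, tpm)
        ppi = build_ppi(tpm)
        node_types.update(ipb.node_types)
        node_types.update(ppi.node_types)
        edges |= ipb.edges | ppi.edges
    net = Network("IPI", node_types, edges)
    logger.info("IPI network: %d nodes, %d edges", net.n_nodes, net.n_edges)
    return net


def prune_isolated(net: Network) -> Network:
    """Copy of the network without degree-0 nodes (off by default in the
    pipeline so published node budgets stay auditable)."""
    deg = net.degrees()
    kept = {node: t for node, t in net.node_types.items() if deg[node] > 0}
    dropped = net.n_nodes - len(kept)
    if dropped:
        logger.info("pruned %d isolated node(s) from %s", dropped, net.name)
    return Network(net.name, kept, set(net.edges))
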
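"""Shared-target network construction rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytonet import (
    INGREDIENT,
    PATHWAY,
    Network,
    build_ipb,
    build_ipi,
    build_ppi,
    build_tti,
    prune_isolated,
)


def random_maps(rng, n_ing=5, n_tgt=12, n_pw=8, p_it=0.3, p_tp=0.25):
    itm = {
        f"i{a}": {f"t{b}" for b in range(n_tgt) if rng.random() < p_it}
        for a in range(n_ing)
    }
    tpm = {
        f"t{b}": pws
        for b in range(n_tgt)
        if (pws := {f"p{c}" for c in range(n_pw) if rng.random() < p_tp})
    }
    return itm, tpm


class TestBuildTTI:
    def test_all_pairs_sharing_gives_complete_graph(self):
        itm = {f"i{a}": {"t_common", f"t{a}"} for a in range(6)}
        net = build_tti(itm)
        assert net.n_nodes == 6 and net.n_edges == 15
        assert all(k == 5 for k in net.degrees().values())

    def test_disjoint_targets_give_no_edges(self):
        net = build_tti({"i1": {"t1"}, "i2": {"t2"}})
        assert net.n_nodes == 2 and net.n_edges == 0

    def test_matches_bruteforce_pairwise_intersection(self, rng):
        itm, _ = random_maps(rng)
        net = build_tti(itm)
        for i1, i2 in itertools.combinations(sorted(itm), 2):
            assert net.has_edge(i1, i2) == bool(itm[i1] & itm[i2])

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            build_tti({})


class TestBuildIPB:
    def test_full_coverage_gives_degree_n_pathways(self):
        pathways = {f"p{c}" for c in range(90)}
        itm = {"hub": {"t1"}, "other": {"t2"}}
        tpm = {"t1": set(pathways), "t2": {"p0"}}
        net = build_ipb(itm, tpm)
        assert net.degrees()["hub"] == 90

    def test_single_edge(self):
        net = build_ipb({"i1": {"t1"}}, {"t1": {"p1"}})
        assert net.edges == {("i1", "p1")}
        assert net.node_types == {"i1": INGREDIENT, "p1": PATHWAY}

    def test_matches_bruteforce_double_loop(self, rng):
        itm, tpm = random_maps(rng, n_ing=4, n_pw=8)
        net = build_ipb(itm, tpm)
        pathways = set().union(*tpm.values())
        for i in itm:
            for p in pathways:
                expected = any(p in tpm.get(t, set()) for t in itm[i])
                assert net.has_edge(i, p) == expected

    def test_unmapped_targets_tolerated(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            net = build_ipb({"i1": {"t1", "t_orphan"}}, {"t1": {"p1"}})
        assert net.n_edges == 1
        assert "no pathway annotation" in caplog.text


class TestBuildPPI:
    def test_single_target_clique(self):
        net = build_ppi({"t1": {"a", "b", "c"}})
        assert net.n_edges == 3 and net.n_nodes == 3

    def test_disjoint_targets_disconnected_cliques(self):
        net = build_ppi({"t1": {"a", "b"}, "t2": {"c", "d", "e"}})
        assert net.n_edges == 1 + 3
        assert not net.has_edge("a", "c")

    def test_equals_union_of_cliques_bruteforce(self, rng):
        _, tpm = random_maps(rng, n_tgt=20, n_pw=10, p_tp=0.3)
        if not tpm:
            pytest.skip("empty draw")
        net = build_ppi(tpm)
        expected = set()
        for pws in tpm.values():
            for a, b in itertools.combinations(sorted(pws), 2):
                expected.add((a, b))
        assert net.edges == expected


class TestBuildIPI:
    def test_node_count_is_ingredients_plus_pathways(self, rng):
        itm, tpm = random_maps(rng)
        net = build_ipi(itm, tpm)
        pathways = set().union(*tpm.values())
        assert net.n_nodes == len(itm) + len(pathways)

    def test_empty_tpm_reduces_to_tti(self):
        itm = {"i1": {"t1"}, "i2": {"t1"}}
        net = build_ipi(itm, {})
        assert net.edges == build_tti(itm).edges

    def test_subnetworks_are_type_restrictions(self, rng):
        itm, tpm = random_maps(rng)
        ipi = build_ipi(itm, tpm)
        tti, ipb, ppi = build_tti(itm), build_ipb(itm, tpm), build_ppi(tpm)
        by_sig = {("ingredient", "ingredient"): set(), ("ingredient", "pathway"): set(),
                  ("pathway", "pathway"): set()}
        for u, v in ipi.edges:
            sig = tuple(sorted((ipi.node_types[u], ipi.node_types[v])))
            by_sig[sig].add((u, v))
        assert by_sig[("ingredient", "ingredient")] == tti.edges
        assert by_sig[("ingredient", "pathway")] == ipb.edges
        assert by_sig[("pathway", "pathway")] == ppi.edges


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_edge_additivity_property(seed):
    """|E(IPI)| = |E(TTI)| + |E(IPB)| + |E(PPI)| on random mappings."""
    rng = np.random.default_rng(seed)
    itm, tpm = random_maps(rng)
    if not tpm:
        tpm = {"t0": {"p0"}}
    ipi = build_ipi(itm, tpm)
    total = build_tti(itm).n_edges + build_ipb(itm, tpm).n_edges + build_ppi(tpm).n_edges
    assert ipi.n_edges == total


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), tgt=st.integers(0, 11), pw=st.integers(0, 7))
def test_adding_annotation_never_removes_edges(seed, tgt, pw):
    rng = np.random.default_rng(seed)
    itm, tpm = random_maps(rng)
    if not tpm:
        tpm = {"t0": {"p0"}}
    before = {
        "TTI": build_tti(itm).edges,
        "IPB": build_ipb(itm, tpm).edges,
        "PPI": build_ppi(tpm).edges,
        "IPI": build_ipi(itm, tpm).edges,
    }
    tpm2 = {t: set(p) for t, p in tpm.items()}
    tpm2.setdefault(f"t{tgt}", set()).add(f"p{pw}")
    itm2 = {i: set(t) | {f"t{tgt}"} if i == sorted(itm)[0] else set(t) for i, t in itm.items()}
    after = {
        "TTI": build_tti(itm2).edges,
        "IPB": build_ipb(itm2, tpm2).edges,
        "PPI": build_ppi(tpm2).edges,
        "IPI": build_ipi(itm2, tpm2).edges,
    }
    for name in before:
        assert before[name] <= after[name], name


class TestNetworkInvariants:
    def test_rejects_self_loop(self):
        with pytest.raises(ValueError):
            Network("X", {"a": INGREDIENT}, {("a", "a")})

    def test_rejects_undeclared_endpoint(self):
        with pytest.raises(ValueError):
            Network("X", {"a": INGREDIENT}, {("a", "b")})

    def test_edges_canonicalized(self):
        net = Network("X", {"a": INGREDIENT, "b": INGREDIENT}, {("b", "a")})
        assert net.edges == {("a", "b")}

    def test_prune_isolated(self):
        net = Network(
            "X",
            {"a": INGREDIENT, "b": INGREDIENT, "c": PATHWAY},
            {("a", "b")},
        )
        pruned = prune_isolated(net)
        assert set(pruned.node_types) == {"a", "b"}
        assert pruned.edges == net.edges
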
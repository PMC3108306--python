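"""Pedigree-graph construction: vertices, edges, clauses, forced colors."""

from __future__ import annotations

import json

from pedphase.graph import (
    GREEN,
    GREY,
    RED,
    add_trio_edges,
    build_member_vertices,
    build_pedigree_graph,
    size_bounds_ok,
    to_dot,
    to_json_dict,
)
from pedphase.pedigree import Genotype, Member
from pedphase.simulate import SimulationSpec, simulate_pedigree
from tests.conftest import pedigree_from_rows


def member(geno: str, mid: str = "u") -> Member:
    return Member(mid, None, None, "unknown", Genotype([int(c) for c in geno]))


class TestMemberVertices:
    def test_mixed_genotype_builds_colored_chain(self):
        verts = {v.vid[1:]: v for v in build_member_vertices(member("01122"))}
        assert verts[(1, 2)].color == RED  # homozygous pair 0 vs 1
        assert verts[(2, 3)].color == GREEN  # homozygous pair 1 vs 1
        assert verts[(4, 5)].color == GREY  # heterozygous pair
        assert set(verts) == {(1, 2), (2, 3), (4, 5)}

    def test_all_homozygous_equal(self):
        verts = build_member_vertices(member("000"))
        assert [(v.vid[1:], v.color) for v in verts] == [((1, 2), GREEN), ((2, 3), GREEN)]

    def test_single_site_has_no_pairs(self):
        assert build_member_vertices(member("2")) == []

    def test_nonadjacent_chains_skip_other_kind(self):
        # het sites 1,4 chain over the homozygous gap; hom sites 2,3
        verts = {v.vid[1:]: v.origin for v in build_member_vertices(member("2002"))}
        assert verts == {(1, 4): "primary_het", (2, 3): "primary_hom"}


class TestTrioConstruction:
    def test_matching_het_pairs_get_positive_edge(self):
        p = pedigree_from_rows("F f 0 0 1 22\nF m 0 0 2 00\nF c f m 1 22\n")
        g, _ = build_pedigree_graph(p)
        pos = [e for e in g.edges if e.sign > 0 and e.relation == "parent_child"]
        assert {(e.u[0], e.v[0]) for e in pos} == {("f", "c")}
        assert all(e.sites == (1, 2) for e in pos)

    def test_mixed_child_pair_routes_through_transmitted_allele(self):
        # child het at 1, hom(1) at 2: father's (1,2) vertex constrained via D
        p = pedigree_from_rows("F f 0 0 1 22\nF m 0 0 2 21\nF c f m 1 21\n")
        g, sets = build_pedigree_graph(p)
        trans = [e for e in g.edges if e.relation == "transmission"]
        assert trans, "expected transmitted-allele edges"
        # child hom allele is 1 at site 2 -> negative sign
        assert {e.sign for e in trans} == {-1}
        kinds = {c.kind for c in sets}
        assert "transmitted_allele" in kinds

    def test_hom_parent_pins_routing(self):
        p = pedigree_from_rows("F f 0 0 1 11\nF m 0 0 2 22\nF c f m 1 22\n")
        _, sets = build_pedigree_graph(p)
        pins = [c for c in sets if c.kind == "routing_pin"]
        # father hom(1) at both child-het sites
        assert len(pins) == 2 and all(c.offset == 1 for c in pins)

    def test_idempotent_under_reapplication(self):
        p = pedigree_from_rows("F f 0 0 1 222\nF m 0 0 2 202\nF c f m 1 221\n")
        g, _ = build_pedigree_graph(p)
        n_v, n_e, n_c = g.n_vertices, g.n_edges, len(g.clauses)
        assert not add_trio_edges(g, p.trios[0], p, 0)
        assert (g.n_vertices, g.n_edges, len(g.clauses)) == (n_v, n_e, n_c)

    def test_construction_deterministic(self, corpus):
        for item in corpus[:6]:
            g1, s1 = build_pedigree_graph(item.pedigree)
            g2, s2 = build_pedigree_graph(item.pedigree)
            assert json.dumps(to_json_dict(g1, s1), sort_keys=True) == json.dumps(
                to_json_dict(g2, s2), sort_keys=True
            )

    def test_no_intra_member_edges(self, corpus):
        for item in corpus[:10]:
            g, _ = build_pedigree_graph(item.pedigree)
            assert all(e.u[0] != e.v[0] for e in g.edges)
            assert all(e.u[1:] != () for e in g.edges)


class TestForcedColors:
    def test_hom_hom_parent_forces_child_pair(self):
        # father hom at both sites of the child's het pair: flip pinned
        p = pedigree_from_rows("F f 0 0 1 01\nF m 0 0 2 22\nF c f m 1 22\n")
        g, _ = build_pedigree_graph(p)
        assert g.vertex(("c", 1, 2)).color == RED  # alleles 0 then 1: flip

    def test_pinning_through_both_mixed_parents(self):
        # father hom at site 1, mother hom at site 2: child pair still pinned
        p = pedigree_from_rows("F f 0 0 1 02\nF m 0 0 2 20\nF c f m 1 22\n")
        g, _ = build_pedigree_graph(p)
        # hap from father: 0 at site 1, complement of mother's 0 -> 1 at site 2
        assert g.vertex(("c", 1, 2)).color == RED

    def test_hom_child_never_forces_het_parent(self):
        p = pedigree_from_rows("F f 0 0 1 22\nF m 0 0 2 22\nF c f m 1 01\n")
        g, _ = build_pedigree_graph(p)
        assert g.vertex(("f", 1, 2)).color == GREY
        assert g.vertex(("m", 1, 2)).color == GREY

    def test_graph_without_trios_unchanged(self):
        p = pedigree_from_rows("F u 0 0 1 2202\n")
        g, sets = build_pedigree_graph(p)
        assert all(v.color == GREY or v.origin == "primary_hom" for v in g.vertices.values())
        assert g.n_edges == 0 and sets == []


class TestParitySets:
    def test_supplementary_anchor_collects_chain(self):
        # father's consecutive het pair (1,3) spans child's chain (1,2),(2,3)
        p = pedigree_from_rows("F f 0 0 1 202\nF m 0 0 2 200\nF c f m 1 222\n")
        g, sets = build_pedigree_graph(p)
        chains = [s for s in sets if s.kind == "member_chain" and s.member_id == "c"]
        assert len(chains) == 1
        assert chains[0].vertex_ids == frozenset(
            {("c", 1, 3), ("c", 1, 2), ("c", 2, 3)}
        )
        assert chains[0].offset == 0

    def test_member_without_supplementary_has_no_chain_sets(self):
        p = pedigree_from_rows("F f 0 0 1 22\nF m 0 0 2 00\nF c f m 1 22\n")
        _, sets = build_pedigree_graph(p)
        assert [s for s in sets if s.kind == "member_chain"] == []


class TestSizeBounds:
    def test_observation_bound_on_random_pedigrees(self):
        for seed in range(100):
            spec = SimulationSpec(
                n_founder_couples=1 + seed % 3,
                children_per_couple=1 + seed % 2,
                generations=1 + seed % 2,
                m=2 + seed % 5,
                planted_recombinations=seed % 3,
                seed=seed,
                allow_loops=seed % 4 == 0,
            )
            p, _ = simulate_pedigree(spec)
            g, _ = build_pedigree_graph(p)
            assert size_bounds_ok(g, p.n, p.m), (
                f"seed {seed}: |V|={g.n_vertices} |E|={g.n_edges} vs 3*{p.n}*{p.m}^2"
            )


def test_dot_export_mentions_every_vertex():
    p = pedigree_from_rows("F f 0 0 1 22\nF m 0 0 2 00\nF c f m 1 22\n")
    g, _ = build_pedigree_graph(p)
    dot = to_dot(g)
    for vid in g.vertices:
        assert f"{vid[0]}:{vid[1]}-{vid[2]}" in dot
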
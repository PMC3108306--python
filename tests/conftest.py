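"""Shared fixtures: hand-built pedigrees and the simulated study corpus."""

from __future__ import annotations

import networkx as nx
import pytest

from pedphase.gber import GberInstance, ParityClause
from pedphase.pedigree import Pedigree, parse_pedigree
from pedphase.simulate import acceptance_corpus

CORPUS_SEED = 20260926


def pedigree_from_rows(rows: str) -> Pedigree:
    """Compact-dialect pedigree from an inline string."""
    return parse_pedigree(rows, dialect="compact")


@pytest.fixture
def trio_k1() -> Pedigree:
    """Father 22, mother 00, children 20 and 22: minimum is exactly one
    recombination (the father transmits incompatible phase patterns)."""
    return pedigree_from_rows(
        """
        F f 0 0 1 22
        F m 0 0 2 00
        F c1 f m 1 20
        F c2 f m 2 22
        """
    )


@pytest.fixture
def trio_k0() -> Pedigree:
    return pedigree_from_rows(
        """
        F f 0 0 1 20
        F m 0 0 2 02
        F c f m 1 22
        """
    )


@pytest.fixture(scope="session")
def corpus():
    """Deterministic study corpus shared by the correctness suites."""
    return acceptance_corpus(CORPUS_SEED, size=60)


def make_gber(graph: nx.MultiGraph, budget: int, clauses=()) -> GberInstance:
    """Wrap a raw multigraph as a GBER instance with anchor gadget."""
    g = nx.MultiGraph()
    g.add_nodes_from(graph.nodes)
    for u, v, k in graph.edges(keys=True):
        g.add_edge(u, v, key=k, weight=1, origin=None)
    ra, ga = "anchor:red", "anchor:green"
    g.add_node(ra)
    g.add_node(ga)
    for _ in range(budget + 1):
        g.add_edge(ra, ga, weight=1, origin="anchor_gadget")
    return GberInstance(
        graph=g,
        budget=budget,
        parity_sets=[ParityClause(None, frozenset(c[0]), c[1]) for c in clauses],
        anchors=(ra, ga),
        site_vertices=frozenset(graph.nodes),
    )


def gber_minimum(graph: nx.MultiGraph, clauses=(), max_budget=None, mode="exhaustive_fallback"):
    """Smallest feasible budget for a raw multigraph, or None."""
    from pedphase.gber import solve_gber

    cap = graph.number_of_edges() if max_budget is None else max_budget
    for budget in range(cap + 1):
        res = solve_gber(make_gber(graph, budget, clauses), mode=mode)
        if res.feasible:
            return res.cost
    return None
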
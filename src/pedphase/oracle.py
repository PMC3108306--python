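"""Independent brute-force reference implementations.

Every stage of the solver pipeline is validated against an exhaustive
enumeration in this module.  The enumerations here deliberately share no
code with the graph construction or the GBER solver (they only reuse the
elementary recombination-counting primitive from :mod:`pedphase.pedigree`,
which is itself specified exhaustively), so agreement between the two
routes is meaningful evidence of correctness.

All operations refuse inputs beyond :class:`OracleLimits` to guard
against accidental exponential blow-ups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from pedphase._flow import FlowNetwork
from pedphase.pedigree import (
    HaplotypeConfiguration,
    HaplotypePair,
    Pedigree,
    count_recombinations,
)

__all__ = [
    "OracleLimits",
    "OracleLimitError",
    "brute_force_min_recombination",
    "brute_force_bipartization",
    "enumerate_all_mincuts",
]


class OracleLimitError(ValueError):
    """Input exceeds the enumeration guard."""


@dataclass(frozen=True)
class OracleLimits:
    max_members: int = 8
    max_sites: int = 8
    max_het_sites_total: int = 18
    max_vertices: int = 16
    max_edges: int = 48


DEFAULT_LIMITS = OracleLimits()


def _member_phasings(member) -> list[HaplotypePair]:
    """All phase assignments of one member modulo the h1/h2 swap.

    The first heterozygous site is anchored to allele 0 on h1, leaving
    2^(h-1) assignments for h heterozygous sites (one for h = 0).
    """
    g = member.genotype
    het = [i for i, c in enumerate(g) if c == 2]
    base = [c if c != 2 else None for c in g]
    if not het:
        h = tuple(base)
        return [HaplotypePair(h, h)]
    out = []
    for rest in itertools.product((0, 1), repeat=len(het) - 1):
        alleles = dict(zip(het, (0,) + rest))
        h1 = tuple(alleles[i] if b is None else b for i, b in enumerate(base))
        h2 = tuple(1 - alleles[i] if b is None else b for i, b in enumerate(base))
        out.append(HaplotypePair(h1, h2))
    return out


def brute_force_min_recombination(
    p: Pedigree, limits: OracleLimits = DEFAULT_LIMITS
) -> tuple[int, HaplotypeConfiguration]:
    """Global minimum recombination count by exhaustive phase enumeration.

    Enumerates the cartesian product of per-member phasings (members in
    file order) and scores each joint assignment with
    :func:`pedphase.pedigree.count_recombinations`.  Partial assignments
    whose completed-trio cost already reaches the incumbent are pruned,
    which changes nothing about exactness.
    """
    if p.n > limits.max_members:
        raise OracleLimitError(f"{p.n} members exceeds limit {limits.max_members}")
    if p.m > limits.max_sites:
        raise OracleLimitError(f"{p.m} sites exceeds limit {limits.max_sites}")
    total_het = sum(len(mem.genotype.heterozygous_sites()) for mem in p.members)
    if total_het > limits.max_het_sites_total:
        raise OracleLimitError(
            f"{total_het} heterozygous sites exceeds limit {limits.max_het_sites_total}"
        )

    order = [mem.member_id for mem in p.members]
    choices = {mem.member_id: _member_phasings(mem) for mem in p.members}
    # trios become scoreable once the last of their three members is assigned
    rank = {mid: idx for idx, mid in enumerate(order)}
    ready_at: dict[int, list] = {i: [] for i in range(len(order))}
    for trio in p.trios:
        ready_at[max(rank[trio.father], rank[trio.mother], rank[trio.child])].append(trio)

    from pedphase.pedigree import _transmission_cost  # elementary shared primitive

    def trio_cost(trio, phases) -> int | None:
        child = phases[trio.child]
        best = None
        for hap_f, hap_m in ((child.h1, child.h2), (child.h2, child.h1)):
            rf = _transmission_cost(phases[trio.father], hap_f)
            rm = _transmission_cost(phases[trio.mother], hap_m)
            if rf is None or rm is None:
                continue
            cost = rf[0] + rm[0]
            if best is None or cost < best:
                best = cost
        return best

    best_cost: list = [None]
    best_phases: list = [None]
    phases: dict[str, HaplotypePair] = {}

    def recurse(idx: int, cost_so_far: int) -> None:
        if idx == len(order):
            if best_cost[0] is None or cost_so_far < best_cost[0]:
                best_cost[0] = cost_so_far
                best_phases[0] = dict(phases)
            return
        mid = order[idx]
        for pair in choices[mid]:
            phases[mid] = pair
            extra = 0
            infeasible = False
            for trio in ready_at[idx]:
                c = trio_cost(trio, phases)
                if c is None:
                    infeasible = True
                    break
                extra += c
            if not infeasible:
                new_cost = cost_so_far + extra
                if best_cost[0] is None or new_cost < best_cost[0]:
                    recurse(idx + 1, new_cost)
            del phases[mid]

    recurse(0, 0)
    assert best_phases[0] is not None, "some joint phasing is always Mendelian-feasible"
    k, events = count_recombinations(p, best_phases[0])
    return k, HaplotypeConfiguration(best_phases[0], events, k)


def brute_force_bipartization(
    graph,
    parity_sets=None,
    red_anchor=None,
    limits: OracleLimits = DEFAULT_LIMITS,
) -> int | None:
    """Minimum monochromatic-edge count over all 2-colorings.

    ``graph`` is an undirected (multi)graph with networkx interface.
    When ``parity_sets`` is given, colorings are restricted to those where
    every set has an even number of vertices on the side of
    ``red_anchor`` (plus the set's fixed offset).  Returns ``None`` when
    no coloring satisfies the parity restriction.
    """
    nodes = sorted(graph.nodes, key=repr)
    if len(nodes) > limits.max_vertices:
        raise OracleLimitError(f"{len(nodes)} vertices exceeds {limits.max_vertices}")
    if graph.number_of_edges() > limits.max_edges:
        raise OracleLimitError("edge count exceeds limit")
    edges = [(u, v) for u, v, _ in graph.edges(keys=True)] if graph.is_multigraph() \
        else list(graph.edges())
    idx = {v: i for i, v in enumerate(nodes)}
    best = None
    for bits in itertools.product((0, 1), repeat=max(len(nodes) - 1, 0)):
        color = (0,) + bits
        cost = sum(1 for u, v in edges if color[idx[u]] == color[idx[v]])
        if best is not None and cost >= best:
            continue
        if parity_sets:
            ra = color[idx[red_anchor]] if red_anchor is not None else 0
            ok = True
            for ps in parity_sets:
                members = getattr(ps, "vertex_ids", None) or getattr(ps, "vertices")
                offset = getattr(ps, "offset", 0)
                reds = sum(1 for v in members if v in idx and color[idx[v]] == ra)
                if (reds + offset) % 2 != 0:
                    ok = False
                    break
            if not ok:
                continue
        best = cost
        if best == 0 and not parity_sets:
            break
    return best


def enumerate_all_mincuts(
    net: FlowNetwork, limits: OracleLimits = DEFAULT_LIMITS
) -> set[frozenset]:
    """All minimum s-t cuts, as the set of their source-side vertex sets.

    Evaluates every s-t vertex bipartition directly; exponential by
    design and guarded by ``limits``.
    """
    nodes = [v for v in net.nodes if v not in (net.source, net.sink)]
    if len(nodes) + 2 > limits.max_vertices:
        raise OracleLimitError("flow network exceeds vertex limit")
    best_value = None
    best: set[frozenset] = set()
    for r in range(len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            side = frozenset((net.source,) + combo)
            value = net.cut_value(side)
            if best_value is None or value < best_value - 1e-9:
                best_value, best = value, {side}
            elif abs(value - best_value) <= 1e-9:
                best.add(side)
    return best
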
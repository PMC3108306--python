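"""Line-index evaluation and transformation to an all-positive GBER instance.

The *line index* of a signed graph is the minimum, over bipartitions
``(V1, V2)``, of the number of positive edges crossing the cut plus
negative edges inside a part.  For the pedigree graph, restricted to
partitions that respect resolved vertex colors and the parity-constraint
sets, the line index equals the minimum recombination count.

The solver pipeline transforms the signed pedigree graph in four steps:

1. every positive edge is replaced by two consecutive negative edges
   through a fresh *dum* vertex (line index preserved);
2. edges joining two resolved vertices are folded into a constant
   (same-colored endpoints of a negative edge cost one unavoidable
   recombination each);
3. all red vertices are merged into one anchor, all green into another,
   and ``k + 1`` parallel negative edges pin the anchors apart;
4. all weights are negated, leaving a unit-weight multigraph in which
   deleting at most ``budget`` edges must make the graph bipartite —
   Graph Bipartization by Edge Removal with parity constraints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from pedphase.gber import GberInstance, ParityClause
from pedphase.graph import (
    GREEN,
    GREY,
    RED,
    ParityConstraintSet,
    PedigreeGraph,
    SignedEdge,
)

RED_ANCHOR = "anchor:red"
GREEN_ANCHOR = "anchor:green"

__all__ = [
    "Partition",
    "TransformedGraph",
    "line_index_of_partition",
    "brute_force_line_index",
    "parity_restricted_line_index",
    "positive_to_negative",
    "fold_constant_costs",
    "merge_resolved",
    "to_gber_instance",
    "build_gber_instance",
    "RED_ANCHOR",
    "GREEN_ANCHOR",
]

Partition = dict  # vertex id -> "V1" | "V2"


def _signed_edge_list(g) -> tuple[list, list[tuple[object, object, int]]]:
    """Normalize a PedigreeGraph or a weighted networkx (multi)graph to
    (nodes, [(u, v, sign)])."""
    if isinstance(g, PedigreeGraph):
        return list(g.vertices), [(e.u, e.v, e.sign) for e in g.edges]
    edges = [
        (u, v, int(data.get("weight", 1)))
        for u, v, data in g.edges(data=True)
    ]
    return list(g.nodes), edges


def line_index_of_partition(g, part: Partition) -> int:
    """Positive edges across the cut plus negative edges within a part."""
    nodes, edges = _signed_edge_list(g)
    missing = [v for v in nodes if v not in part]
    if missing:
        raise ValueError(f"partition is not total; missing {missing[:3]}")
    cost = 0
    for u, v, sign in edges:
        crossing = part[u] != part[v]
        if (sign > 0 and crossing) or (sign < 0 and not crossing):
            cost += 1
    return cost


def brute_force_line_index(g, max_vertices: int = 20) -> int:
    """Minimum of :func:`line_index_of_partition` over all bipartitions.

    One side of the first vertex is fixed by symmetry; guarded to small
    graphs (2^(|V|-1) evaluations).
    """
    nodes, edges = _signed_edge_list(g)
    if len(nodes) > max_vertices:
        raise ValueError(f"{len(nodes)} vertices exceeds brute-force guard {max_vertices}")
    if not nodes:
        return 0
    idx = {v: i for i, v in enumerate(nodes)}
    best = None
    for bits in itertools.product((0, 1), repeat=len(nodes) - 1):
        side = (0,) + bits
        cost = 0
        for u, v, sign in edges:
            crossing = side[idx[u]] != side[idx[v]]
            if (sign > 0 and crossing) or (sign < 0 and not crossing):
                cost += 1
                if best is not None and cost >= best:
                    break
        else:
            if best is None or cost < best:
                best = cost
        if best == 0:
            break
    return best if best is not None else 0


def parity_restricted_line_index(
    g: PedigreeGraph,
    parity_sets: list[ParityConstraintSet],
    max_free_bits: int = 22,
) -> int | None:
    """Exact line index restricted to colorings fixing resolved vertices
    and satisfying every hard parity clause.

    The clauses form a GF(2) linear system over the grey vertices;
    Gaussian reduction parametrizes the feasible colorings by the free
    bits that remain (member phase chains and unpinned routing bits),
    and the edge costs of all ``2^r`` assignments are evaluated with
    vectorized bit arithmetic.  Returns ``None`` when the clauses are
    inconsistent (cannot occur for graphs built from Mendelian-consistent
    pedigrees).  Independent of the GBER solver route.
    """
    import numpy as np

    vids = sorted(g.vertices)
    greys = [v for v in vids if g.vertex(v).color == GREY]
    gidx = {v: i for i, v in enumerate(greys)}
    const_color = {
        v: 1 if g.vertex(v).color == RED else 0 for v in vids if v not in gidx
    }

    # reduced row echelon form of the clause system over grey bits
    pivots: dict[int, tuple[int, int]] = {}
    for ps in parity_sets:
        mask, rhs = 0, ps.offset % 2
        for v in ps.vertex_ids:
            if v in gidx:
                mask ^= 1 << gidx[v]
            else:
                rhs ^= const_color[v]
        for b, (pm, pr) in list(pivots.items()):
            if mask >> b & 1:
                mask ^= pm
                rhs ^= pr
        if mask == 0:
            if rhs:
                return None
            continue
        b = mask.bit_length() - 1
        for ob, (om, orh) in list(pivots.items()):
            if om >> b & 1:
                pivots[ob] = (om ^ mask, orh ^ rhs)
        pivots[b] = (mask, rhs)

    free = [i for i in range(len(greys)) if i not in pivots]
    if len(free) > max_free_bits:
        raise ValueError(
            f"{len(free)} free phase bits exceed the enumeration guard {max_free_bits}"
        )
    fpos = {b: k for k, b in enumerate(free)}
    forms: list[tuple[int, int]] = [None] * len(greys)  # (free-bit mask, const)
    for i in range(len(greys)):
        if i in pivots:
            mask, rhs = pivots[i]
            fmask = 0
            for b in free:
                if mask >> b & 1:
                    fmask |= 1 << fpos[b]
            forms[i] = (fmask, rhs)
        else:
            forms[i] = (1 << fpos[i], 0)

    n_assign = 1 << len(free)
    idx = np.arange(n_assign, dtype=np.uint64)

    def color_of(v):
        if v in gidx:
            fmask, c = forms[gidx[v]]
            if fmask == 0:
                return c
            return (np.bitwise_count(idx & np.uint64(fmask)).astype(np.uint8) & 1) ^ c
        return const_color[v]

    cost = np.zeros(n_assign, dtype=np.int32)
    const_cost = 0
    for e in g.edges:
        cu, cv = color_of(e.u), color_of(e.v)
        diff = cu ^ cv
        viol = diff if e.sign > 0 else 1 ^ diff
        if isinstance(viol, (int, np.integer)):
            const_cost += int(viol)
        else:
            cost += viol
    return int(cost.min()) + const_cost


# ---------------------------------------------------------------------------
# transformation pipeline


@dataclass
class TransformedGraph:
    """All-negative multigraph en route to a GBER instance.

    ``graph`` edge data carries ``weight`` (-1 until the final negation)
    and ``origin`` (the generating :class:`SignedEdge`, or a synthetic
    role string).  ``colors`` snapshots vertex colors at transform time;
    ``baseline_cost`` accumulates recombinations forced regardless of the
    partition; ``budget`` is set by :func:`merge_resolved`.
    """

    graph: nx.MultiGraph
    colors: dict
    parity_sets: list[ParityConstraintSet]
    site_vertices: frozenset
    baseline_cost: int = 0
    forced_edges: list = field(default_factory=list)
    budget: int | None = None
    anchors: tuple | None = None
    gber_parity: list = field(default_factory=list)


def positive_to_negative(
    g: PedigreeGraph, parity_sets: list[ParityConstraintSet] | None = None
) -> TransformedGraph:
    """Replace each positive edge by two negative edges through a fresh
    *dum* vertex; line index is invariant under this rewrite."""
    parity_sets = list(parity_sets or [])
    ng = nx.MultiGraph()
    for vid in g.vertices:
        ng.add_node(vid)
    for e in sorted(g.edges, key=SignedEdge.sort_key):
        if e.sign < 0:
            ng.add_edge(e.u, e.v, weight=-1, origin=e)
        else:
            dum = ("dum", e.edge_id)
            ng.add_edge(e.u, dum, weight=-1, origin=e, half=0)
            ng.add_edge(dum, e.v, weight=-1, origin=e, half=1)
    colors = {vid: v.color for vid, v in g.vertices.items()}
    return TransformedGraph(
        graph=ng,
        colors=colors,
        parity_sets=parity_sets,
        site_vertices=frozenset(g.vertices),
    )


def fold_constant_costs(tg: TransformedGraph) -> TransformedGraph:
    """Remove edges joining two resolved vertices.

    Such an edge's contribution does not depend on the partition: a
    negative edge inside one color class is an unavoidable recombination
    (baseline_cost += 1); between classes it is satisfied for free.
    Folding before the merge avoids self-loops at the anchors.
    """

    def resolved(v) -> bool:
        return tg.colors.get(v) in (RED, GREEN)

    doomed = []
    for u, v, key, data in tg.graph.edges(keys=True, data=True):
        if resolved(u) and resolved(v):
            doomed.append((u, v, key, data))
    for u, v, key, data in sorted(doomed, key=lambda t: t[3]["origin"].edge_id):
        if tg.colors[u] == tg.colors[v]:
            tg.baseline_cost += 1
            tg.forced_edges.append(data["origin"])
        tg.graph.remove_edge(u, v, key)
    return tg


def merge_resolved(tg: TransformedGraph, k: int) -> TransformedGraph:
    """Identify all red vertices into one anchor and all green into the
    other, re-attach incident edges, relabel the anchors grey, and insert
    ``k + 1`` parallel negative edges pinning them to opposite sides.

    Parity sets are carried over with merged-away resolved members
    replaced by their fixed red-count contribution (an offset mod 2).
    """
    g = tg.graph
    g.add_node(RED_ANCHOR)
    g.add_node(GREEN_ANCHOR)
    anchor_of = {RED: RED_ANCHOR, GREEN: GREEN_ANCHOR}
    for vid in sorted((v for v, c in tg.colors.items() if c in anchor_of), key=repr):
        target = anchor_of[tg.colors[vid]]
        for _, nbr, key, data in sorted(
            g.edges(vid, keys=True, data=True), key=lambda t: repr(t)
        ):
            if nbr == vid:
                raise RuntimeError("self-loop on a resolved vertex; fold first")
            g.add_edge(target, nbr, **data)
        g.remove_node(vid)
    for _ in range(k + 1):
        g.add_edge(RED_ANCHOR, GREEN_ANCHOR, weight=-1, origin="anchor_gadget")
    tg.anchors = (RED_ANCHOR, GREEN_ANCHOR)
    tg.budget = k - tg.baseline_cost
    tg.gber_parity = []
    for ps in tg.parity_sets:
        greys = frozenset(v for v in ps.vertex_ids if tg.colors.get(v) == GREY)
        reds = sum(1 for v in ps.vertex_ids if tg.colors.get(v) == RED)
        tg.gber_parity.append(
            ParityClause(ps.member_id, greys, (ps.offset + reds) % 2)
        )
    return tg


def to_gber_instance(tg: TransformedGraph) -> GberInstance:
    """Negate all weights: the all-negative line-index problem becomes
    unit-weight Graph Bipartization by Edge Removal."""
    if tg.budget is None or tg.anchors is None:
        raise ValueError("merge_resolved must run before to_gber_instance")
    for _, _, data in tg.graph.edges(data=True):
        data["weight"] = 1
    return GberInstance(
        graph=tg.graph,
        budget=tg.budget,
        parity_sets=tg.gber_parity,
        anchors=tg.anchors,
        baseline_cost=tg.baseline_cost,
        forced_edges=list(tg.forced_edges),
        site_vertices=tg.site_vertices,
        resolved_colors={v: c for v, c in tg.colors.items() if c in (RED, GREEN)},
    )


def build_gber_instance(
    g: PedigreeGraph, parity_sets: list[ParityConstraintSet], k: int
) -> GberInstance | None:
    """Full transformation for budget ``k``; ``None`` when the folded
    baseline alone already exceeds ``k``."""
    tg = fold_constant_costs(positive_to_negative(g, parity_sets))
    if tg.baseline_cost > k:
        return None
    return to_gber_instance(merge_resolved(tg, k))
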
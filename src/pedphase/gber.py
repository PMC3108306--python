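"""Graph Bipartization by Edge Removal with parity constraints.

Given a unit-weight multigraph, a budget ``k`` and parity-constraint
sets, find at most ``k`` edges whose removal leaves a bipartite graph
admitting a proper 2-coloring in which every parity set has an even
number of vertices on the red-anchor side (plus its fixed offset).

The solver uses *iterative compression*: edges are added one at a time
in deterministic order while a minimum parity-feasible bipartization set
``X`` is maintained.  When ``X`` stops working, ``X' = X ∪ {e}`` is
compressed: each edge of ``X'`` is subdivided into three so a smaller
solution may be assumed disjoint from ``X'``, all ``2^{k'}`` valid
partitions Φ of the subdivision endpoints are enumerated, and for each Φ
a minimum ``A_Φ``–``B_Φ`` edge cut is sought with Edmonds-Karp.  All
minimum cuts of that value are explored through the Picard-Queyranne
closure structure of the residual graph (strongly connected components
condensed into a DAG; every successor-closed choice of free components
is a minimum cut), and each candidate removal set is tested for parity
feasibility exactly, via a GF(2) linear system over per-component color
flips.

The mincut-only search is the fixed-parameter route; the exhaustive
fallback mode re-checks failed compressions with a complete
branch-and-bound, so any gap between "no parity-feasible *minimum* cut"
and "no parity-feasible cut at all" is both closed and reported.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from pedphase._flow import FlowNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ParityClause",
    "GberInstance",
    "BipartizationResult",
    "FlowNetwork",
    "ClosureDAG",
    "parity_feasible_coloring",
    "max_flow_min_cut",
    "build_closure_dag",
    "parity_feasible_closure",
    "compress",
    "solve_gber",
    "exact_bipartization_search",
]

MODES = ("paper_faithful", "exhaustive_fallback")


@dataclass(frozen=True)
class ParityClause:
    """Even-red-count constraint over ``vertices`` with a fixed offset
    contributed by merged-away resolved vertices."""

    member_id: str | None
    vertices: frozenset
    offset: int = 0


@dataclass
class GberInstance:
    graph: nx.MultiGraph  # unit weights; edge attr "origin"
    budget: int
    parity_sets: list[ParityClause] = field(default_factory=list)
    anchors: tuple | None = None  # (red anchor, green anchor)
    baseline_cost: int = 0
    forced_edges: list = field(default_factory=list)
    site_vertices: frozenset = frozenset()
    resolved_colors: dict = field(default_factory=dict)  # merged-away vertices

    @property
    def red_anchor(self):
        return self.anchors[0] if self.anchors else None


@dataclass
class BipartizationResult:
    feasible: bool
    removed_edges: list  # (u, v, key) in instance graph
    coloring: dict  # node -> "A" | "B"
    cost: int
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# parity feasibility of a fixed removal set (GF(2) over component flips)


def _bipartite_coloring(graph: nx.MultiGraph, removed: set) -> tuple[dict, list, list | None]:
    """BFS 2-coloring of ``graph`` minus ``removed`` edge keys.

    Returns (base coloring, list of components as node lists, odd cycle
    as a list of edge keys or None).  Deterministic: nodes scanned in
    insertion order, neighbors in sorted order.
    """
    color: dict = {}
    comps: list[list] = []
    parent_edge: dict = {}
    for start in graph.nodes:
        if start in color:
            continue
        comp = [start]
        color[start] = 0
        parent_edge[start] = None
        queue = deque([start])
        while queue:
            u = queue.popleft()
            nbrs = sorted(graph.adj[u].items(), key=lambda t: repr(t[0]))
            for v, keydict in nbrs:
                live = [k for k in sorted(keydict) if (u, v, k) not in removed
                        and (v, u, k) not in removed]
                if not live:
                    continue
                if v not in color:
                    color[v] = 1 - color[u]
                    parent_edge[v] = (u, v, live[0])
                    comp.append(v)
                    queue.append(v)
                elif color[v] == color[u]:
                    # reconstruct the odd cycle through the BFS tree
                    def path_to_root(x):
                        out = []
                        while parent_edge[x] is not None:
                            pu, pv, pk = parent_edge[x]
                            out.append((pu, pv, pk))
                            x = pu
                        return out
                    pu_path, pv_path = path_to_root(u), path_to_root(v)
                    common = set(pu_path) & set(pv_path)
                    cycle = [e for e in pu_path if e not in common]
                    cycle += [e for e in pv_path if e not in common]
                    cycle.append((u, v, live[0]))
                    return color, comps, cycle
        comps.append(comp)
    return color, comps, None


def _solve_gf2(rows: list[int], consts: list[int], n_vars: int) -> list[int] | None:
    """Solve a GF(2) linear system given as bitmask rows; any solution."""
    system = [(r, c) for r, c in zip(rows, consts)]
    pivots: list[tuple[int, int, int]] = []  # (var bit, row, const)
    for row, const in system:
        for bit, prow, pconst in pivots:
            if row >> bit & 1:
                row ^= prow
                const ^= pconst
        if row == 0:
            if const:
                return None
            continue
        bit = row.bit_length() - 1
        pivots.append((bit, row, const))
    solution = [0] * n_vars
    # each pivot row's non-pivot bits are strictly smaller, so ascending
    # pivot order resolves dependencies (free variables default to 0)
    for bit, row, const in sorted(pivots):
        acc = const
        for other in range(bit):
            if row >> other & 1:
                acc ^= solution[other]
        solution[bit] = acc
    return solution


def parity_feasible_coloring(
    graph: nx.MultiGraph,
    clauses: list[ParityClause],
    red_anchor,
    removed=(),
) -> dict | None:
    """A proper 2-coloring of ``graph`` minus ``removed`` satisfying all
    parity clauses, or ``None``.

    Exact for the given removal set: the per-component color flips form
    GF(2) variables and each clause one linear equation, since a vertex
    is red iff its color equals the red anchor's.
    """
    removed = {(u, v, k) for (u, v, k) in removed}
    base, comps, odd = _bipartite_coloring(graph, removed)
    if odd is not None:
        return None
    comp_of = {}
    for ci, comp in enumerate(comps):
        for v in comp:
            comp_of[v] = ci
    flips = [0] * len(comps)
    if clauses:
        if red_anchor is None or red_anchor not in comp_of:
            raise ValueError("parity clauses require a red anchor present in the graph")
        ra_comp = comp_of[red_anchor]
        rows, consts = [], []
        for cl in clauses:
            members = [v for v in cl.vertices if v in comp_of]
            row = 0
            # red(v) = NOT (bit(v) XOR bit(red anchor)): each member adds
            # 1 + base[v] + base[ra] to the constant besides its flip vars
            const = (cl.offset + len(members) * (1 + base[red_anchor])) % 2
            if len(members) % 2:
                row ^= 1 << ra_comp
            for v in members:
                row ^= 1 << comp_of[v]
                const ^= base[v]
            rows.append(row)
            consts.append(const % 2)
        solution = _solve_gf2(rows, consts, len(comps))
        if solution is None:
            return None
        flips = solution
    return {
        v: "A" if (base[v] ^ flips[comp_of[v]]) == 0 else "B" for v in comp_of
    }


# ---------------------------------------------------------------------------
# Edmonds-Karp max flow / min cut


def max_flow_min_cut(net: FlowNetwork, bound: int) -> tuple[int, FlowNetwork] | None:
    """Shortest-augmenting-path max flow, aborting once the flow value
    would exceed ``bound``.  Returns (value, net-with-flows) or None."""
    adj: dict = {}
    for (u, v) in net.capacity:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    for node in adj:
        adj[node] = sorted(adj[node], key=repr)

    def residual(u, v) -> float:
        cap = net.capacity.get((u, v), 0.0)
        return (cap - net.flow.get((u, v), 0.0)) + net.flow.get((v, u), 0.0)

    net.reset_flow()
    value = 0
    while True:
        parent = {net.source: None}
        queue = deque([net.source])
        while queue and net.sink not in parent:
            u = queue.popleft()
            for v in adj.get(u, ()):
                if v not in parent and residual(u, v) > 1e-9:
                    parent[v] = u
                    queue.append(v)
        if net.sink not in parent:
            return value, net
        path = []
        node = net.sink
        while parent[node] is not None:
            path.append((parent[node], node))
            node = parent[node]
        delta = min(residual(u, v) for u, v in path)
        if math.isinf(delta):
            raise RuntimeError("augmenting path of infinite capacity (s-t arc?)")
        for u, v in path:
            back = min(net.flow.get((v, u), 0.0), delta)
            if back > 0:
                net.flow[(v, u)] -= back
            fwd = delta - back
            if fwd > 0:
                net.flow[(u, v)] = net.flow.get((u, v), 0.0) + fwd
        value += int(round(delta))
        if value > bound:
            return None


# ---------------------------------------------------------------------------
# Picard-Queyranne closure structure of all minimum cuts


@dataclass
class ClosureDAG:
    components: list[list]  # SCCs of the residual graph, by index
    dag: nx.DiGraph  # edges between component indices (relation R̄)
    forced_source: frozenset  # component indices forced to the source side
    forced_sink: frozenset
    free: list  # remaining component indices, deterministic order
    vertex_map: dict  # original vertex -> component index


def build_closure_dag(net: FlowNetwork) -> ClosureDAG:
    """Condense the residual graph of a *maximum* flow.

    Residual relation R: i→j iff (i, j) has spare capacity or (j, i)
    carries flow.  A source side of a minimum cut is exactly a closure
    for R containing s and not t, so after condensing strongly connected
    components, the source's component plus its successors are forced in,
    the sink's component plus its predecessors are forced out, and every
    successor-closed subset of the remaining components induces a
    minimum cut.
    """
    res = nx.DiGraph()
    res.add_nodes_from(net.nodes)
    for (u, v), cap in net.capacity.items():
        if net.flow.get((u, v), 0.0) < cap - 1e-9:
            res.add_edge(u, v)
        if net.flow.get((u, v), 0.0) > 1e-9:
            res.add_edge(v, u)
    comp_sets = [sorted(c, key=repr) for c in nx.strongly_connected_components(res)]
    comp_sets.sort(key=lambda c: repr(c[0]))
    vertex_map = {}
    for idx, comp in enumerate(comp_sets):
        for v in comp:
            vertex_map[v] = idx
    dag = nx.DiGraph()
    dag.add_nodes_from(range(len(comp_sets)))
    for u, v in res.edges:
        cu, cv = vertex_map[u], vertex_map[v]
        if cu != cv:
            dag.add_edge(cu, cv)
    s_comp, t_comp = vertex_map[net.source], vertex_map[net.sink]
    forced_source = frozenset({s_comp} | nx.descendants(dag, s_comp))
    forced_sink = frozenset({t_comp} | nx.ancestors(dag, t_comp))
    if forced_source & forced_sink:
        raise RuntimeError("source reaches sink in the residual graph: flow not maximal")
    free = sorted(set(dag.nodes) - forced_source - forced_sink)
    return ClosureDAG(comp_sets, dag, forced_source, forced_sink, free, vertex_map)


def iter_mincut_source_sides(dag: ClosureDAG, max_closures: int = 200_000):
    """Yield the source-side vertex sets of every minimum cut.

    Enumerates successor-closed subsets of the free components (each
    united with the forced source side).  Deterministic order; guarded by
    ``max_closures``.
    """
    free_set = set(dag.free)
    sub = dag.dag.subgraph(dag.free)
    # successors first: including a component then only requires
    # already-decided components, so every closed subset appears once
    free_topo = list(reversed(list(nx.lexicographical_topological_sort(sub))))
    succ_in_free = {f: set(sub.successors(f)) for f in free_set}
    count = 0

    def emit(chosen: frozenset):
        members = set()
        for ci in dag.forced_source | chosen:
            members.update(dag.components[ci])
        return frozenset(members)

    def recurse(idx: int, chosen: frozenset):
        nonlocal count
        if count > max_closures:
            return
        if idx == len(free_topo):
            count += 1
            if count > max_closures:
                logger.warning("closure enumeration truncated at %d cuts", max_closures)
                return
            yield emit(chosen)
            return
        f = free_topo[idx]
        yield from recurse(idx + 1, chosen)  # exclude f
        if succ_in_free[f] <= chosen:  # include f: successors must be in
            yield from recurse(idx + 1, chosen | {f})

    yield from recurse(0, frozenset())


def parity_feasible_closure(
    dag: ClosureDAG,
    parity_sets: list[ParityClause],
    coloring_context: dict,
    max_closures: int = 200_000,
):
    """Search the minimum cuts encoded by ``dag`` for one whose induced
    removal set is parity-feasible.

    ``coloring_context`` supplies the working graph, the red anchor, the
    map from a source side to the removal-set candidate, and a
    diagnostics dict.  Returns (removed_edges, coloring) or None.  Parity
    is checked exactly per candidate (GF(2) over component flips), which
    subsumes the per-member backtracking decomposition.
    """
    graph = coloring_context["graph"]
    red_anchor = coloring_context["red_anchor"]
    cut_edges_of = coloring_context["cut_edges_of"]
    diag = coloring_context.get("diagnostics")
    budget = coloring_context["budget"]
    seen: set = set()
    for source_side in iter_mincut_source_sides(dag, max_closures=max_closures):
        removed = cut_edges_of(source_side)
        key = frozenset(removed)
        if key in seen:
            continue
        seen.add(key)
        if diag is not None:
            diag["closure_candidates"] = diag.get("closure_candidates", 0) + 1
        if len(removed) > budget:
            continue
        coloring = parity_feasible_coloring(graph, parity_sets, red_anchor, removed)
        if coloring is not None:
            return removed, coloring
    return None


# ---------------------------------------------------------------------------
# compression step


def _edge_sort_key(data: dict) -> tuple:
    origin = data.get("origin")
    half = data.get("half", 0)
    if origin is None:
        return (0, "", half)
    if isinstance(origin, str):
        return (1, origin, half)
    if hasattr(origin, "sort_key"):
        return (2, origin.sort_key(), half)
    return (3, repr(origin), half)


def ordered_edges(graph: nx.MultiGraph) -> list:
    """Deterministic edge order: synthetic gadget edges first, then by
    provenance (trio, site pair, sign) and dum-path half."""
    edges = [
        ((u, v, k), data) for u, v, k, data in graph.edges(keys=True, data=True)
    ]
    edges.sort(key=lambda t: (_edge_sort_key(t[1]), repr(t[0])))
    return [key for key, _ in edges]


def compress(
    graph: nx.MultiGraph,
    x_prime: list,
    parity_sets: list[ParityClause],
    red_anchor,
    diagnostics: dict | None = None,
) -> tuple[list, dict] | None:
    """Shrink the bipartization set ``x_prime`` (size k'+1) to ≤ k'.

    Subdivides every ``x_prime`` edge into three (the middle edge taking
    its place, so a smaller solution may be assumed disjoint), enumerates
    the 2^k' valid partitions Φ of the subdivision endpoints, and for
    each seeks a parity-feasible minimum ``A_Φ``–``B_Φ`` cut of size
    ≤ k' in the rest of the graph.  Returns (removed original edges,
    coloring of the original graph) or None.
    """
    k_prime = len(x_prime) - 1
    diag = diagnostics if diagnostics is not None else {}

    work = nx.MultiGraph()
    work.add_nodes_from(graph.nodes)
    orig_of: dict = {}  # work edge key -> original edge key
    middle: list = []  # (a, b) endpoints of the subdivided x_prime edges
    xset = set(x_prime)
    for u, v, k in graph.edges(keys=True):
        if (u, v, k) in xset or (v, u, k) in xset:
            continue
        key = work.add_edge(u, v)
        orig_of[(u, v, key)] = (u, v, k)
    for idx, (u, v, k) in enumerate(sorted(xset, key=repr)):
        a, b = ("sub", idx, 0), ("sub", idx, 1)
        key = work.add_edge(u, a)
        orig_of[(u, a, key)] = (u, v, k)
        key = work.add_edge(b, v)
        orig_of[(b, v, key)] = (u, v, k)
        middle.append((a, b))
        # the middle edge itself is never added: it is the new x_prime

    base, comps, odd = _bipartite_coloring(work, set())
    if odd is not None:
        raise RuntimeError("graph minus bipartization set is not bipartite")

    def canonical(u, v, k):
        return (u, v, k) if (u, v, k) in orig_of else (v, u, k)

    def cut_edges_of(source_side: frozenset) -> list:
        out = []
        for u, v, k in work.edges(keys=True):
            if (u in source_side) != (v in source_side):
                out.append(orig_of[canonical(u, v, k)])
        return sorted(set(out), key=repr)

    # valid partitions: d(a) free, d(b) forced so the middle edge is bichromatic
    # (relative to the base coloring); first bit fixed by global symmetry
    n_bits = len(middle)
    for bits in itertools.product((0, 1), repeat=max(n_bits - 1, 0)):
        dvals = (0,) + bits
        diag["partitions_tried"] = diag.get("partitions_tried", 0) + 1
        a_side, b_side = [], []
        for (a, b), da in zip(middle, dvals):
            db = da ^ base[a] ^ base[b] ^ 1
            (a_side if da == 0 else b_side).append(a)
            (a_side if db == 0 else b_side).append(b)
        net = FlowNetwork(source=("super", "s"), sink=("super", "t"))
        for u, v, k in work.edges(keys=True):
            net.add_undirected(u, v, 1.0)
        for node in a_side:
            net.add_arc(net.source, node, math.inf)
        for node in b_side:
            net.add_arc(node, net.sink, math.inf)
        diag["flows_computed"] = diag.get("flows_computed", 0) + 1
        flow = max_flow_min_cut(net, bound=k_prime)
        if flow is None:
            continue
        dag = build_closure_dag(net)
        found = parity_feasible_closure(
            dag,
            parity_sets,
            {
                "graph": graph,
                "red_anchor": red_anchor,
                "cut_edges_of": cut_edges_of,
                "budget": k_prime,
                "diagnostics": diag,
            },
        )
        if found is not None:
            removed, coloring = found
            return removed, coloring
    return None


# ---------------------------------------------------------------------------
# exhaustive fallback: exact branch and bound


def exact_bipartization_search(
    graph: nx.MultiGraph,
    budget: int,
    parity_sets: list[ParityClause],
    red_anchor,
    edge_pool: list | None = None,
) -> tuple[list, dict] | None:
    """Complete search for a parity-feasible bipartization set of size
    ≤ ``budget``.

    Odd-cycle branching while the graph is non-bipartite (every solution
    must remove one edge of any odd cycle); once bipartite, parity
    infeasibility is repaired by branching over further removals in
    canonical edge order (feasibility is monotone under edge removal, so
    the ordered enumeration is complete).  Independent of the flow/
    closure machinery.
    """
    pool = edge_pool if edge_pool is not None else ordered_edges(graph)
    index: dict = {}
    for i, (u, v, k) in enumerate(pool):
        index[(u, v, k)] = i
        index[(v, u, k)] = i  # BFS may report the flipped orientation
    seen: set = set()

    def recurse(removed: tuple, budget_left: int, repair_start: int):
        key = (frozenset(removed), repair_start)
        if key in seen:
            return None
        seen.add(key)
        base, comps, odd = _bipartite_coloring(graph, set(removed))
        if odd is not None:
            if budget_left == 0:
                return None
            for e in sorted({pool[index[e]] for e in odd}, key=lambda e: index[e]):
                hit = recurse(removed + (e,), budget_left - 1, repair_start)
                if hit is not None:
                    return hit
            return None
        coloring = parity_feasible_coloring(graph, parity_sets, red_anchor, set(removed))
        if coloring is not None:
            return list(removed), coloring
        if budget_left == 0:
            return None
        # feasibility is monotone under further removal, so ordering the
        # repair-phase removals (and only those) keeps the search complete
        taken = set(removed)
        for pos in range(repair_start, len(pool)):
            e = pool[pos]
            if e in taken:
                continue
            hit = recurse(removed + (e,), budget_left - 1, pos + 1)
            if hit is not None:
                return hit
        return None

    return recurse((), budget, 0)


# ---------------------------------------------------------------------------
# iterative compression driver


def solve_gber(inst: GberInstance, mode: str = "paper_faithful") -> BipartizationResult:
    """Minimum parity-feasible edge bipartization within ``inst.budget``.

    Iterative compression over the instance edges in deterministic
    order.  Infeasibility (|X| would exceed the budget) is a result, not
    an exception.  In ``exhaustive_fallback`` mode every failed
    mincut-only compression is retried with the complete search; the
    diagnostics record whether the fallback ever rescued a compression
    (``fallback_rescues``), which flags a gap of the mincut-only route.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    diag: dict = {
        "mode": mode,
        "iterations": 0,
        "compressions": 0,
        "partitions_tried": 0,
        "flows_computed": 0,
        "closure_candidates": 0,
        "fallback_invocations": 0,
        "fallback_rescues": 0,
        "x_sizes": [],
    }
    order = ordered_edges(inst.graph)
    work = nx.MultiGraph()
    work.add_nodes_from(inst.graph.nodes)

    coloring = parity_feasible_coloring(work, inst.parity_sets, inst.red_anchor, set())
    if coloring is None:
        return BipartizationResult(False, [], {}, 0, diag)

    x: list = []
    for u, v, k in order:
        work.add_edge(u, v, key=k, **inst.graph.edges[u, v, k])
        diag["iterations"] += 1
        cand = parity_feasible_coloring(work, inst.parity_sets, inst.red_anchor, set(x))
        if cand is not None:
            coloring = cand
            diag["x_sizes"].append(len(x))
            continue
        x_prime = x + [(u, v, k)]
        diag["compressions"] += 1
        hit = compress(work, x_prime, inst.parity_sets, inst.red_anchor, diag)
        if hit is None and mode == "exhaustive_fallback":
            diag["fallback_invocations"] += 1
            hit = exact_bipartization_search(
                work, len(x), inst.parity_sets, inst.red_anchor
            )
            if hit is not None:
                diag["fallback_rescues"] += 1
                logger.warning(
                    "mincut-only compression missed a parity-feasible set; "
                    "exhaustive fallback rescued it"
                )
        if hit is not None:
            x, coloring = list(hit[0]), hit[1]
        else:
            x = x_prime
            coloring = parity_feasible_coloring(
                work, inst.parity_sets, inst.red_anchor, set(x)
            )
            assert coloring is not None, "X' must remain a valid bipartization set"
        diag["x_sizes"].append(len(x))
        if len(x) > inst.budget:
            return BipartizationResult(False, x, {}, len(x), diag)
    return BipartizationResult(True, x, coloring, len(x), diag)
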
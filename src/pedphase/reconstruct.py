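"""Map a bipartization solution back to haplotypes and recombination events.

The GBER coloring splits vertices into the side of the red anchor and
the side of the green anchor; a grey site-pair vertex is red when its
member's leading haplotype flips its allele between the two sites and
green when it keeps it.  Walking each member's chain of consecutive
heterozygous pairs therefore reconstructs the full phase (anchored at
allele 0 on the first heterozygous site — the complementary assignment
is equally valid).  Each removed or folded edge maps through its
provenance to one recombination event: a positive edge localizes the
event to the parent of its trio transmission, a negative edge to one of
the child's two parents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from pedphase.gber import BipartizationResult, GberInstance, solve_gber
from pedphase.graph import GREEN, RED, build_pedigree_graph
from pedphase.pedigree import (
    HaplotypeConfiguration,
    HaplotypePair,
    MendelianError,
    Pedigree,
    RecombinationEvent,
    check_mendelian_consistency,
    count_recombinations,
)
from pedphase.reduction import build_gber_instance

logger = logging.getLogger(__name__)

__all__ = [
    "VertexColoring",
    "Infeasible",
    "PhasingReport",
    "colors_from_result",
    "haplotypes_from_colors",
    "localize_recombinations",
    "phase_pedigree",
    "solve_rhc",
]

VertexColoring = dict  # SiteVertex id -> "red" | "green"


class Infeasible(Exception):
    """No haplotype configuration with at most k_max recombinations."""


def colors_from_result(inst: GberInstance, res: BipartizationResult) -> VertexColoring:
    """Vertex colors from the 2-coloring: the red anchor's side is red.

    Dum and subdivision vertices are dropped; merged-away resolved
    vertices are restored to their construction colors via the instance's
    color snapshot.
    """
    if not res.feasible:
        raise ValueError("cannot derive colors from an infeasible result")
    ra, ga = inst.anchors
    if res.coloring[ra] == res.coloring[ga]:
        raise RuntimeError("anchors on the same side: k+1 edge gadget violated")
    red_side = res.coloring[ra]
    colors: VertexColoring = {}
    for vid in inst.site_vertices:
        if vid in res.coloring:
            colors[vid] = RED if res.coloring[vid] == red_side else GREEN
        else:
            colors[vid] = inst.resolved_colors[vid]
    return colors


def haplotypes_from_colors(p: Pedigree, vc: VertexColoring) -> dict[str, HaplotypePair]:
    """Decode per-member haplotypes from site-pair vertex colors.

    Homozygous sites are fixed by the genotype.  h1 carries allele 0 at
    the member's first heterozygous site; along the chain of consecutive
    heterozygous pairs, green preserves the allele and red flips it.  h2
    is the site-wise complement at heterozygous sites.
    """
    phases: dict[str, HaplotypePair] = {}
    for mem in p.members:
        g = mem.genotype
        h1 = [None] * len(g)
        for idx, code in enumerate(g):
            if code != 2:
                h1[idx] = code
        het = g.heterozygous_sites()
        if het:
            allele = 0
            h1[het[0] - 1] = 0
            for i, j in zip(het, het[1:]):
                color = vc.get((mem.member_id, i, j))
                if color is None:
                    raise KeyError(f"no color for chain vertex ({mem.member_id},{i},{j})")
                allele = allele if color == GREEN else 1 - allele
                h1[j - 1] = allele
        h2 = [1 - a if g[idx] == 2 else a for idx, a in enumerate(h1)]
        phases[mem.member_id] = HaplotypePair(tuple(h1), tuple(h2))
    return phases


def _event_of(edge) -> RecombinationEvent:
    return RecombinationEvent(edge.child, frozenset(edge.parents), edge.sites)


def localize_recombinations(
    inst: GberInstance, res: BipartizationResult, vc: VertexColoring
) -> list[RecombinationEvent]:
    """One event per removed edge (plus the folded baseline edges).

    A removed edge with synthetic provenance (anchor gadget) indicates a
    solver defect and raises: within budget, gadget edges are never the
    cheapest removal.
    """
    events = [_event_of(e) for e in inst.forced_edges]
    for (u, v, key) in res.removed_edges:
        origin = inst.graph.edges[u, v, key].get("origin")
        if origin is None or isinstance(origin, str):
            raise RuntimeError(f"removed edge ({u},{v}) has synthetic provenance {origin!r}")
        events.append(_event_of(origin))
    return sorted(events, key=RecombinationEvent.sort_key)


@dataclass
class PhasingReport:
    feasible: bool
    config: HaplotypeConfiguration | None
    k: int | None
    mode: str
    diagnostics: dict = field(default_factory=dict)


def phase_pedigree(
    p: Pedigree, k_max: int = 10, mode: str = "exhaustive_fallback"
) -> PhasingReport:
    """Search k = 0..k_max upward for the minimum-recombination phasing.

    The pedigree graph is built once; the transformation (whose anchor
    gadget depends on k) and the GBER solve are re-run per k.  The first
    feasible k is the minimum; the returned configuration is verified
    against :func:`count_recombinations` before being reported.
    """
    violations = check_mendelian_consistency(p)
    if violations:
        v = violations[0]
        raise MendelianError(
            f"Mendelian inconsistency at site {v['site']} of trio "
            f"({v['trio'].father},{v['trio'].mother},{v['trio'].child})"
        )
    graph, parity_sets = build_pedigree_graph(p)
    diagnostics: dict = {
        "n_vertices": graph.n_vertices,
        "n_edges": graph.n_edges,
        "n_parity_sets": len(parity_sets),
        "per_k": [],
    }
    for k in range(k_max + 1):
        inst = build_gber_instance(graph, parity_sets, k)
        if inst is None:  # baseline of forced recombinations already exceeds k
            diagnostics["per_k"].append({"k": k, "skipped": "baseline_exceeds_k"})
            continue
        res = solve_gber(inst, mode=mode)
        diagnostics["per_k"].append(
            {"k": k, "feasible": res.feasible, **{
                key: res.diagnostics.get(key)
                for key in (
                    "compressions",
                    "partitions_tried",
                    "flows_computed",
                    "closure_candidates",
                    "fallback_invocations",
                    "fallback_rescues",
                )
            }}
        )
        if not res.feasible:
            continue
        vc = colors_from_result(inst, res)
        phases = haplotypes_from_colors(p, vc)
        events = localize_recombinations(inst, res, vc)
        solver_k = inst.baseline_cost + len(res.removed_edges)
        counted_k, counted_events = count_recombinations(p, phases)
        if counted_k != solver_k:
            # the phasing itself is the ground truth for the event count
            logger.warning(
                "solver cost %d != recombination count %d; using the count",
                solver_k,
                counted_k,
            )
            events = counted_events
        cfg = HaplotypeConfiguration(phases, events, counted_k)
        cfg.validate(p)
        diagnostics["k"] = counted_k
        diagnostics["baseline_cost"] = inst.baseline_cost
        diagnostics["mode_used"] = mode
        return PhasingReport(True, cfg, counted_k, mode, diagnostics)
    return PhasingReport(False, None, None, mode, diagnostics)


def solve_rhc(
    p: Pedigree, k_max: int = 10, mode: str = "exhaustive_fallback"
) -> HaplotypeConfiguration:
    """Minimum-recombination haplotype configuration with at most
    ``k_max`` events; raises :class:`Infeasible` when none exists."""
    report = phase_pedigree(p, k_max=k_max, mode=mode)
    if not report.feasible:
        raise Infeasible(f"no haplotype configuration with at most {k_max} recombinations")
    return report.config
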
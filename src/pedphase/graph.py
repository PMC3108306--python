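"""Colored signed pedigree graph and parity-constraint sets.

The reduction represents each member's phase by *site-pair vertices*: a
**grey** vertex over two heterozygous sites ``(i, j)`` stands for the
unknown relation between ``h1[i]`` and ``h1[j]`` — *green* if the allele
is preserved, *red* if it flips — while a vertex over two homozygous
sites is **resolved** at construction (red when the genotype codes
differ, green when they agree).  Grey vertices over *consecutive*
heterozygous pairs form each member's primary chain; a vertex spanning a
wider heterozygous interval is redundant with the chain it covers, and a
*parity-constraint set* (the anchor plus its chain must carry an even
number of red vertices) keeps the two representations consistent.

Transmission constraints are exact, derived from the mosaic model of
recombination.  For a trio with parents ``u, v`` and child ``c``:

* one *routing* vertex per trio encodes which of the child's two
  haplotypes came from the father;
* a *transmitted-allele* vertex ``D`` per (parent, child-heterozygous
  site) encodes the allele that parent's transmission carries there; a
  hard parity clause ties it to the child's chain prefix and the routing
  bit, and a *routing pin* clause fixes it outright where the parent is
  homozygous (it can only transmit its own allele, recombination or not);
* each recombination detectable in parent ``p`` falls between two
  consecutive heterozygous sites ``(i, j)`` of ``p``, and the minimal
  mosaic cost of the transmission is exactly the number of pairs where
  the transmitted flip disagrees with ``p``'s own phase flip.  Each pair
  therefore contributes one signed edge from ``p``'s vertex: positive to
  the child's same-pair vertex when ``(i, j)`` is heterozygous in the
  child (supplementary vertices bridge non-consecutive intervals),
  positive to a resolved vertex when homozygous in the child, and signed
  by the child's homozygous allele to the ``D`` vertex when mixed.

Minimizing positive edges across a red/green partition plus negative
edges within a part — the signed graph's *line index*, restricted to
colorings satisfying every parity clause — then equals the minimum
recombination count exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

from pedphase.pedigree import Genotype, Member, Pedigree, Trio

logger = logging.getLogger(__name__)

VertexId = tuple[str, int, int]  # (member or pseudo-member, i, j), 1-based, i < j

GREY, RED, GREEN = "grey", "red", "green"


@dataclass
class SiteVertex:
    member_id: str
    i: int
    j: int
    color: str  # grey | red | green
    origin: str  # primary_het | primary_hom | supplementary | routing | transmitted_allele

    def __post_init__(self):
        if not self.i < self.j:
            raise ValueError(f"site pair must be ordered, got ({self.i}, {self.j})")

    @property
    def vid(self) -> VertexId:
        return (self.member_id, self.i, self.j)

    @property
    def resolved(self) -> bool:
        return self.color in (RED, GREEN)


@dataclass(frozen=True)
class SignedEdge:
    edge_id: int
    u: VertexId
    v: VertexId
    sign: int
    trio_index: int
    relation: str  # parent_child | transmission | parent_parent
    parents: tuple[str, ...]  # the parent(s) a violation charges
    child: str

    def __post_init__(self):
        allowed = {
            (1, "parent_child"),
            (1, "transmission"),
            (-1, "transmission"),
            (-1, "parent_parent"),
        }
        if (self.sign, self.relation) not in allowed:
            raise ValueError("sign/relation mismatch")

    @property
    def sites(self) -> tuple[int, int]:
        """Site pair of the parent-side endpoint (the event interval)."""
        return self.u[1:]

    def key(self) -> tuple:
        a, b = sorted((self.u, self.v))
        return (a, b, self.sign, self.trio_index, self.relation)

    def sort_key(self) -> tuple:
        return (self.trio_index, self.sites, -self.sign, self.u, self.v)


@dataclass(frozen=True)
class ParityConstraintSet:
    """Hard XOR constraint: the red-count over ``vertex_ids`` must have
    parity ``offset``.

    ``member_chain`` sets are the classic per-member anchor+chain sets;
    ``transmitted_allele`` sets define a D vertex from the child's chain
    prefix and the routing bit; ``routing_pin`` sets fix the transmitted
    allele where a parent is homozygous at a child-heterozygous site.
    """

    member_id: str | None
    anchor: VertexId | None
    vertex_ids: frozenset
    offset: int = 0
    kind: str = "member_chain"


class PedigreeGraph:
    """Signed multigraph over site-pair vertices plus hard parity clauses."""

    def __init__(self):
        self.vertices: dict[VertexId, SiteVertex] = {}
        self.edges: list[SignedEdge] = []
        self.clauses: list[ParityConstraintSet] = []
        self._edge_keys: set = set()
        self._clause_keys: set = set()
        self._degree: dict[VertexId, int] = {}
        self._next_edge_id = 0

    # -- vertices -----------------------------------------------------
    def add_vertex(self, v: SiteVertex) -> SiteVertex:
        if v.vid in self.vertices:
            return self.vertices[v.vid]
        self.vertices[v.vid] = v
        self._degree[v.vid] = 0
        return v

    def vertex(self, vid: VertexId) -> SiteVertex:
        return self.vertices[vid]

    def degree(self, vid: VertexId) -> int:
        return self._degree.get(vid, 0)

    def member_vertices(self, member_id: str) -> list[SiteVertex]:
        return sorted(
            (v for v in self.vertices.values() if v.member_id == member_id),
            key=lambda v: (v.i, v.j),
        )

    # -- edges and clauses --------------------------------------------
    def add_edge(
        self,
        u: VertexId,
        v: VertexId,
        sign: int,
        trio_index: int,
        relation: str,
        parents: tuple[str, ...],
        child: str,
    ) -> bool:
        """Insert an edge; returns False when an identical one exists."""
        if u[0] == v[0]:
            raise ValueError("no edge may join two vertices of the same member")
        edge = SignedEdge(self._next_edge_id, u, v, sign, trio_index, relation, parents, child)
        if edge.key() in self._edge_keys:
            return False
        self._edge_keys.add(edge.key())
        self.edges.append(edge)
        self._degree[u] += 1
        self._degree[v] += 1
        self._next_edge_id += 1
        return True

    def add_clause(self, clause: ParityConstraintSet) -> bool:
        key = (clause.vertex_ids, clause.offset, clause.kind)
        if key in self._clause_keys:
            return False
        self._clause_keys.add(key)
        self.clauses.append(clause)
        return True

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# construction


def _pair_kind(g: Genotype, i: int, j: int) -> str:
    """'het' / 'hom' / 'mixed' status of sites i, j (1-based) in a genotype."""
    a_het = g[i - 1] == 2
    b_het = g[j - 1] == 2
    if a_het and b_het:
        return "het"
    if not a_het and not b_het:
        return "hom"
    return "mixed"


def _resolved_color(g: Genotype, i: int, j: int) -> str:
    return RED if g[i - 1] != g[j - 1] else GREEN


def build_member_vertices(mem: Member) -> list[SiteVertex]:
    """Primary vertices of one member: one grey vertex per consecutive
    heterozygous pair, one resolved vertex per consecutive homozygous pair."""
    out: list[SiteVertex] = []
    het = mem.genotype.heterozygous_sites()
    for i, j in zip(het, het[1:]):
        out.append(SiteVertex(mem.member_id, i, j, GREY, "primary_het"))
    hom = mem.genotype.homozygous_sites()
    for i, j in zip(hom, hom[1:]):
        out.append(
            SiteVertex(mem.member_id, i, j, _resolved_color(mem.genotype, i, j), "primary_hom")
        )
    return sorted(out, key=lambda v: (v.i, v.j))


def _chain_vertices(member: Member, lo: int, hi: int) -> list[VertexId]:
    """Primary het chain of ``member`` covering sites ``lo..hi`` (both het)."""
    het = member.genotype.heterozygous_sites()
    span = [s for s in het if lo <= s <= hi]
    return [(member.member_id, a, b) for a, b in zip(span, span[1:])]


def _ensure_supplementary(g: PedigreeGraph, member: Member, i: int, j: int) -> VertexId:
    """Vertex (member, i, j) over a non-mixed pair, creating a properly
    colored supplementary vertex (plus, for a grey one spanning a
    non-consecutive heterozygous interval, its parity-constraint set)."""
    vid = (member.member_id, i, j)
    if vid in g.vertices:
        return vid
    kind = _pair_kind(member.genotype, i, j)
    if kind == "mixed":
        raise ValueError(f"no vertex possible over mixed pair {vid}")
    color = GREY if kind == "het" else _resolved_color(member.genotype, i, j)
    g.add_vertex(SiteVertex(member.member_id, i, j, color, "supplementary"))
    if kind == "het":
        chain = _chain_vertices(member, i, j)
        if len(chain) > 1:
            g.add_clause(
                ParityConstraintSet(
                    member.member_id, vid, frozenset([vid] + chain), 0, "member_chain"
                )
            )
    return vid


def _routing_vertex(g: PedigreeGraph, trio_index: int) -> VertexId:
    vid = (f"@route{trio_index}", 1, 2)
    if vid not in g.vertices:
        g.add_vertex(SiteVertex(vid[0], 1, 2, GREY, "routing"))
    return vid


def _transmitted_vertex(
    g: PedigreeGraph, trio: Trio, trio_index: int, p: Pedigree, parent_id: str, site: int
) -> VertexId:
    """Vertex for the allele ``parent_id`` transmits at child-het ``site``.

    Red encodes allele 1.  The defining clause says: transmitted allele =
    child's h1 allele at ``site`` XOR routing, where the child's h1
    allele is the XOR of its chain colors from its first heterozygous
    site (canonically allele 0) up to ``site``, and the routing bit is
    flipped for the mother (the parents carry complementary haplotypes
    of the child).
    """
    vid = (f"@trans{trio_index}:{parent_id}", site, site + 1)
    if vid in g.vertices:
        return vid
    g.add_vertex(SiteVertex(vid[0], site, site + 1, GREY, "transmitted_allele"))
    child = p.by_id[trio.child]
    first_het = child.genotype.heterozygous_sites()[0]
    chain = _chain_vertices(child, first_het, site)
    route = _routing_vertex(g, trio_index)
    offset = 1 if parent_id == trio.mother else 0
    g.add_clause(
        ParityConstraintSet(
            None, vid, frozenset([vid, route] + chain), offset, "transmitted_allele"
        )
    )
    return vid


def add_trio_edges(g: PedigreeGraph, trio: Trio, p: Pedigree, trio_index: int) -> bool:
    """All transmission constraints of one trio.  Idempotent.

    Routing pins: wherever a parent is homozygous at a child-heterozygous
    site, its transmitted allele there is its own allele regardless of
    recombination — a hard clause on the D vertex.

    Soft edges: one per parent consecutive-heterozygous pair, as
    described in the module docstring; removing the edge is one
    recombination in that parent between those sites.
    """
    changed = False
    father, mother, child = (p.by_id[trio.father], p.by_id[trio.mother], p.by_id[trio.child])
    g_c = child.genotype

    for parent in (father, mother):
        g_p = parent.genotype
        # hard routing pins at child-het sites where this parent is hom
        for s in g_c.heterozygous_sites():
            if g_p[s - 1] != 2:
                d = _transmitted_vertex(g, trio, trio_index, p, parent.member_id, s)
                if g.add_clause(
                    ParityConstraintSet(
                        None, d, frozenset([d]), int(g_p[s - 1]), "routing_pin"
                    )
                ):
                    changed = True
        # soft edges per consecutive-het pair of the parent
        het = g_p.heterozygous_sites()
        for i, j in zip(het, het[1:]):
            u_vid = (parent.member_id, i, j)
            kind = _pair_kind(g_c, i, j)
            if kind == "het":
                v_vid = _ensure_supplementary(g, child, i, j)
                if g.add_edge(
                    u_vid, v_vid, +1, trio_index, "parent_child",
                    (parent.member_id,), child.member_id,
                ):
                    changed = True
            elif kind == "hom":
                v_vid = _ensure_supplementary(g, child, i, j)
                if g.add_edge(
                    u_vid, v_vid, +1, trio_index, "parent_child",
                    (parent.member_id,), child.member_id,
                ):
                    changed = True
            else:  # mixed: het at s, hom at t in the child
                s, t = (i, j) if g_c[i - 1] == 2 else (j, i)
                d = _transmitted_vertex(g, trio, trio_index, p, parent.member_id, s)
                sign = +1 if g_c[t - 1] == 0 else -1
                if g.add_edge(
                    u_vid, d, sign, trio_index, "transmission",
                    (parent.member_id,), child.member_id,
                ):
                    changed = True
    return changed


def propagate_forced_colors(g: PedigreeGraph, p: Pedigree) -> PedigreeGraph:
    """Resolve grey vertices whose color is forced by Mendelian law.

    For a child's heterozygous pair ``(i, j)``, the allele received from
    the father is pinned at a site whenever the father is homozygous
    there (he always transmits that allele, recombination or not) or the
    mother is homozygous there (the father's contribution is the
    complement).  When both sites are pinned, the child's phase flip over
    the pair — hence the vertex color — is fixed at no cost.  The
    classic special case is a parent vertex over two homozygous sites
    forcing the child vertex across a positive edge.  A homozygous
    *child* vertex never forces its heterozygous parent: a recombination
    there is detectable and must stay payable.

    Purely genotype-driven (implied by the routing-pin clauses), so one
    deterministic pass suffices and conflicts cannot arise on
    Mendelian-consistent input.  Resolving these vertices early shrinks
    the grey search space.
    """
    for trio in p.trios:
        gf = p.by_id[trio.father].genotype
        gm = p.by_id[trio.mother].genotype
        for vert in g.member_vertices(trio.child):
            if vert.color != GREY:
                continue
            hap_from_father = {}
            for s in (vert.i, vert.j):
                if gf[s - 1] != 2:
                    hap_from_father[s] = gf[s - 1]
                elif gm[s - 1] != 2:
                    hap_from_father[s] = 1 - gm[s - 1]
            if len(hap_from_father) == 2:
                flips = hap_from_father[vert.i] != hap_from_father[vert.j]
                vert.color = RED if flips else GREEN
    return g


def build_parity_sets(g: PedigreeGraph, p: Pedigree) -> list[ParityConstraintSet]:
    """All hard parity constraints: every member-chain set for a grey
    vertex spanning a non-consecutive heterozygous interval, plus the
    transmitted-allele definitions and routing pins accumulated during
    edge construction."""
    member_ids = {mem.member_id for mem in p.members}
    sets: list[ParityConstraintSet] = [
        c for c in g.clauses if c.kind == "member_chain"
    ]
    have_anchor = {c.anchor for c in sets}
    for mem in p.members:
        for vert in g.member_vertices(mem.member_id):
            if vert.vid in have_anchor or _pair_kind(mem.genotype, vert.i, vert.j) != "het":
                continue
            chain = _chain_vertices(mem, vert.i, vert.j)
            if len(chain) <= 1:
                continue  # consecutive pair: primary, no redundancy
            missing = [c for c in chain if c not in g.vertices]
            if missing:
                raise RuntimeError(
                    f"parity chain incomplete for anchor {vert.vid}: missing {missing}"
                )
            sets.append(
                ParityConstraintSet(
                    mem.member_id, vert.vid, frozenset([vert.vid] + chain), 0, "member_chain"
                )
            )
    sets.extend(c for c in g.clauses if c.kind != "member_chain")
    assert all(
        c.kind != "member_chain" or c.member_id in member_ids for c in sets
    )
    return sets


def build_pedigree_graph(p: Pedigree) -> tuple[PedigreeGraph, list[ParityConstraintSet]]:
    """Primary vertices, per-trio constraints, forced colors, parity sets.

    The construction is a single deterministic pass per trio (constraints
    depend only on genotypes, never on vertices created for other trios),
    followed by the forced-coloring pass and parity-set collection.
    """
    g = PedigreeGraph()
    for mem in p.members:
        for vert in build_member_vertices(mem):
            g.add_vertex(vert)
    for idx, trio in enumerate(p.trios):
        add_trio_edges(g, trio, p, idx)
    propagate_forced_colors(g, p)
    return g, build_parity_sets(g, p)


def size_bounds_ok(g: PedigreeGraph, n: int, m: int) -> bool:
    """Vertex/edge counts within the 3·n·m² construction bound."""
    bound = 3 * n * m * m
    return g.n_vertices <= bound and g.n_edges <= bound


# ---------------------------------------------------------------------------
# debug export


def to_json_dict(g: PedigreeGraph, parity_sets: list[ParityConstraintSet]) -> dict:
    return {
        "vertices": [
            {"id": list(v.vid), "color": v.color, "origin": v.origin}
            for v in g.vertices.values()
        ],
        "edges": [
            {
                "u": list(e.u),
                "v": list(e.v),
                "sign": e.sign,
                "trio": e.trio_index,
                "relation": e.relation,
                "parents": list(e.parents),
                "child": e.child,
            }
            for e in g.edges
        ],
        "parity_sets": [
            {
                "member": s.member_id,
                "anchor": list(s.anchor) if s.anchor else None,
                "vertices": sorted(list(v) for v in s.vertex_ids),
                "offset": s.offset,
                "kind": s.kind,
            }
            for s in parity_sets
        ],
    }


def to_dot(g: PedigreeGraph) -> str:
    """GraphViz export; edge sign as style, vertex color as fill."""
    fill = {GREY: "lightgrey", RED: "salmon", GREEN: "palegreen"}

    def name(vid: VertexId) -> str:
        return f'"{vid[0]}:{vid[1]}-{vid[2]}"'

    lines = ["graph pedigree {"]
    for v in g.vertices.values():
        shape = "ellipse"
        if v.origin == "supplementary":
            shape = "box"
        elif v.origin in ("routing", "transmitted_allele"):
            shape = "diamond"
        lines.append(
            f"  {name(v.vid)} [style=filled, fillcolor={fill[v.color]}, shape={shape}];"
        )
    for e in g.edges:
        style = "solid" if e.sign > 0 else "dashed"
        lines.append(
            f'  {name(e.u)} -- {name(e.v)} [style={style}, label="{e.sign:+d}"];'
        )
    lines.append("}")
    return "\n".join(lines)


def export_json(g: PedigreeGraph, parity_sets, sink) -> None:
    json.dump(to_json_dict(g, parity_sets), sink, indent=2)
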
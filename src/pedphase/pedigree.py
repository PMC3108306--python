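"""Core domain types for pedigrees, genotypes and haplotypes, plus file I/O.

Genotypes are vectors over ``{0, 1, 2}``: ``0`` means both alleles are 0,
``1`` means both alleles are 1, and ``2`` marks a heterozygous site where
the two haplotypes carry ``{0, 1}``.  A pedigree is an ordered collection
of members whose parent references form full trios (both parents known or
neither).  Recombination events are counted per parent-to-child
transmission as the minimum number of source switches needed to explain
the transmitted haplotype as a mosaic of the parent's two haplotypes.

Sites are numbered 1..m throughout; a recombination breakpoint between
sites ``i`` and ``j`` is reported as the open interval ``(i, j)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

__all__ = [
    "Genotype",
    "HaplotypePair",
    "Member",
    "Pedigree",
    "Trio",
    "RecombinationEvent",
    "HaplotypeConfiguration",
    "PedigreeError",
    "PedigreeParseError",
    "MendelianError",
    "parse_pedigree",
    "write_pedigree",
    "write_haplotypes",
    "check_mendelian_consistency",
    "count_recombinations",
]


class PedigreeError(Exception):
    """Base class for pedigree-level errors."""


class PedigreeParseError(PedigreeError):
    """Malformed pedigree input; carries the offending line and column."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + loc)


class MendelianError(PedigreeError):
    """A haplotype transmission impossible under Mendelian inheritance."""


# ---------------------------------------------------------------------------
# types


def _as_genotype(codes: Sequence[int]) -> np.ndarray:
    arr = np.asarray(codes, dtype=np.int8)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("genotype must be a non-empty 1-d vector")
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError("genotype codes must be in {0, 1, 2}")
    return arr


class Genotype:
    """Immutable per-site genotype codes over ``{0, 1, 2}``."""

    __slots__ = ("codes",)

    def __init__(self, codes: Sequence[int]):
        arr = _as_genotype(codes)
        arr.setflags(write=False)
        object.__setattr__(self, "codes", arr)

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("Genotype is immutable")

    def __len__(self) -> int:
        return int(self.codes.size)

    def __getitem__(self, i):
        return int(self.codes[i])

    def __iter__(self):
        return iter(int(x) for x in self.codes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genotype) and np.array_equal(self.codes, other.codes)

    def __hash__(self) -> int:
        return hash(self.codes.tobytes())

    def __repr__(self) -> str:
        return f"Genotype({''.join(str(int(x)) for x in self.codes)})"

    def heterozygous_sites(self) -> list[int]:
        """1-based positions of heterozygous sites."""
        return [int(i) + 1 for i in np.flatnonzero(self.codes == 2)]

    def homozygous_sites(self) -> list[int]:
        """1-based positions of homozygous sites."""
        return [int(i) + 1 for i in np.flatnonzero(self.codes != 2)]


@dataclass(frozen=True)
class HaplotypePair:
    """The two haplotypes of one member, as 0/1 vectors of equal length."""

    h1: tuple[int, ...]
    h2: tuple[int, ...]

    def __post_init__(self):
        h1 = tuple(int(x) for x in self.h1)
        h2 = tuple(int(x) for x in self.h2)
        if len(h1) != len(h2) or not h1:
            raise ValueError("haplotypes must be non-empty and of equal length")
        if any(x not in (0, 1) for x in h1 + h2):
            raise ValueError("haplotype alleles must be 0/1")
        object.__setattr__(self, "h1", h1)
        object.__setattr__(self, "h2", h2)

    def consistent_with(self, g: Genotype) -> bool:
        if len(g) != len(self.h1):
            return False
        for a, b, code in zip(self.h1, self.h2, g):
            if code == 2:
                if {a, b} != {0, 1}:
                    return False
            elif not (a == b == code):
                return False
        return True

    def swapped(self) -> "HaplotypePair":
        return HaplotypePair(self.h2, self.h1)

    @staticmethod
    def from_strings(h1: str, h2: str) -> "HaplotypePair":
        return HaplotypePair(tuple(int(c) for c in h1), tuple(int(c) for c in h2))


@dataclass
class Member:
    member_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"; parsed, preserved, unused by the solver
    genotype: Genotype
    family_id: str = "0"

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"member {self.member_id!r}: father and mother must both be present "
                "or both absent (full trios only)"
            )
        if self.father_id is not None and self.father_id == self.mother_id:
            raise PedigreeError(
                f"member {self.member_id!r}: father and mother must be distinct"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass(frozen=True)
class Trio:
    father: str
    mother: str
    child: str


class Pedigree:
    """Ordered collection of members; trios are derived from parent links.

    General pedigrees are allowed: marriages between relatives may create
    multiple inheritance paths (loops), but the parent relation itself must
    be acyclic and all parent references must resolve.
    """

    def __init__(self, members: Iterable[Member]):
        self.members: list[Member] = list(members)
        self.by_id: dict[str, Member] = {}
        for mem in self.members:
            if mem.member_id in self.by_id:
                raise PedigreeError(f"duplicate member id {mem.member_id!r}")
            self.by_id[mem.member_id] = mem
        m = None
        for mem in self.members:
            if m is None:
                m = len(mem.genotype)
            elif len(mem.genotype) != m:
                raise PedigreeError(
                    f"member {mem.member_id!r} has {len(mem.genotype)} sites, expected {m}"
                )
        self.m: int = m or 0
        for mem in self.members:
            for pid in (mem.father_id, mem.mother_id):
                if pid is not None and pid not in self.by_id:
                    raise PedigreeError(
                        f"member {mem.member_id!r} references unknown parent {pid!r}"
                    )
        self._check_acyclic()
        self.trios: list[Trio] = [
            Trio(mem.father_id, mem.mother_id, mem.member_id)
            for mem in self.members
            if not mem.is_founder
        ]

    @property
    def n(self) -> int:
        return len(self.members)

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(mid: str) -> None:
            if state.get(mid) == 1:
                raise PedigreeError(f"parent relation contains a cycle through {mid!r}")
            if state.get(mid) == 2:
                return
            state[mid] = 1
            mem = self.by_id[mid]
            for pid in (mem.father_id, mem.mother_id):
                if pid is not None:
                    visit(pid)
            state[mid] = 2

        for mem in self.members:
            visit(mem.member_id)

    def genotype(self, member_id: str) -> Genotype:
        return self.by_id[member_id].genotype


@dataclass(frozen=True, order=True)
class RecombinationEvent:
    """A breakpoint strictly between ``interval`` sites in one transmission.

    ``parent_ids`` has one element when the parent is identified, two when
    only the trio is known (either parent could carry the event).
    """

    child_id: str
    parent_ids: frozenset = field(compare=False)
    interval: tuple[int, int] = (1, 2)

    def __post_init__(self):
        i, j = self.interval
        if not (1 <= i < j):
            raise ValueError(f"invalid interval {self.interval}")
        object.__setattr__(self, "parent_ids", frozenset(self.parent_ids))

    def sort_key(self):
        return (self.child_id, self.interval, tuple(sorted(self.parent_ids)))


@dataclass
class HaplotypeConfiguration:
    """Phased haplotypes for every member plus localized recombination events."""

    phases: dict[str, HaplotypePair]
    events: list[RecombinationEvent]
    k: int

    def validate(self, pedigree: Pedigree) -> None:
        for mem in pedigree.members:
            pair = self.phases.get(mem.member_id)
            if pair is None:
                raise PedigreeError(f"no phase for member {mem.member_id!r}")
            if not pair.consistent_with(mem.genotype):
                raise PedigreeError(
                    f"phase of member {mem.member_id!r} inconsistent with genotype"
                )
        k, _ = count_recombinations(pedigree, self.phases)
        if k != self.k:
            raise PedigreeError(f"stored k={self.k} but count_recombinations gives {k}")


# ---------------------------------------------------------------------------
# parsing / writing

_SEX_IN = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def _parse_row_common(fields: list[str], lineno: int) -> tuple[str, str, str | None, str | None, str]:
    fam, mid, fid, moid, sex = fields[:5]
    father = None if fid == "0" else fid
    mother = None if moid == "0" else moid
    if (father is None) != (mother is None):
        raise PedigreeParseError(
            f"member {mid!r} has exactly one known parent; full trios required",
            line=lineno,
            column=4 if father is not None else 5,
        )
    return fam, mid, father, mother, _SEX_IN.get(sex, "unknown")


def parse_pedigree(text: str | IO[str], dialect: str = "linkage") -> Pedigree:
    """Parse a whitespace-delimited pedigree file.

    ``linkage`` rows carry two allele columns per site with alleles in
    ``{1, 2}`` (``1/1`` -> 0, ``2/2`` -> 1, ``1/2`` or ``2/1`` -> 2);
    ``compact`` rows carry a single genotype string over ``{0, 1, 2}``.
    Allele code ``0`` (missing data) is rejected: the model assumes
    complete, error-free genotypes.
    """
    if dialect not in ("linkage", "compact"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if hasattr(text, "read"):
        text = text.read()
    members: list[Member] = []
    n_sites: int | None = None
    for lineno, raw in enumerate(str(text).splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeParseError(
                f"expected at least 6 columns, got {len(fields)}", line=lineno
            )
        fam, mid, father, mother, sex = _parse_row_common(fields, lineno)
        if dialect == "compact":
            if len(fields) != 6:
                raise PedigreeParseError(
                    f"compact dialect expects exactly 6 columns, got {len(fields)}",
                    line=lineno,
                )
            geno_str = fields[5]
            codes = []
            for pos, ch in enumerate(geno_str):
                if ch not in "012":
                    raise PedigreeParseError(
                        f"invalid genotype code {ch!r} (missing data is not supported)",
                        line=lineno,
                        column=6,
                    )
                codes.append(int(ch))
        else:
            alleles = fields[5:]
            if len(alleles) % 2 != 0:
                raise PedigreeParseError(
                    "odd number of allele columns", line=lineno, column=len(fields)
                )
            codes = []
            for site, (a, b) in enumerate(zip(alleles[::2], alleles[1::2]), start=1):
                col = 4 + 2 * site
                if a == "0" or b == "0":
                    raise PedigreeParseError(
                        "missing allele code '0' encountered (no missing data supported)",
                        line=lineno,
                        column=col,
                    )
                if a not in ("1", "2") or b not in ("1", "2"):
                    raise PedigreeParseError(
                        f"invalid allele pair {a}/{b}", line=lineno, column=col
                    )
                if a == b:
                    codes.append(0 if a == "1" else 1)
                else:
                    codes.append(2)
        if not codes:
            raise PedigreeParseError("no genotype data", line=lineno, column=6)
        if n_sites is None:
            n_sites = len(codes)
        elif len(codes) != n_sites:
            raise PedigreeParseError(
                f"member {mid!r} has {len(codes)} sites, expected {n_sites}",
                line=lineno,
                column=6,
            )
        try:
            members.append(
                Member(mid, father, mother, sex, Genotype(codes), family_id=fam)
            )
        except PedigreeError as exc:
            raise PedigreeParseError(str(exc), line=lineno) from exc
    if not members:
        raise PedigreeParseError("empty pedigree file", line=1)
    try:
        return Pedigree(members)
    except PedigreeError as exc:
        raise PedigreeParseError(str(exc)) from exc


def write_pedigree(p: Pedigree, sink: IO[str], dialect: str = "linkage") -> None:
    """Inverse of :func:`parse_pedigree`; preserves member order."""
    for mem in p.members:
        row = [
            mem.family_id,
            mem.member_id,
            mem.father_id or "0",
            mem.mother_id or "0",
            _SEX_OUT[mem.sex],
        ]
        if dialect == "compact":
            row.append("".join(str(c) for c in mem.genotype))
        elif dialect == "linkage":
            pairs = {0: ("1", "1"), 1: ("2", "2"), 2: ("1", "2")}
            for code in mem.genotype:
                row.extend(pairs[code])
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        sink.write("\t".join(row) + "\n")


def write_haplotypes(cfg: HaplotypeConfiguration, sink: IO[str]) -> None:
    """Emit the phased haplotypes as TSV followed by a structured event block."""
    for mid, pair in cfg.phases.items():
        sink.write(
            f"{mid}\t{''.join(map(str, pair.h1))}\t{''.join(map(str, pair.h2))}\n"
        )
    events = sorted(cfg.events, key=RecombinationEvent.sort_key)
    sink.write(f"#events\t{len(events)}\tk={cfg.k}\n")
    for ev in events:
        parents = ",".join(sorted(ev.parent_ids))
        sink.write(f"{ev.child_id}\t{parents}\t({ev.interval[0]},{ev.interval[1]})\n")


# ---------------------------------------------------------------------------
# Mendelian checking and recombination counting


def check_mendelian_consistency(p: Pedigree) -> list[dict]:
    """Site-level Mendelian violations for every trio.

    Recombination never changes which *single-site* alleles a parent can
    transmit, so each site is checkable independently: the child must
    receive one allele producible by the father and one by the mother.
    Returns an empty list iff the pedigree is consistent.
    """
    options = {0: {0}, 1: {1}, 2: {0, 1}}
    violations = []
    for trio in p.trios:
        gf = p.genotype(trio.father)
        gm = p.genotype(trio.mother)
        gc = p.genotype(trio.child)
        for site in range(1, p.m + 1):
            f_opt, m_opt = options[gf[site - 1]], options[gm[site - 1]]
            c = gc[site - 1]
            if c == 0:
                ok = 0 in f_opt and 0 in m_opt
            elif c == 1:
                ok = 1 in f_opt and 1 in m_opt
            else:
                ok = (0 in f_opt and 1 in m_opt) or (1 in f_opt and 0 in m_opt)
            if not ok:
                violations.append(
                    {"trio": trio, "site": site, "father": gf[site - 1],
                     "mother": gm[site - 1], "child": c}
                )
    return violations


def _transmission_cost(
    parent: HaplotypePair, transmitted: Sequence[int]
) -> tuple[int, list[tuple[int, int]]] | None:
    """Minimum breakpoints for ``transmitted`` as a mosaic of the parent pair.

    Greedy left-to-right scan.  Sites where the parent is homozygous never
    constrain the source (but the allele must match); at heterozygous
    parent sites exactly one source matches.  Each forced source switch
    contributes one breakpoint whose interval spans the two nearest
    constraining sites.  Returns ``None`` if the haplotype is not
    producible even with recombination at every site.
    """
    cost = 0
    events: list[tuple[int, int]] = []
    prev_source: int | None = None
    prev_site: int | None = None
    for idx, allele in enumerate(transmitted):
        site = idx + 1
        a1, a2 = parent.h1[idx], parent.h2[idx]
        if a1 == a2:
            if allele != a1:
                return None
            continue
        source = 1 if allele == a1 else 2
        if prev_source is not None and source != prev_source:
            cost += 1
            events.append((prev_site, site))
        prev_source, prev_site = source, site
    return cost, events


def count_recombinations(
    p: Pedigree, phases: dict[str, HaplotypePair]
) -> tuple[int, list[RecombinationEvent]]:
    """Total minimum recombination count implied by a full phasing.

    For each trio the child's two haplotypes are assigned to the two
    parents in whichever of the two ways is cheaper; each transmitted
    haplotype contributes its minimal mosaic breakpoint count.
    """
    for mem in p.members:
        pair = phases.get(mem.member_id)
        if pair is None or not pair.consistent_with(mem.genotype):
            raise MendelianError(
                f"phase missing or inconsistent for member {mem.member_id!r}"
            )
    total = 0
    all_events: list[RecombinationEvent] = []
    for trio in p.trios:
        child = phases[trio.child]
        best: tuple[int, list[RecombinationEvent]] | None = None
        for hap_f, hap_m in ((child.h1, child.h2), (child.h2, child.h1)):
            rf = _transmission_cost(phases[trio.father], hap_f)
            rm = _transmission_cost(phases[trio.mother], hap_m)
            if rf is None or rm is None:
                continue
            events = [
                RecombinationEvent(trio.child, frozenset({trio.father}), iv)
                for iv in rf[1]
            ] + [
                RecombinationEvent(trio.child, frozenset({trio.mother}), iv)
                for iv in rm[1]
            ]
            cand = (rf[0] + rm[0], events)
            if best is None or cand[0] < best[0]:
                best = cand
        if best is None:
            raise MendelianError(
                f"child {trio.child!r} haplotypes not producible from parents"
            )
        total += best[0]
        all_events.extend(best[1])
    return total, sorted(all_events, key=RecombinationEvent.sort_key)
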
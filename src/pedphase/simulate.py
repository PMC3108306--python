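"""Synthetic pedigrees with known haplotypes and planted recombinations.

The generator emulates the solver's input model: diallelic SNP sites,
founder haplotypes drawn independently per site, Mendelian transmission
through full trios, and a hard *count* of planted recombination
breakpoints assigned uniformly over (transmission, interval) slots.
Genotypes are derived from the simulated haplotypes, so generated
pedigrees are Mendelian-consistent by construction and the planted
configuration is always one witness for the minimum recombination count
(the optimum may be lower — planted breakpoints between homozygous
sites are undetectable).

With ``allow_loops`` couples are formed between members of distinct
sibships inside the pedigree (never ancestor-descendant), creating the
multiple-inheritance-path structures that make general pedigrees hard.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from pedphase.graph import PedigreeGraph, SiteVertex
from pedphase.pedigree import (
    Genotype,
    HaplotypeConfiguration,
    HaplotypePair,
    Member,
    Pedigree,
    count_recombinations,
)

__all__ = [
    "SimulationSpec",
    "simulate_pedigree",
    "random_signed_graph",
    "acceptance_corpus",
    "CorpusItem",
]


@dataclass(frozen=True)
class SimulationSpec:
    n_founder_couples: int = 1
    children_per_couple: int = 2
    generations: int = 1
    m: int = 4
    planted_recombinations: int = 0
    allele_freq: float = 0.5
    seed: int = 0
    allow_loops: bool = False

    def __post_init__(self):
        if min(self.n_founder_couples, self.children_per_couple, self.generations, self.m) < 1:
            raise ValueError("all structural counts must be positive")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must lie in (0, 1)")
        if self.planted_recombinations < 0:
            raise ValueError("planted_recombinations must be nonnegative")


@dataclass
class _Person:
    pid: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"
    sibship: int = -1  # index of the parental couple, -1 for founders


def _build_structure(spec: SimulationSpec) -> list[_Person]:
    people: list[_Person] = []
    counter = [0]

    def new_person(**kw) -> _Person:
        counter[0] += 1
        p = _Person(pid=f"I{counter[0]}", **kw)
        people.append(p)
        return p

    couples: list[tuple[_Person, _Person]] = []
    for _ in range(spec.n_founder_couples):
        f = new_person(sex="male")
        m = new_person(sex="female")
        couples.append((f, m))

    sibship_counter = [0]

    def breed(cpls):
        kids = []
        for f, m in cpls:
            sib = sibship_counter[0]
            sibship_counter[0] += 1
            for _ in range(spec.children_per_couple):
                kids.append(
                    new_person(father=f.pid, mother=m.pid, sibship=sib)
                )
        return kids

    pool = breed(couples)
    for _gen in range(2, spec.generations + 1):
        next_couples: list[tuple[_Person, _Person]] = []
        unpaired = list(pool)
        while unpaired and len(next_couples) < spec.n_founder_couples:
            a = unpaired.pop(0)
            partner = None
            if spec.allow_loops:
                for idx, b in enumerate(unpaired):
                    if b.sibship != a.sibship:
                        partner = unpaired.pop(idx)
                        break
            if partner is None:
                partner = new_person(sex="female")
            a.sex, partner.sex = "male", "female"
            next_couples.append((a, partner))
        for p in unpaired:
            if p.sex == "unknown":
                p.sex = "male"
        pool = breed(next_couples)
    for p in pool:
        if p.sex == "unknown":
            p.sex = "male" if int(p.pid[1:]) % 2 else "female"
    return people


def simulate_pedigree(spec: SimulationSpec) -> tuple[Pedigree, HaplotypeConfiguration]:
    """Simulate (pedigree, ground-truth configuration); deterministic per seed.

    The truth configuration's ``k`` is the recombination count *implied*
    by the true phases (≤ the planted count, since some planted
    breakpoints may be undetectable or jointly redundant).
    """
    rng = np.random.default_rng(spec.seed)
    people = _build_structure(spec)
    m = spec.m

    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    founders = [p for p in people if p.father is None]
    non_founders = [p for p in people if p.father is not None]
    for p in founders:
        h1 = (rng.random(m) < spec.allele_freq).astype(np.int8)
        h2 = (rng.random(m) < spec.allele_freq).astype(np.int8)
        haplotypes[p.pid] = (h1, h2)

    transmissions = [
        (p.pid, parent) for p in non_founders for parent in (p.father, p.mother)
    ]
    slots = [(t, i) for t in range(len(transmissions)) for i in range(1, m)]
    if spec.planted_recombinations > len(slots):
        raise ValueError(
            f"cannot plant {spec.planted_recombinations} breakpoints in "
            f"{len(slots)} (transmission, interval) slots"
        )
    chosen = (
        rng.choice(len(slots), size=spec.planted_recombinations, replace=False)
        if spec.planted_recombinations
        else np.empty(0, dtype=int)
    )
    breaks: dict[int, list[int]] = {}
    for s in sorted(int(c) for c in chosen):
        t, i = slots[s]
        breaks.setdefault(t, []).append(i)

    def transmit(parent_id: str, t_index: int) -> np.ndarray:
        h1, h2 = haplotypes[parent_id]
        source = int(rng.integers(2))
        cuts = set(breaks.get(t_index, ()))
        out = np.empty(m, dtype=np.int8)
        for site in range(1, m + 1):
            out[site - 1] = (h1 if source == 0 else h2)[site - 1]
            if site in cuts:
                source = 1 - source
        return out

    # children in member order; each child pulls one haplotype per parent
    for p in non_founders:
        tf = transmissions.index((p.pid, p.father))
        tm = transmissions.index((p.pid, p.mother))
        haplotypes[p.pid] = (transmit(p.father, tf), transmit(p.mother, tm))

    members = []
    phases: dict[str, HaplotypePair] = {}
    for p in people:
        h1, h2 = haplotypes[p.pid]
        codes = np.where(h1 == h2, h1, 2).astype(np.int8)
        members.append(
            Member(p.pid, p.father, p.mother, p.sex, Genotype(codes), family_id="SIM")
        )
        phases[p.pid] = HaplotypePair(tuple(int(a) for a in h1), tuple(int(a) for a in h2))
    pedigree = Pedigree(members)
    k, events = count_recombinations(pedigree, phases)
    return pedigree, HaplotypeConfiguration(phases, events, k)


def random_signed_graph(
    n_vertices: int, n_edges: int, p_positive: float, seed: int
) -> PedigreeGraph:
    """Random signed multigraph in pedigree-graph shape (test fixture).

    Each vertex belongs to its own pseudo-member so the no-intra-member
    edge rule never bites; parallel edges are allowed.
    """
    if n_vertices < 2 and n_edges > 0:
        raise ValueError("need at least two vertices to place edges")
    rng = np.random.default_rng(seed)
    g = PedigreeGraph()
    for t in range(n_vertices):
        g.add_vertex(SiteVertex(f"v{t}", 1, 2, "grey", "primary_het"))
    for e in range(n_edges):
        u, v = rng.choice(n_vertices, size=2, replace=False)
        u, v = int(u), int(v)
        sign = 1 if rng.random() < p_positive else -1
        if sign > 0:
            g.add_edge(
                (f"v{u}", 1, 2), (f"v{v}", 1, 2), +1, e, "parent_child",
                (f"v{u}",), f"v{v}",
            )
        else:
            g.add_edge(
                (f"v{u}", 1, 2), (f"v{v}", 1, 2), -1, e, "parent_parent",
                (f"v{u}", f"v{v}"), "c",
            )
    return g


# ---------------------------------------------------------------------------
# study corpus


@dataclass(frozen=True)
class CorpusItem:
    spec: SimulationSpec
    pedigree: Pedigree
    truth: HaplotypeConfiguration


_TEMPLATES = (
    # two founder couples, one child each: n = 6, two trios
    SimulationSpec(n_founder_couples=2, children_per_couple=1, generations=1, m=4),
    # three-generation chain: n = 5, two trios
    SimulationSpec(n_founder_couples=1, children_per_couple=1, generations=2, m=4),
    # one couple with two children: n = 4, two trios
    SimulationSpec(n_founder_couples=1, children_per_couple=2, generations=1, m=4),
    SimulationSpec(n_founder_couples=2, children_per_couple=1, generations=1, m=3),
    # looped pedigree: the two sibships intermarry, n = 7, three trios
    SimulationSpec(
        n_founder_couples=2, children_per_couple=1, generations=2, m=3, allow_loops=True
    ),
    SimulationSpec(n_founder_couples=1, children_per_couple=2, generations=1, m=3),
)


def acceptance_corpus(
    seed: int, size: int = 200, max_total_het: int = 18
) -> list[CorpusItem]:
    """Deterministic corpus of small simulated pedigrees.

    Cycles through the structural templates with 0/1/2 planted
    recombinations; pedigrees whose total heterozygous-site count would
    defeat exhaustive cross-validation are skipped and replaced (the
    draw stream is unaffected, so the corpus is reproducible per seed).
    """
    master = np.random.default_rng(seed)
    items: list[CorpusItem] = []
    index = 0
    while len(items) < size:
        template = _TEMPLATES[index % len(_TEMPLATES)]
        planted = index % 3
        sub_seed = int(master.integers(0, 2**31 - 1))
        index += 1
        spec = replace(template, planted_recombinations=planted, seed=sub_seed)
        pedigree, truth = simulate_pedigree(spec)
        total_het = sum(
            len(mem.genotype.heterozygous_sites()) for mem in pedigree.members
        )
        if total_het > max_total_het:
            continue
        items.append(CorpusItem(spec, pedigree, truth))
    return items
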
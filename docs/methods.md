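# Methods

## Model and assumptions

pedphase phases diallelic SNP genotypes on a general pedigree under the
standard meiotic model: each child haplotype is a mosaic of its parent's
two haplotypes, and every source switch between adjacent sites is one
recombination event. The input is assumed complete and error-free; all
parent links form full trios (a record with exactly one known parent is
rejected rather than imputed, because every transmission constraint in
the reduction needs both parents). The sex column is parsed and
preserved but unused — the model is autosomal. Sites are numbered
1..m; a breakpoint is reported as the open interval `(i, j)` between
the two nearest sites that constrain it.

Two structural facts shape everything downstream:

* a recombination is detectable only when the parent is heterozygous on
  both sides of the breakpoint, so the *minimum* event count — the
  quantity the undetectability argument makes well-defined — decomposes
  exactly over each parent's consecutive heterozygous site pairs;
* at heterozygous sites the two haplotypes are complementary, so a
  member's phase is fully described by one bit per consecutive
  heterozygous pair: allele preserved (*green*) or flipped (*red*).

## The exact signed-graph encoding

Per member, one grey vertex per consecutive heterozygous pair (the
phase chain) and one resolved vertex per consecutive homozygous pair.
For each trio the transmission structure is encoded with:

* a **routing vertex** `R_t` — which of the child's two haplotypes came
  from the father (one bit per trio, since a transmission passes a whole
  haplotype);
* **transmitted-allele vertices** `D_{t,p,s}` for parent `p` and
  child-heterozygous site `s`, defined by the hard XOR clause
  `D = (child chain prefix up to s) ⊕ R_t (⊕ 1 for the mother)`;
* **routing pins**: where `p` is homozygous at a child-heterozygous
  site it can only transmit its own allele, recombination or not, so
  `D` is fixed outright;
* **soft signed edges**, one per consecutive heterozygous pair `(i, j)`
  of each parent: to the child's same-pair vertex when `(i, j)` is
  heterozygous in the child (a supplementary child vertex plus its
  anchor-chain parity set bridges non-consecutive intervals), to a
  resolved vertex when homozygous in the child, and to `D` — signed by
  the child's homozygous allele — when mixed. Violating the edge is
  exactly one recombination in that parent between those sites.

Given any assignment satisfying the hard clauses, the number of
violated soft edges *equals* the recombination count of the decoded
configuration under the routing the assignment encodes; minimizing over
assignments therefore equals the mosaic minimum (which itself minimizes
over the two routings per trio). This is stronger than coupling parent
pairs with a single symmetric negative edge: when the child's haplotype
content at the shared heterozygous site is already pinned through its
own chain, the two orientations of "parents colored differently" have
different true costs, and only the transmitted-allele route represents
that. The package's hard clauses generalize the classic per-member
parity-constraint sets (even red count over an anchor and its chain)
with offsets and cross-member membership; the solver machinery treats
both identically.

A purely genotype-driven pass resolves child vertices whose flip is
pinned on both sites (the classic case is a parent homozygous at both
sites; pinning through two differently-mixed parents forces just the
same). This is implied by the clauses and only shrinks the grey search
space. A homozygous child vertex never forces a heterozygous parent:
a recombination there is detectable and must stay payable.

## Transformation and the GBER solver

Positive edges become two-edge negative paths through fresh
intermediate vertices (line index invariant — property-tested on random
signed graphs). Edges joining two resolved vertices fold into a
partition-independent constant. All red vertices merge into one anchor,
all green into the other, `k + 1` parallel edges pin the anchors to
opposite sides, and negating the weights leaves unit-weight Graph
Bipartization by Edge Removal with parity clauses (clause membership of
merged-away resolved vertices becomes a constant offset).

The solver is iterative compression. Edges enter in a fixed order
(synthetic gadget edges first, then by trio, site pair and sign), so
runs are fully reproducible. Whether the maintained set `X` still works
after an insertion — and whether a candidate removal set is
parity-feasible at all — is decided exactly: per-component color flips
of the bipartite remainder are GF(2) variables, each clause one linear
equation (a vertex is red iff it matches the red anchor's side), and
any solution yields a witness coloring. This subsumes the per-member
backtracking decomposition one would otherwise run over the closure
DAG, at negligible cost for small m.

Compression subdivides each `X'` edge into three (the middle edge
taking its place, so a smaller solution may be assumed disjoint — the
subdivision preserves all cycle parities), enumerates the `2^{k'}`
valid endpoint partitions, computes a bounded Edmonds–Karp max flow per
partition, and walks the Picard–Queyranne closure structure of the
residual graph: strongly connected components condensed to a DAG,
source-side forced in with its successors, sink-side forced out with
its predecessors, every successor-closed choice of the free components
a distinct minimum cut. Candidate cuts are deduplicated and tested with
the GF(2) check.

**Completeness.** Searching parity-feasibility only among *minimum*
cuts per partition is not complete: randomized testing against the
brute-force parity-restricted optimum exhibits instances (a few percent
of random GBER instances, and about one corpus pedigree in three
hundred) where every minimum cut of every valid partition fails parity
although a larger cut within budget succeeds. The solver therefore has
two modes. `paper_faithful` is the pure mincut-only search;
`exhaustive_fallback` (the default) runs it first and, only when a
compression fails, re-checks with a complete branch-and-bound
(odd-cycle branching while non-bipartite, then parity-repair removals
in canonical edge order — feasibility is monotone under edge removal,
so the ordered enumeration is complete). Diagnostics count fallback
invocations and rescues, so a gap is always visible in the report.

The decision budget `k` is searched upward from 0; each `k` rebuilds
the transformation (the anchor gadget depends on `k`). The first
feasible `k` is the minimum. The returned configuration is re-verified:
phases must match genotypes and the independent mosaic recombination
count must equal the solver's cost.

## Decoding

The red anchor's side defines red. Each member's `h1` carries allele 0
at its first heterozygous site (the complementary configuration,
swapping `h1`/`h2` of any member, is equally valid and documented as a
symmetry); walking the chain, green keeps the allele and red flips it.
Each removed soft edge maps through its provenance to one event with a
single identified parent and the parent's site-pair interval; folded
constant-cost edges contribute their events likewise.

## Synthetic data and the study corpus

The generator draws founder haplotypes i.i.d. per site (allele
frequency 0.5 by default — maximal heterozygosity is the regime where
phase is actually ambiguous), transmits haplotypes through trios, and
plants a *hard count* of breakpoints assigned uniformly without
replacement over (transmission, interval) slots, so tests can assert
`solver k ≤ planted` exactly. Genotypes are derived from the simulated
haplotypes, hence always Mendelian-consistent, and the truth phasing is
a witness. Loops are created by intermarrying members of distinct
sibships, never ancestor–descendant pairs.

The correctness corpus cycles through six structural templates — two
founder couples with one child each (n = 6), a three-generation chain
(n = 5), one couple with two children (n = 4), their three-site
variants, and a looped pedigree where two sibships intermarry (n = 7,
three trios) — at 4 and 3 sites with 0/1/2 planted recombinations.
Pedigrees whose total heterozygous-site count exceeds the exhaustive
oracle's enumeration guard are skipped and redrawn (deterministically
per seed). With these panel sizes most planted breakpoints fall outside
detectable intervals, so the realized minimum is 0 for roughly 85% of
corpus pedigrees and 1–2 for the rest; the higher-k regime is exercised
separately on random GBER instances and triangle gadgets.

What passing does and does not show: the corpus covers every structural
feature the model recognizes (loops, chains, multiple children, mixed
pairs, forced colors, parity anchors) at small n and m, cross-checked
against exhaustive enumeration — but it says nothing about missing or
erroneous genotypes, multi-allelic markers, or panels large enough that
the `2^k` and per-k rebuild costs bite.

## Numerical and design choices

* All arithmetic is integral; flows use unit capacities (multiplicity
  aggregated) with ∞ only on super-terminal arcs.
* Determinism throughout: sorted neighbor iteration in BFS, fixed edge
  order, seeded generators; identical invocations produce identical
  output files.
* Oracle guards: phase enumeration refuses > 8 members, > 8 sites or
  > 18 total heterozygous sites; coloring enumeration refuses > 16
  vertices; the exact line-index evaluator bounds *free* GF(2)
  parameters (22) rather than raw vertex count, since hard clauses
  eliminate most variables.
* The closure enumeration carries a large node cap as a safety valve;
  truncation logs a warning and can only affect `paper_faithful`
  completeness, which the fallback already covers.
* `k_max` defaults to 10 with a warning about `2^k` growth.

## Known limitations

* No missing data, genotyping errors, or multi-allelic sites; no
  X-chromosome model; unit (unweighted) recombination costs only.
* Runtime grows with `2^k` and with the per-`k` rebuild of the
  transformation; the tool targets small marker panels, not
  chromosome-scale phasing.
* Event attribution reports the parent and interval of each removed
  constraint; when several optimal configurations exist only one
  (deterministic) witness is returned.
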
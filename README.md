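# pedphase

Minimum-recombination haplotype phasing for general pedigrees with a
small number of SNP sites.

## The problem

Each member of a diploid pedigree carries two haplotypes per chromosome,
but genotyping only observes their unordered combination: at every site
we know the genotype code `0` (both alleles 0), `1` (both alleles 1) or
`2` (heterozygous — one of each, phase unknown). Under Mendelian
inheritance a child receives one full haplotype from each parent, except
where meiotic crossover splices complementary parts of a parent's two
haplotypes into the transmitted copy. Given complete, error-free
genotypes `g_u ∈ {0,1,2}^m` for all `n` members of a pedigree (loops
through intermarriage allowed), **pedphase** finds haplotypes
`h1_u, h2_u ∈ {0,1}^m` for every member that are consistent with the
genotypes and minimize the total number of recombination events `k` —
the minimum-recombination haplotype configuration (MRHC) problem, which
is NP-hard even in severely restricted cases but fixed-parameter
tractable in `k` and `m`.

It is a tool for genetic-disease studies working with dense local marker
panels: small `m`, small expected `k`, arbitrary family structure.

## The method

The solver is an exact fixed-parameter algorithm built on a chain of
reductions:

1. **Signed pedigree graph.** Every pair of consecutive heterozygous
   sites `(i, j)` of a member becomes a vertex whose two colors encode
   whether `h1` keeps or flips its allele between `i` and `j` (*green* /
   *red*); homozygous pairs are resolved at construction. Transmission
   constraints become ±1-signed edges on each parent's heterozygous
   pairs, and hard parity constraints (XOR clauses over vertex sets,
   including one routing bit per trio and transmitted-allele vertices)
   pin everything Mendelian law determines. The minimum number of
   recombinations equals the graph's **line index** — the minimum over
   red/green partitions of positive edges across the cut plus negative
   edges within a side — restricted to parity-feasible partitions.
2. **Bipartization.** Positive edges are split into two negative edges
   through fresh intermediate vertices (line index preserved); resolved
   vertices merge into a red and a green anchor pinned apart by `k + 1`
   parallel edges; negating all weights turns the problem into **Graph
   Bipartization by Edge Removal**: delete at most `k` unit edges so the
   remaining multigraph is bipartite, under the parity constraints.
3. **Iterative compression.** Edges are added one at a time while a
   minimum parity-feasible removal set `X` is maintained; when `X`
   stops working, all `2^{k'}` valid partitions of the endpoints of
   `X ∪ {e}` are enumerated and a parity-feasible minimum cut is sought
   with Edmonds–Karp max-flow. All minimum cuts per partition are
   explored through the Picard–Queyranne closure structure (strongly
   connected components of the residual graph condensed into a DAG;
   every successor-closed component choice is a minimum cut), and each
   candidate is tested exactly via a GF(2) system over per-component
   color flips. A complete branch-and-bound fallback covers the rare
   instances where no *minimum* cut is parity-feasible although a
   larger cut within budget is.

The upward search over `k = 0, 1, 2, …` returns the true minimum, the
phases of every member, and the localized breakpoint intervals.

## Worked example

A nuclear family genotyped at two sites, in the compact dialect
(`FamID IndID FatherID MotherID Sex genotype-string`):

```text
FAM1 father  0      0      1 22
FAM1 mother  0      0      2 00
FAM1 child1  father mother 1 20
FAM1 child2  father mother 2 22
```

The two children are incompatible with any single pair of paternal
haplotypes: whatever phase the father has, one child needs a spliced
copy. Running

```sh
pedphase phase --input fam.ped --dialect compact --k-max 4
```

prints

```text
k = 1
father	01	10
mother	00	00
child1	00	10
child2	00	11
#events	1	k=1
child2	father	(1,2)
```

meaning: the minimum is exactly one recombination event; the father is
phased `01 / 10` (each member's first heterozygous site carries allele 0
on `h1` by convention — the complementary assignment is equally valid);
and the single event happened in the father's transmission to `child2`,
with the breakpoint strictly between sites 1 and 2. A JSON report with
solver diagnostics is available via `--report`, and `pedphase simulate`,
`pedphase oracle` and `pedphase graph-dump` provide a seeded pedigree
simulator, an exhaustive-enumeration cross-check for small inputs, and a
DOT/JSON export of the constructed graph.

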
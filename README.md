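# vmusdbg

De novo genome assembly on a **variable-length de Bruijn graph whose nodes
are minimum unique substrings (MUSs)** instead of fixed-length k-mers.

Classical de Bruijn assembly forces one global k: small k collapses repeats,
large k fragments low-coverage regions. A MUS is a substring that occurs
exactly once in its uniqueness scope and is minimal at both ends — dropping
its first or last character leaves a string that occurs at least twice. MUS
lengths adapt to local sequence context, and MUSs sit precisely at the
boundaries of maximal repeats, so a graph built on MUS anchors encodes
repeat structure in its topology without any k-mer length to choose. The
package is aimed at people experimenting with assembly graph models on
clean, HiFi-like (error-free) reads at small to moderate scales.

## The model

Let ℛ = R₁,…,Rₘ be reads over {A,C,G,T} and 𝒜 the anchor (MUS) set. The
assembly graph is a directed multigraph G = (U, V, f, ℐ, P) with
U = 𝒜 ∪ {U_start, U_end}. For each read, anchor occurrences are sorted by
start position; every consecutive pair (wᵢ, wᵢ₊₁) at starts sᵢ < sᵢ₊₁ adds
one edge instance with

- weight δ = sᵢ₊₁ − sᵢ (positional offset), and
- tag τ = the intervening sequence when δ > |wᵢ| (a repeat gap), else ε;

a read whose first anchor starts at s₁ > 1 adds a U_start edge carrying its
leading sequence, and one whose last anchor ends before the read end adds a
U_end edge carrying the trailing sequence. The flow f(u,v) is the number of
instances on (u,v) — the read support of the transition.

Strictly linear nodes (one distinct predecessor and successor, total flow 1
on both sides) are collapsed, merging (δ₁,τ₁) and (δ₂,τ₂) into
(δ₁+δ₂, τ₁·v·τ₂). The simplified graph is decomposed into maximal
non-branching paths (unitigs) bounded by junctions — terminals, or nodes
whose distinct in- or out-neighbour count differs from one — consuming each
edge instance at most once and preferring, per hop, the instance with the
smallest δ (longest τ on terminal edges). Unitigs are then chained across
junctions whose anchor-to-anchor continuation is unambiguous, which undoes
the fragmentation induced by read-boundary terminal edges; a chain that
closes on itself becomes a circular contig. Spelling appends, per hop, the
part of the next anchor not covered by the overlap φ = |seq(u)| − δ, or
τ plus the next anchor when φ < 0.

## Worked example

The bundled fixture is the 10 bp circular genome `ATGCTAGCAC` sampled by
five 6 bp reads (`ATGCTA, GCTAGC, TAGCAC, GCACAT, ACATGC`):

```sh
vmusdbg simulate --toy -o toy.fq --genome toy_genome.fa
vmusdbg run --genome toy_genome.fa --circular -o out toy.fq
```

prints

```
INFO vmusdbg: loaded 5 reads
INFO vmusdbg: extracted 7 anchors
INFO vmusdbg: graph: 9 nodes, 10 distinct edges, 0 reads without anchors
INFO vmusdbg: simplified: 9 nodes, 0 collapses
4 contigs, total 19 bp, largest 10 bp, N50 10 bp -> out/contigs.fa
```

The seven anchors are the genome's MUSs {AT, TG, CT, TA, AG, GCA, AC}
(under circular uniqueness — `CA` wraps from position 10 to 1 and is
therefore not unique). The 9 graph nodes are the anchors plus the two
terminals. The largest contig is circular and 10 bp long:

```
>contig_1 length=10 circular=true
AGCACATGCT
```

— a rotation of the genome, recovered exactly. The three 3 bp contigs are
read-boundary overhangs (e.g. the uncovered leading `G` of `GCTAGC` plus
its first anchor), each an exact substring of the genome.

The same recovery holds at larger scale: error-free 20× reads of length
200 from a 2 kb random circular genome assemble into one circular contig
whose rotation equals the genome (see the test suite).

Per-stage subcommands (`extract`, `build`, `simplify`, `assemble`,
`simulate`) expose the intermediate TSV/GFA/JSON artifacts; see
`vmusdbg --help`.

## Layout

- `src/vmusdbg/mus_core.py` — MUS and maximal-repeat extraction, occurrence
  lookup (suffix-array, suffix-tree, and brute-force backends)
- `src/vmusdbg/graph_build.py` — multigraph construction and GFA export
- `src/vmusdbg/simplify.py` — strictly-linear node collapsing
- `src/vmusdbg/assemble.py` — junctions, unitigs, chaining, spelling, stats
- `src/vmusdbg/synthetic.py` — genome/read simulation and the toy fixture
- `src/vmusdbg/io.py`, `pipeline.py`, `cli.py` — formats, driver, CLI
- `docs/methods.md` — modelling choices, parameters, and limitations
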
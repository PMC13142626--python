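# Methods

## Anchor extraction

A minimum unique substring (MUS) of a scope text occurs exactly once in
scope while its proper prefix and proper suffix each occur at least twice;
single-character unique substrings count as minimal by convention (their
proper affixes are empty). Two consequences shape everything downstream:
at most one MUS starts at any position, and no MUS is a substring of
another (uniqueness is inherited by superstrings, so a nested unique word
would contradict minimality). Anchors are therefore prefix-free, which
makes per-read occurrence lists totally ordered by start position.

Uniqueness scope is configurable:

- **genome** — counts are taken over a single reference text. With
  `circular=True` the text is doubled and only match starts inside the
  first copy are counted, so wrap-around occurrences are seen exactly once.
  The worked 10 bp example only reproduces its published anchor set under
  circular counting: linearly, `CA` (position 9) is unique and `GCA` fails
  left-minimality because its suffix `CA` is unique; circularly `CA` also
  matches across the origin and the published set falls out.
- **reads** — counts are taken across every read (a word is an anchor if it
  occurs once in the entire set). This follows the definition literally,
  but note that at meaningful coverage depth almost nothing is unique
  across a read set; the genome scope is the operating mode for all worked
  examples, and the reads scope is provided as a best-effort reading.
- `use_reverse_complement=True` adds reverse-complement counting (a word
  and its reverse complement are the same object on two strands). Default
  off: the worked example is forward-only.

Extraction finds, per start position, the shortest unique substring by
binary search on length (occurrence counts are monotone non-increasing in
length), then filters on left-minimality. Three occurrence-counting
backends are interchangeable and tested for exact agreement: direct string
scanning (the oracle), a suffix array (numpy prefix doubling, O(n log² n)
construction, O(|w| log n) queries), and a compressed suffix tree with
subtree leaf counts (naive suffix insertion, O(n²) worst case). These are
desk-scale choices: the package targets kilobase genomes and read sets,
not chromosome-scale indexes.

Maximal repeats (≥ 2 occurrences, extendable on neither side at all
occurrences) are enumerated as LCP-interval words with a left-maximality
check on preceding characters. The occurrence threshold is ≥ 2, which is
what makes the two-copy `GC` repeat of the worked example a maximal repeat.

## Graph construction

Rules are applied per read in occurrence order (prefix, internal, suffix;
see README for the definitions). Decisions on under-specified corners:

- Reads with no anchor occurrence contribute nothing and are counted.
- A read with a single occurrence still triggers the applicable terminal
  rules; if it exactly spans its anchor it contributes node presence only.
- The suffix tag is the uncovered trailing substring (not the whole read,
  which would duplicate covered sequence and break spelling).
- Instance lists keep insertion order (read input order, then position);
  flows and best-instance selection are order-independent, so rebuilding
  from a shuffled read set yields an equal graph.
- Self-loops and repeated anchors within one read are handled by the
  ordinary consecutive-pair rule; nothing assumes per-read uniqueness.

Node metadata P(u) records the longest prefix/suffix context observed for
each node, plus global maxima at the terminals. Terminal nodes are named
`FIRST_NODE` / `LAST_NODE`, which cannot collide with anchor words.

## Simplification

A node is strictly linear when its distinct in/out neighbour counts and
total in/out flows are all 1. Collapsing removes it and merges its two
instances into (δ₁+δ₂, τ₁·v·τ₂). The literal flow-1 condition is kept
(chains with higher flow are left to traversal). Nodes are processed in
lexicographic order to a fixed point; the operation is confluent, so the
order only stabilizes serialization. A collapse candidate involved in a
self-loop is skipped — the merge formula presumes three distinct nodes.

Merged instances keep references to their sources (`parts`). This matters
for spelling: the concatenated tag τ₁·v·τ₂ over-counts sequence whenever
the source transitions overlapped (δ ≤ |word|), so spelling always expands
merged instances back to raw hops instead of trusting merged tags. The
collapse records exported as TSV are an audit trail of the same
information.

## Traversal and contigs

Junctions are terminals and nodes whose distinct-neighbour counts differ
from one. Unitig extraction starts one path per (junction, distinct
successor) with at least one unused instance, walks interior 1-in-1-out
nodes consuming the best unused instance per hop, and stops at the next
junction. Each instance is used at most once; surplus parallel instances
are reported rather than forced into duplicate paths. Junction-free cycles
are emitted as circular unitigs anchored at their lexicographically
smallest node — otherwise their sequence would be lost silently.

Best-instance selection: internal edges minimize δ (repeat transitions
with detours lose to the direct adjacency), terminal edges maximize |τ|
(keep the longest observed overhang); residual ties break on the other
component, then lexicographic τ, then read id, making traversal fully
deterministic.

Every read boundary injects terminal edges, which makes interior anchors
junctions and would shred even a perfectly covered genome into read-scale
unitigs. Final contig assembly therefore chains unitigs: at a junction
with exactly one unitig entering through an anchor-to-anchor edge and
exactly one leaving through one, the pair is concatenated. Terminal-edge
stubs (leading/trailing read overhangs) never chain and surface as short
contigs that are genuine substrings of the genome. A chain that returns to
its first unitig closes into a circular contig; on a fully covered
circular genome the anchor adjacency is a single cycle (anchors are unique
loci and anchor intervals cannot nest, so error-free reads cannot skip an
anchor), and the assembly returns exactly one circular contig equal to a
rotation of the genome.

Spelling follows the overlap arithmetic φ = |seq(u)| − δ per raw hop:
suffix of the next anchor when φ > 0, the whole anchor when φ = 0, tag
plus anchor when φ < 0 (the tag length must equal the gap, enforced).
φ > |seq(v)| is reported as a hard error naming the hop — it indicates a
construction bug, not data to be clamped. Circular paths are spelled by
one extra hop back to the start node and trimmed to Σδ characters, with a
wrap-consistency check. A terminal hop into the sink appends its tag
verbatim, mirroring the source-side base case.

N50 is the largest L such that contigs of length ≥ L sum to at least half
the total assembly length. Alignment-based metrics (NA50, genome fraction,
duplication ratio) need a reference aligner and are out of scope; the
duplication a repeat-aware graph preserves by design is visible here as
unused parallel instances rather than duplicated contigs, because
traversal uses each instance at most once.

## Synthetic data

The generator emulates the regime the model assumes: error-free reads with
uniform starts (wrapping on circular genomes) over a random background
with optional planted exact repeats. Defaults — 2 kb circular genome, 20×
coverage, 200 bp reads — are the recovery-test conditions and give every
anchor adjacency deep support while staying near-instant to assemble; read
counts are coverage·|G|/ℓ, so empirical coverage concentrates within a few
percent of the request. A substitution-rate hook exists (default 0) but
there is no realistic error model: a single substitution can destroy or
forge uniqueness, and the model's robustness to errors is untested here.
Passing recovery tests therefore demonstrates correctness of the graph
machinery on clean data, not performance on real sequencing error
profiles, uneven coverage, or genomes whose repeat structure exceeds the
read length.

## Known limitations

- Reads-scope extraction at realistic coverage yields very few anchors;
  the genome scope (with a reference or a draft) is the practical mode.
- All indexes are in-memory and desk-scale; no attempt at succinct data
  structures.
- No error correction, tip clipping, bubble popping, or coverage-based
  filtering: none belong to the model as specified.
- Chaining resolves only junctions whose anchor-level continuation is
  unique; genuine repeat branches are left unresolved by design, so
  repeat-rich genomes fragment at repeat boundaries.
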
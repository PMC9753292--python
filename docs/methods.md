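# Methods

This note documents the models, conventions and numerical choices behind
scafkit, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the problem was genuinely open.

## Coordinates and formats

All in-memory coordinates are 0-based half-open, on the forward strand of
the query (the PAF convention). The two formats that disagree convert at
the I/O boundary: AGP v2.1 (1-based inclusive) and MUMmer delta (1-based
inclusive, reverse alignments encoded as a descending query interval).
Keeping one internal convention eliminates an entire class of off-by-one
errors; the AGP reader/writer and the delta parser are the only places
that add or subtract 1. Sequence case is preserved on output but carries
no meaning (soft-masking is metadata, not sequence).

`nx_statistics(lengths, x)` is the standard nX: sort descending,
accumulate, and report the length at which the cumulative sum first
reaches x% of the total. A small epsilon (1e-9) guards the floating-point
percentage comparison.

## Alignment filtering and merging

Unique-anchor filtering processes each query's alignments in decreasing
aligned-length order; an alignment survives only if it contributes at
least `min_unique_anchor` bp of query territory not covered by previously
accepted alignments. The default anchor length is 10 kbp, the canonical
Assemblytics setting; the processing order (strongest first) is a design
choice — it lets the dominant alignment claim territory before repetitive
echoes are considered.

Merging walks each query's alignments sorted by `(ref_id, ref_start,
ref_end)`. An alignment joins the current block iff same reference, same
strand, and the reference-coordinate separation — gap length between the
intervals, with overlap counting as zero — is **≤ d** (default 100 kbp).
The inclusive boundary is a deliberate, tested convention. Finally, blocks
contained within other blocks on the query axis are removed; for identical
intervals the block with more aligned bp wins, then the lexicographically
smaller identity key. Containment is only ever compared between blocks on
the same sequence of the relevant axis.

## Correction

A query with ≥ 2 merged blocks is a misassembly candidate. The break
coordinate between consecutive blocks is the **midpoint of the
inter-block query interval**; when blocks abut this degenerates to the
shared coordinate, and when they overlap it is the midpoint of the
overlap. The exact coordinate within the uncertain interval is
unknowable from homology alone; the midpoint is the symmetric choice.

Suppression rules, in order: a candidate within `terminus_margin`
(default 5 kbp) of either sequence end is suppressed; a candidate inside
a protected annotation interval is suppressed; `mode` restricts
candidacy to boundaries between blocks on the same (`intra`) or
different (`inter`) reference sequences. Coverage validation is opt-in:
with depth bounds set, a break survives only if some base in the
**closed** window `[pos − v, pos + v]` (default v = 10 kbp, clamped at
sequence ends) is below `min_cov` or above `max_cov`; otherwise the
boundary is attributed to genuine structural variation and suppressed.
Without read evidence all candidates stay applied. Read alignment itself
is out of scope — the module consumes a per-base depth array, with a
small adapter that builds one from placement intervals.

Fragments are named `<id>:<start>-<end>` (0-based half-open), and the
emitted AGP maps them back to source coordinates, so breaking is lossless
and reversible.

## Scaffolding

Confidence scores, all in [0, 1]:

- **grouping** — aligned bp to the best reference sequence over total
  aligned bp;
- **orientation** — majority-strand bp within the best reference over
  best-reference bp;
- **location** — bp of best-reference blocks overlapping the primary
  block's reference interval (itself included) over best-reference bp.

These ratio definitions are scafkit's own (the lineage tools describe the
scores qualitatively); they are scale-invariant and each equals 1 for a
query aligning to a single locus. Default thresholds are permissive —
grouping 0.2, location 0.0, orientation 0.0 — and exposed as flags, so by
default only grossly ambiguous queries are excluded.

The *primary* block is the one with the largest query span (ties: more
aligned bp, then leftmost reference start). Primaries contained within
other primaries on the same reference are removed, demoting those queries
to unplaced. Order ties at equal reference start go to the longer primary,
then the lexicographically smaller query id.

Gap inference evaluates
`(aln2_rs − aln2_qs) − (aln1_re + len(seq1) − aln1_qe)` on the two
primaries. For a `-`-oriented placement the primary's query interval is
mirrored (`qs' = L − qe`) first, so the formula always sees
scaffold-oriented coordinates — this also defines the behavior for
mixed-orientation neighbours. An inferred size below `max(min_gap, 1)`
or above `max_gap` (defaults 1 bp and 100 kbp) is replaced by the 100-bp
unknown placeholder, written as an AGP `U` row; retained sizes become `N`
rows. The hard 1-bp floor is part of the model: a non-positive gap is not
a gap. Homology-evidenced gaps carry evidence `align_genus`.

## The scaffold graph and its solver

Nodes are sequence termini (two per sequence); edges join termini of
distinct sequences and carry nonnegative weights plus provenance metadata
(original gap, patch filler, AGP support, Hi-C score). "Maximal weight
matching" is implemented as a true maximum-weight matching (networkx's
blossom algorithm) — the global optimum, verified in tests against an
exhaustive oracle on all graphs up to 8 sequences. Matched edges overlaid
on the implicit begin–end pairing of each sequence give components that
are paths or cycles; each cycle is broken by deleting its minimum-weight
matched edge (ties: lexicographically smallest edge key) — the
least-supported adjacency is the one to sacrifice. Chains are read off by
walking paths; entering a sequence at its *end* terminus means it is
carried reverse-complemented. Chain direction is canonicalized
(lexicographically smaller of the two traversals) so results are
reproducible run to run. Integral weights compare exactly; float weights
(Hi-C scores) only ever feed the matching and the cycle minimum, where
exact ties are broken by edge key.

## Patching

Targets are split at N runs; seqlets keep the parent name when gapless,
else `<id>:<start>-<end>`. Original adjacencies seed the graph as gap
edges. Filters on query-vs-seqlet blocks: target span ≥ `min_block_len`
(50 kbp) and within `terminus_distance` (default 10 kbp — a chosen,
exposed default) of a seqlet terminus; blocks interior to their query
that reach no seqlet terminus imply a containment the alignment does not
cover and are discarded. The terminus test uses merged-block coordinates
(not individual members).

Per query, blocks sorted by query position contribute one edge per
consecutive seqlet pair. The edge's terminus sides encode direction: a
`+` block is exited at the seqlet *end* and entered at *begin*, a `-`
block the reverse, so strand-discordant joins naturally connect like
sides. The edge stores the inter-block query interval; a negative
interval records an overlap. Query support **replaces** gap metadata on
an existing edge (the gap gets filled); an adjacency supported by more
than one alignment pair is deleted outright, including any gap
provenance — ambiguity is disqualifying.

Edge weights are a prior, not an evidence scale: gap edges weigh 10
(the adjacency existed in the input and should only be abandoned for
cause), query edges 1, and a filled gap 11. Any positive separation
would do; the chosen constants make gap retention dominate every
realistic conflict among single-alignment query edges.

Synthesis walks each chain: seqlet sequences (reverse-complemented as
oriented), query fillers (reverse-complemented when the chain traverses
the edge against its query-forward direction), N runs for unfilled gap
edges. An overlap trims the start of the downstream seqlet in traversal
orientation — the upstream copy of the duplicated sequence wins; the
symmetric choice is equally defensible and this one is fixed and tested.
A chain that reproduces an original target exactly keeps its name, which
makes empty-query patching the identity; composite chains are named
`scf<NNNNN>`. A join report records, per query-filled join, the source
coordinates of both flanks and the filler. An optional
`max_filler_len` guard can discard implausibly long fillers (misassembled
queries); no automatic misassembly detection is claimed.

## Merging

All input AGPs must order and orient the same component set (checked; the
symmetric difference is reported). Components shorter than
`min_component_len` (default 100 kbp) are unmergeable singletons;
adjacency is **not** bridged across a dropped component, because bridging
would put an adjacency in the output that no input asserted. Each source
adds its weight (default 1) to the edge for every adjacent oriented
component pair.

Hi-C re-weighting **replaces** the vote weights: for edge (t1, t2),
`h = links / max(1, sites(t1) + sites(t2))`, where links counts contacts
with one end in each terminus's terminal window and sites counts
restriction-motif matches (forward strand, overlaps allowed; default the
Arima motif set GATC, GA[ATCG]TC, CT[ATCG]AG, TTAA) in those windows. The
terminal window defaults to `min(component_length / 2, 1 Mbp)` per
component — large enough to capture proximity-ligation signal, never
overlapping from both ends. The normalization and window default are this
package's concrete rendering of SALSA2-style scoring; both are
configurable. Re-weighting applies uniformly to all edges, including
gap-derived ones.

Merged chains become AGP objects with 100-bp unknown gaps (evidence
`proximity_ligation` when Hi-C-weighted, else `align_genus`); input gap
sizes are deliberately not propagated, since a merged adjacency has no
single size evidence. Unmerged components pass through unchanged. Output
contiguity can therefore be lower than the best single input whenever
inputs conflict — conservatism is the intended behavior, and the
idempotence/conservatism properties are tested.

## Synthetic data

`simulate_genome` draws i.i.d. uniform ACGT chromosomes, optionally
implanting duplicated 1–5 kbp segments to a target repeat fraction.
`fragment_assembly` cuts chromosomes into fragments uniform in
[N50/2, 3·N50/2] (chromosome-end slivers are absorbed into the last
fragment); junctions become either an intra-contig N run that replaces
the underlying bases (rate `gap_rate`, lengths 50–500 bp) or a contig
break with a deleted spacer drawn from `inter_contig_bp`; contigs fuse
across chromosomes at rate `misassembly_rate` and are flipped with
probability 0.5 by default. Every event is logged and the truth AGP both
validates and reconstructs the genome outside gap bases.
`simulate_hic_pairs` draws contact separations exponentially (mean
`decay_bp`) on the truth genome and maps endpoints into contig
coordinates, rejecting pairs that land in deleted regions.

What this does *not* emulate: sequencing error, heterozygosity and
haplotypic duplication, biologically realistic repeat families,
GC/mappability bias in Hi-C coverage, and aligner-induced coordinate
jitter. Exact alignments derived from the truth layout make the
end-to-end tests sharp (recovery and patch-coordinate distance can be
required to be exact); on real data, aligner noise at repeat boundaries
shifts coordinates by construction-dependent amounts, so exactness there
demonstrates the algorithms, not the robustness of any aligner.

Problem sizes in the test suite — 2 × 5 Mbp for scaffold recovery,
~0.3–1.5 Mbp elsewhere, 200 solver-oracle trials at ≤ 8 sequences — were
chosen so every property is exercised end-to-end with sub-minute wall
times; all recovery results are size-independent in the exact-alignment
regime.

The contig-screening classifier and the Euclidean patch distance are pure
evaluation functions over their inputs (coverage fractions; coordinate
vectors). Building the screening databases and running the underlying
aligners/BLAST is out of scope. The rDNA exemption is evaluated first and
shields a putative rDNA contig from all three removal rules.

## Known limitations

- `correct` places breaks at interval midpoints; with sparse alignments
  the true breakpoint may sit anywhere in the inter-block interval.
- `patch` trusts single-alignment adjacencies; a chimeric query
  contiguous across two loci produces a confident false join (the guard
  flag bounds filler length but cannot detect the chimera).
- `merge` treats AGP votes as independent; correlated inputs (two
  scaffolds derived from the same reference) double-count their shared
  biases. Use the minimal informative set of inputs.
- Hi-C scoring normalizes by restriction sites only; no coverage or
  length bias correction is applied.
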
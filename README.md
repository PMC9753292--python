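# scafkit

Homology-based genome assembly improvement: misassembly **correction**,
reference-guided **scaffolding**, gapless **patching**, and reconciliation
(**merging**) of multiple scaffolding solutions, with optional Hi-C
re-weighting of adjacency evidence.

scafkit is for assembly practitioners who have a draft genome (contigs)
plus some combination of: a related reference genome, a second assembly of
the same sample from a complementary technology, several candidate
scaffolding solutions in AGP format, and/or Hi-C read pairs. It turns those
into chromosome-scale scaffolds while staying conservative where the
evidence disagrees. Everything is exercisable on synthetic assemblies
generated by the built-in `fixtures` module; no external data is required
to test or demo the tool.

## The core machinery

**Alignment filtering and macro-synteny blocks.** Pairwise whole-genome
alignments (PAF or MUMmer delta) are filtered by unique-anchor coverage
(an alignment must contribute ≥ 10 kbp of query territory not claimed by a
stronger alignment) and optionally by mapping quality. Per query, sorted by
reference position, consecutive same-strand alignments within *d* = 100 kbp
are merged into blocks spanning min-start to max-end; blocks nested inside
other blocks on the query axis are dropped.

**Scaffolding.** Each query contig is assigned to the reference sequence
attracting most of its aligned bp and scored with three confidence ratios
(grouping, location, orientation) in [0, 1]. Its longest merged block is
the *primary* alignment: primaries ordered by reference coordinate give
contig order, and the primary's strand gives orientation. Adjacent contigs
are separated by 100-bp unknown gaps, or by inferred sizes

```
gapsize = (aln2_rs − aln2_qs) − (aln1_re + len(seq1) − aln1_qe)
```

where `rs/re/qs/qe` are reference/query start/end of the two primaries.
Inferred sizes below 1 bp (or a configured minimum `-g`) or above `-m`
fall back to the 100-bp unknown placeholder.

**The scaffold graph.** Correction of ambiguous adjacency evidence is a
matching problem: each sequence contributes *begin* and *end* terminus
nodes, weighted edges join termini of distinct sequences, and a
maximum-weight matching (networkx) overlaid on the implicit intra-sequence
pairings yields chains; cycles are broken at their weakest edge. Both
`patch` and `merge` solve this same structure.

**Patching.** The target assembly is split at N runs into *seqlets*;
original gap adjacencies seed the graph. Query contigs aligning across two
seqlet ends contribute edges carrying the intervening query interval — the
sequence that bridges the join without introducing any N. Blocks shorter
than 50 kbp or far (> 10 kbp) from a seqlet terminus are ignored, and an
adjacency claimed by more than one alignment pair is discarded as
ambiguous. Gaps no query could fill are re-emitted verbatim, so patching
with an empty query is the identity.

**Merging.** Each input AGP votes for its component adjacencies with its
source weight (1 by default), CAMSA-style. Optionally the votes are
replaced by Hi-C scores: contacts linking two terminal windows, normalized
by the restriction-site count of those windows (SALSA2-style). The solved
graph becomes one merged AGP; components the inputs disagree on fall out
as singletons, so the merge never invents an adjacency absent from every
input.

## Worked example

Simulate a 2 × 2 Mbp genome, shatter it into contigs with random
orientations and deleted inter-contig spacers, realign, and scaffold with
inferred gap sizes:

```python
from scafkit import fixtures as fx
from scafkit.formats_io import nx_statistics
from scafkit.scaffold import ScaffoldConfig, scaffold_assembly

genome = fx.simulate_genome(seed=1, n_chrom=2, chrom_len=2_000_000)
truth = fx.fragment_assembly(genome, seed=2, target_n50=100_000,
                             inter_contig_bp=(200, 5_000))
agp, fasta, placements, unplaced, report = scaffold_assembly(
    truth.contigs, fx.exact_alignments(truth),
    ScaffoldConfig(gap_policy="inferred"))
print(f"contigs in: {len(truth.contigs)}  placed: {len(placements)}  unplaced: {len(unplaced)}")
print(f"contig N50: {nx_statistics([len(r) for r in truth.contigs.values()], 50):,} bp")
print(f"scaffold N50: {nx_statistics([len(r) for r in fasta], 50):,} bp")
print("first placements:", [(p.query_id, p.ref_id, p.orientation) for p in placements[:3]])
```

prints

```
contigs in: 36  placed: 36  unplaced: 0
contig N50: 119,252 bp
scaffold N50: 2,000,000 bp
first placements: [('ctg00001', 'chr1', '+'), ('ctg00002', 'chr1', '-'), ('ctg00003', 'chr1', '-')]
```

All 36 contigs are placed, every recovered order/orientation matches the
simulation's truth layout, each inferred gap equals the deleted spacer
length, and the two emitted scaffolds are exactly chromosome-sized — the
N50 jumps from the contig 119 kbp to the full 2 Mbp chromosome length.

The same pipelines are available from the shell:

```sh
scafkit sim genome --seed 1 --n-chrom 2 --chrom-len 2000000 -o genome.fasta
scafkit sim fragment genome.fasta --seed 2 -o draft
scafkit stats draft.fasta --x 50
scafkit agpcheck draft.truth.agp
scafkit scaffold --query draft.fasta --alignments aln.paf --infer-gaps
scafkit patch --target hifi.fasta            # writes the gap-split seqlets
scafkit patch --target hifi.fasta --query ont.fasta --alignments aln.paf
scafkit merge contigs.fasta a.agp b.agp -b contacts.tsv
```

(`aln.paf` comes from any whole-genome aligner, e.g.
`minimap2 -x asm5 reference.fasta draft.fasta`.)

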
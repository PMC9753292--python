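"""Shared test helpers: record builders, brute-force oracles, scenario
constructors."""

from __future__ import annotations

from scafkit.alignment_processing import MergedBlock
from scafkit.formats_io import AlignmentRecord, SequenceRecord


def make_aln(
    q="q1",
    qlen=1_000_000,
    qs=0,
    qe=100_000,
    strand="+",
    r="r1",
    rlen=2_000_000,
    rs=0,
    re=100_000,
    matches=None,
    alen=None,
    mapq=60,
):
    alen = alen if alen is not None else qe - qs
    matches = matches if matches is not None else alen
    return AlignmentRecord(q, qlen, qs, qe, strand, r, rlen, rs, re, matches, alen, mapq)


def make_block(
    q="q1",
    r="r1",
    strand="+",
    rs=0,
    re=100_000,
    qs=0,
    qe=100_000,
    bp=None,
    qlen=1_000_000,
    rlen=2_000_000,
):
    bp = bp if bp is not None else qe - qs
    member = make_aln(q, qlen, qs, qe, strand, r, rlen, rs, re, alen=bp)
    return MergedBlock(q, r, strand, rs, re, qs, qe, [member], bp)


def paf_line(a: AlignmentRecord) -> str:
    return "\t".join(
        str(x)
        for x in [
            a.query_id, a.query_len, a.query_start, a.query_end, a.strand,
            a.ref_id, a.ref_len, a.ref_start, a.ref_end, a.num_matches,
            a.aln_len, a.mapq if a.mapq is not None else 255,
        ]
    )


def best_matching_weight(edges):
    """Exhaustive maximum-weight matching over [(node_a, node_b, w), ...]."""
    best = 0.0

    def rec(i, used, total):
        nonlocal best
        best = max(best, total)
        for j in range(i, len(edges)):
            a, b, w = edges[j]
            if a not in used and b not in used:
                rec(j + 1, used | {a, b}, total + w)

    rec(0, frozenset(), 0.0)
    return best


def build_patch_scenario(seed: int, n_junctions: int = 4, flank: int = 55_000):
    """A target broken at alternating gap/split junctions plus a query
    assembly contiguous across every junction, with exact alignments.

    Even junctions delete 200 bp and leave an N run inside one target
    sequence; odd junctions split the target with no deletion.  Each query
    is the contiguous genome slice spanning one junction with ``flank`` bp
    on either side.

    Returns ``(genome_seq, targets, queries, alignments, truth_joins)``;
    ``truth_joins`` maps left-seqlet id -> (left_end, right_start,
    fill_start, fill_end) in the patch join-report convention.
    """
    from scafkit import fixtures as fx
    from scafkit.patch import split_at_gaps

    spacing = 300_000
    L = spacing * (n_junctions + 1)
    genome = fx.simulate_genome(seed, 1, L)["chr1"].sequence

    junctions = [
        (spacing * (j + 1), 200 if j % 2 == 0 else 0) for j in range(n_junctions)
    ]

    # seqlets in genome order: every junction terminates one
    seqlet_bounds = []
    start = 0
    for pos, dlen in junctions:
        seqlet_bounds.append((start, pos))
        start = pos + dlen
    seqlet_bounds.append((start, L))

    # target pieces split at zero-deletion junctions; gap junctions stay
    # inside a piece as an N run
    targets = {}
    parts = []
    piece_start = 0
    n_piece = 0
    for pos, dlen in junctions:
        if dlen > 0:
            parts.append(genome[piece_start:pos] + "N" * dlen)
            piece_start = pos + dlen
        else:
            parts.append(genome[piece_start:pos])
            n_piece += 1
            targets[f"t{n_piece}"] = SequenceRecord(f"t{n_piece}", "".join(parts))
            parts = []
            piece_start = pos
    parts.append(genome[piece_start:L])
    n_piece += 1
    targets[f"t{n_piece}"] = SequenceRecord(f"t{n_piece}", "".join(parts))

    # identify each seqlet's genome interval by content
    seqlets, _ = split_at_gaps(targets)
    ordered = []
    claimed = set()
    for gs, ge in seqlet_bounds:
        segment = genome[gs:ge]
        sid = next(
            s for s in seqlets
            if s not in claimed and seqlets[s].sequence == segment
        )
        claimed.add(sid)
        ordered.append(sid)

    queries = {}
    alignments = []
    truth_joins = {}
    for j, (pos, dlen) in enumerate(junctions):
        qid = f"q{j + 1}"
        qseq = genome[pos - flank : pos + dlen + flank]
        queries[qid] = SequenceRecord(qid, qseq)
        qlen = len(qseq)
        left, right = ordered[j], ordered[j + 1]
        llen, rlen = len(seqlets[left]), len(seqlets[right])
        alignments.append(
            make_aln(qid, qlen, 0, flank, "+", left, llen, llen - flank, llen)
        )
        alignments.append(
            make_aln(qid, qlen, flank + dlen, qlen, "+", right, rlen, 0, flank)
        )
        truth_joins[left] = (llen, 0, flank, flank + dlen)
    return genome, targets, queries, alignments, truth_joins
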
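"""Reference-guided ordering and orienting of query sequences.

Each query is assigned to the reference sequence attracting most of its
aligned bp, scored with grouping / location / orientation confidences,
and placed along that reference at the position of its *primary* (longest)
macro-synteny block, inheriting the primary's strand.  Adjacent placements
are separated by 100-bp unknown gaps by default, or by gap sizes inferred
from the primary-alignment coordinates:

    gapsize = (aln2_rs - aln2_qs) - (aln1_re + len(seq1) - aln1_qe)

where aln1/aln2 are the primary alignments of the upstream/downstream
sequences (query coordinates flipped to scaffold orientation for '-'
placements).  Inferred sizes below the minimum (at least 1 bp) or above
the maximum are replaced with the 100-bp unknown placeholder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Mapping, Sequence

from .alignment_processing import (
    FilterConfig,
    MergedBlock,
    blocks_by_query,
    process_alignments,
    remove_contained,
)
from .formats_io import (
    AgpComponent,
    AgpGap,
    AgpObject,
    SequenceRecord,
    build_fasta_from_agp,
)

HOMOLOGY_EVIDENCE = "align_genus"
UNKNOWN_GAP_LEN = 100


@dataclass
class ConfidenceScores:
    grouping: float
    location: float
    orientation: float


@dataclass
class Placement:
    query_id: str
    ref_id: str
    order_index: int
    orientation: str
    primary_block: MergedBlock
    confidences: ConfidenceScores


@dataclass
class ScaffoldConfig:
    """Scaffolding thresholds and gap policy.

    min_grouping / min_location / min_orientation
        Confidence cutoffs in [0, 1]; a query failing any is left unplaced.
        Defaults are permissive (0.2 / 0.0 / 0.0).
    gap_policy
        "fixed_100" places 100-bp unknown gaps; "inferred" sizes gaps from
        primary-alignment coordinates.
    min_gap / max_gap
        Bounds on inferred sizes; out-of-bounds sizes fall back to the
        100-bp unknown placeholder.  Inferred gaps are never smaller than
        1 bp regardless of min_gap.
    min_contig_len
        Queries shorter than this are not considered for placement.
    excluded_refs
        Reference sequences that never inform scaffolding.
    """

    min_grouping: float = 0.2
    min_location: float = 0.0
    min_orientation: float = 0.0
    gap_policy: str = "fixed_100"
    min_gap: int = 1
    max_gap: int = 100_000
    min_contig_len: int = 0
    concat_unplaced: bool = False
    excluded_refs: frozenset = frozenset()


@dataclass
class GapEstimate:
    size: int
    known: bool


def _best_ref(blocks: Sequence[MergedBlock]) -> str:
    per_ref: dict = {}
    for b in blocks:
        per_ref[b.ref_id] = per_ref.get(b.ref_id, 0) + b.total_aln_bp
    return min(per_ref, key=lambda r: (-per_ref[r], r))


def _primary(blocks: Sequence[MergedBlock]) -> MergedBlock:
    """Longest block: largest query span, ties by total aligned bp then
    leftmost reference start."""
    return max(blocks, key=lambda b: (b.query_span, b.total_aln_bp, -b.ref_start))


def compute_confidences(blocks: Sequence[MergedBlock]) -> ConfidenceScores:
    """Grouping, location and orientation confidence ratios for one query.

    grouping: aligned bp to the best reference sequence / total aligned bp.
    orientation: majority-strand bp within the best reference / best-ref bp.
    location: bp of best-ref blocks overlapping the primary block's
    reference interval (itself included) / best-ref bp.
    """
    if not blocks:
        raise ValueError("compute_confidences requires at least one block")
    total = sum(b.total_aln_bp for b in blocks)
    best = _best_ref(blocks)
    ref_blocks = [b for b in blocks if b.ref_id == best]
    best_bp = sum(b.total_aln_bp for b in ref_blocks)
    strand_bp = {"+": 0, "-": 0}
    for b in ref_blocks:
        strand_bp[b.strand] += b.total_aln_bp
    primary = _primary(ref_blocks)
    loc_bp = sum(
        b.total_aln_bp
        for b in ref_blocks
        if b.ref_start < primary.ref_end and primary.ref_start < b.ref_end
    )
    return ConfidenceScores(
        grouping=best_bp / total,
        location=loc_bp / best_bp,
        orientation=max(strand_bp.values()) / best_bp,
    )


def place_queries(
    blocks: Mapping[str, Sequence[MergedBlock]],
    query_lengths: Mapping[str, int],
    cfg: ScaffoldConfig | None = None,
) -> tuple:
    """Assign queries to reference groups, order and orient them.

    Returns ``(placements, unplaced_ids)``.  A query is unplaced when it
    has no (post-exclusion) blocks, is shorter than ``min_contig_len``,
    fails a confidence threshold, or its primary alignment is contained
    within another query's primary on the reference axis.
    """
    cfg = cfg or ScaffoldConfig()
    candidates = []  # (qid, ref, primary, confidences)
    unplaced = []
    for qid in sorted(query_lengths):
        qblocks = [
            b for b in blocks.get(qid, []) if b.ref_id not in cfg.excluded_refs
        ]
        if query_lengths[qid] < cfg.min_contig_len or not qblocks:
            unplaced.append(qid)
            continue
        conf = compute_confidences(qblocks)
        if (
            conf.grouping < cfg.min_grouping
            or conf.location < cfg.min_location
            or conf.orientation < cfg.min_orientation
        ):
            unplaced.append(qid)
            continue
        best = _best_ref(qblocks)
        primary = _primary([b for b in qblocks if b.ref_id == best])
        candidates.append((qid, best, primary, conf))

    kept_primaries = {
        id(p) for p in remove_contained([p for _, _, p, _ in candidates], "reference")
    }
    placements = []
    by_ref: dict = {}
    for qid, ref, primary, conf in candidates:
        if id(primary) not in kept_primaries:
            unplaced.append(qid)
            continue
        by_ref.setdefault(ref, []).append((qid, primary, conf))
    for ref in sorted(by_ref):
        ordered = sorted(
            by_ref[ref], key=lambda t: (t[1].ref_start, -t[1].query_span, t[0])
        )
        for idx, (qid, primary, conf) in enumerate(ordered):
            placements.append(
                Placement(qid, ref, idx, primary.strand, primary, conf)
            )
    return placements, sorted(unplaced)


def oriented_primary(placement: Placement, query_len: int) -> SimpleNamespace:
    """Primary-alignment coordinates flipped to scaffold orientation.

    For '-' placements the query interval is mirrored (qs' = L - qe) so the
    gap-size formula sees orientation-adjusted coordinates.
    """
    b = placement.primary_block
    if placement.orientation == "+":
        qs, qe = b.query_start, b.query_end
    else:
        qs, qe = query_len - b.query_end, query_len - b.query_start
    return SimpleNamespace(
        ref_start=b.ref_start, ref_end=b.ref_end, query_start=qs, query_end=qe
    )


def infer_gap_size(aln1, aln2, len_seq1: int, g: int = 1, m: int = 100_000) -> GapEstimate:
    """Gap size between adjacent placements from their primary alignments.

    ``aln1``/``aln2`` expose ref_start/ref_end/query_start/query_end in
    orientation-adjusted coordinates (see :func:`oriented_primary`).
    Sizes below ``max(g, 1)`` or above ``m`` become the 100-bp unknown
    placeholder.
    """
    size = (aln2.ref_start - aln2.query_start) - (
        aln1.ref_end + len_seq1 - aln1.query_end
    )
    if size < max(g, 1) or size > m:
        return GapEstimate(UNKNOWN_GAP_LEN, False)
    return GapEstimate(size, True)


def emit_scaffolds(
    placements: Sequence[Placement],
    unplaced: Sequence[str],
    queries: Mapping[str, SequenceRecord],
    cfg: ScaffoldConfig | None = None,
) -> tuple:
    """Render placements as AGP objects + scaffold sequences.

    One object per reference group (named ``<ref>_scaffold``); unplaced
    queries come out as singleton objects, or concatenated into one
    ``unplaced_scaffold`` object when ``concat_unplaced``.
    Returns ``(agp_objects, fasta_records, report_rows)``.
    """
    cfg = cfg or ScaffoldConfig()
    agp = []
    report = []
    by_ref: dict = {}
    for p in placements:
        by_ref.setdefault(p.ref_id, []).append(p)
    for ref in sorted(by_ref):
        group = sorted(by_ref[ref], key=lambda p: p.order_index)
        rows = []
        pos = 0
        part = 0
        for i, p in enumerate(group):
            qlen = len(queries[p.query_id])
            if i > 0:
                prev = group[i - 1]
                if cfg.gap_policy == "inferred":
                    prev_len = len(queries[prev.query_id])
                    est = infer_gap_size(
                        oriented_primary(prev, prev_len),
                        oriented_primary(p, qlen),
                        prev_len,
                        cfg.min_gap,
                        cfg.max_gap,
                    )
                else:
                    est = GapEstimate(UNKNOWN_GAP_LEN, False)
                part += 1
                rows.append(
                    AgpGap(
                        pos + 1, pos + est.size, part, est.size,
                        "scaffold", "yes", HOMOLOGY_EVIDENCE, known=est.known,
                    )
                )
                pos += est.size
            part += 1
            rows.append(
                AgpComponent(pos + 1, pos + qlen, part, p.query_id, 1, qlen, p.orientation)
            )
            pos += qlen
            report.append(
                {
                    "query": p.query_id,
                    "ref": ref,
                    "order": p.order_index,
                    "strand": p.orientation,
                    "grouping": p.confidences.grouping,
                    "location": p.confidences.location,
                    "orientation": p.confidences.orientation,
                }
            )
        agp.append(AgpObject(f"{ref}_scaffold", rows))

    if cfg.concat_unplaced and unplaced:
        rows = []
        pos = 0
        part = 0
        for i, qid in enumerate(unplaced):
            qlen = len(queries[qid])
            if i > 0:
                part += 1
                rows.append(
                    AgpGap(
                        pos + 1, pos + UNKNOWN_GAP_LEN, part, UNKNOWN_GAP_LEN,
                        "scaffold", "no", "na", known=False,
                    )
                )
                pos += UNKNOWN_GAP_LEN
            part += 1
            rows.append(AgpComponent(pos + 1, pos + qlen, part, qid, 1, qlen, "+"))
            pos += qlen
        agp.append(AgpObject("unplaced_scaffold", rows))
    else:
        for qid in unplaced:
            qlen = len(queries[qid])
            agp.append(AgpObject(qid, [AgpComponent(1, qlen, 1, qid, 1, qlen, "+")]))

    fasta = build_fasta_from_agp(agp, queries)
    return agp, fasta, report


def scaffold_assembly(
    query_seqs: Mapping[str, SequenceRecord],
    alignments: Sequence,
    cfg: ScaffoldConfig | None = None,
    filter_cfg: FilterConfig | None = None,
) -> tuple:
    """Full scaffolding pipeline from raw alignments to AGP + FASTA.

    Returns ``(agp, fasta, placements, unplaced, report)``.
    """
    cfg = cfg or ScaffoldConfig()
    merged = process_alignments(alignments, filter_cfg)
    lengths = {qid: len(rec) for qid, rec in query_seqs.items()}
    placements, unplaced = place_queries(blocks_by_query(merged), lengths, cfg)
    agp, fasta, report = emit_scaffolds(placements, unplaced, query_seqs, cfg)
    return agp, fasta, placements, unplaced, report
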
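"""Whole-genome alignment filtering and macro-synteny block merging.

Pairwise alignments of a query assembly against a reference (or target)
assembly are first filtered — unique-anchor filtering to suppress
repetitive alignments, plus an optional mapping-quality cutoff — and then
merged into macro-synteny blocks: per query, alignments are sorted by
reference position and consecutive same-strand alignments to the same
reference sequence within ``merge_distance`` bp of each other are fused,
taking the minimum coordinate as the new start and the maximum as the new
end.  Merged blocks contained within other merged blocks on the query axis
are finally removed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats_io import AlignmentRecord


@dataclass
class FilterConfig:
    """Alignment filtering/merging knobs.

    merge_distance
        Maximum reference-coordinate gap (bp) between consecutive
        same-strand alignments fused into one block (default 100 kbp).
        Separation is measured as gap length between reference intervals
        (overlap counts as 0) and the bound is inclusive.
    min_mapq
        Drop alignments with mapping quality below this; alignments with
        no mapping quality (delta input) always pass.  ``None`` disables.
    min_unique_anchor
        Minimum novel query bp an alignment must contribute to be kept by
        unique-anchor filtering (default 10 kbp, the canonical
        Assemblytics anchor length).
    """

    merge_distance: int = 100_000
    min_mapq: int | None = None
    min_unique_anchor: int = 10_000


@dataclass
class MergedBlock:
    """A macro-synteny block merged from same-strand consecutive alignments."""

    query_id: str
    ref_id: str
    strand: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    members: list = field(default_factory=list)
    total_aln_bp: int = 0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_len(self) -> int:
        return self.members[0].query_len

    def sort_key(self):
        return (self.query_id, self.ref_id, self.strand, self.query_start, self.ref_start)


# ---------------------------------------------------------------------------
# Filters


def _novel_bp(union: list, start: int, end: int) -> int:
    """bp of [start, end) not covered by the sorted disjoint interval union."""
    covered = 0
    i = bisect.bisect_left(union, (start,)) - 1
    if i < 0:
        i = 0
    while i < len(union):
        s, e = union[i]
        if s >= end:
            break
        lo, hi = max(s, start), min(e, end)
        if hi > lo:
            covered += hi - lo
        i += 1
    return (end - start) - covered


def _union_insert(union: list, start: int, end: int) -> None:
    """Insert [start, end) into a sorted disjoint interval union, in place."""
    merged = []
    placed = False
    for s, e in union:
        if e < start or s > end:
            if not placed and s > end:
                merged.append((start, end))
                placed = True
            merged.append((s, e))
        else:
            start, end = min(s, start), max(e, end)
    if not placed:
        merged.append((start, end))
    merged.sort()
    union[:] = merged


def filter_unique_anchor(
    alignments: Sequence[AlignmentRecord],
    min_unique_anchor: int = 10_000,
) -> list:
    """Assemblytics-style unique anchor filtering.

    Per query, alignments are processed in decreasing ``aln_len`` order so
    the strongest alignment claims query territory first; an alignment is
    kept iff its query interval contributes at least ``min_unique_anchor``
    bp not already covered by previously kept alignments of that query.
    Kept alignments are returned in input order.
    """
    by_query: dict = {}
    for idx, a in enumerate(alignments):
        by_query.setdefault(a.query_id, []).append((idx, a))
    kept = set()
    for items in by_query.values():
        union: list = []
        for idx, a in sorted(items, key=lambda t: (-t[1].aln_len, t[0])):
            if _novel_bp(union, a.query_start, a.query_end) >= min_unique_anchor:
                kept.add(idx)
                _union_insert(union, a.query_start, a.query_end)
    return [a for i, a in enumerate(alignments) if i in kept]


def filter_mapq(alignments: Sequence[AlignmentRecord], min_mapq: int | None) -> list:
    """Drop alignments with mapq below the cutoff; missing mapq always passes."""
    if min_mapq is None:
        return list(alignments)
    return [a for a in alignments if a.mapq is None or a.mapq >= min_mapq]


# ---------------------------------------------------------------------------
# Block merging


def merge_blocks(
    alignments: Sequence[AlignmentRecord],
    d: int = 100_000,
) -> list:
    """Merge filtered alignments into macro-synteny blocks.

    Per query, alignments are sorted by reference position; an alignment is
    fused into the current block iff it is on the same reference sequence
    and strand and its reference gap to the block (overlap => 0) is <= d.
    Blocks contained within other blocks on the query axis are removed.
    """
    by_query: dict = {}
    for a in alignments:
        by_query.setdefault(a.query_id, []).append(a)
    out = []
    for qid in sorted(by_query):
        blocks: list = []
        for a in sorted(by_query[qid], key=lambda a: (a.ref_id, a.ref_start, a.ref_end)):
            cur = blocks[-1] if blocks else None
            if (
                cur is not None
                and a.ref_id == cur.ref_id
                and a.strand == cur.strand
                and max(0, a.ref_start - cur.ref_end) <= d
            ):
                cur.ref_start = min(cur.ref_start, a.ref_start)
                cur.ref_end = max(cur.ref_end, a.ref_end)
                cur.query_start = min(cur.query_start, a.query_start)
                cur.query_end = max(cur.query_end, a.query_end)
                cur.members.append(a)
                cur.total_aln_bp += a.aln_len
            else:
                blocks.append(
                    MergedBlock(
                        query_id=qid,
                        ref_id=a.ref_id,
                        strand=a.strand,
                        ref_start=a.ref_start,
                        ref_end=a.ref_end,
                        query_start=a.query_start,
                        query_end=a.query_end,
                        members=[a],
                        total_aln_bp=a.aln_len,
                    )
                )
        out.extend(remove_contained(blocks, axis="query"))
    return out


def _axis_interval(block: MergedBlock, axis: str):
    if axis == "query":
        return block.query_start, block.query_end
    if axis == "reference":
        return block.ref_start, block.ref_end
    raise ValueError(f"unknown axis {axis!r}")


def _axis_group(block: MergedBlock, axis: str) -> str:
    return block.query_id if axis == "query" else block.ref_id


def remove_contained(blocks: Sequence[MergedBlock], axis: str) -> list:
    """Remove blocks contained within other blocks on the chosen axis.

    Containment is only compared between blocks on the same sequence for
    that axis.  Identical intervals keep the block with the larger
    ``total_aln_bp``, then the lexicographically smaller sort key.
    """
    groups: dict = {}
    for b in blocks:
        groups.setdefault(_axis_group(b, axis), []).append(b)
    removed = set()
    for group in groups.values():
        for b in group:
            bs, be = _axis_interval(b, axis)
            for c in group:
                if c is b:
                    continue
                cs, ce = _axis_interval(c, axis)
                if cs <= bs and be <= ce:
                    if (cs, ce) != (bs, be):
                        removed.add(id(b))
                        break
                    if (-c.total_aln_bp, c.sort_key()) < (-b.total_aln_bp, b.sort_key()):
                        removed.add(id(b))
                        break
    return [b for b in blocks if id(b) not in removed]


def blocks_by_query(blocks: Iterable[MergedBlock]) -> dict:
    """Group blocks into ``{query_id: [blocks sorted by query_start]}``."""
    out: dict = {}
    for b in blocks:
        out.setdefault(b.query_id, []).append(b)
    for qid in out:
        out[qid].sort(key=lambda b: (b.query_start, b.query_end))
    return out


def process_alignments(
    alignments: Sequence[AlignmentRecord],
    cfg: FilterConfig | None = None,
) -> list:
    """Standard filter+merge pipeline: mapq filter, unique-anchor filter,
    macro-synteny merging with query-axis containment removal."""
    cfg = cfg or FilterConfig()
    alns = filter_mapq(alignments, cfg.min_mapq)
    alns = filter_unique_anchor(alns, cfg.min_unique_anchor)
    return merge_blocks(alns, cfg.merge_distance)
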
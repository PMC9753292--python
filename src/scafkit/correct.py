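"""Homology-based misassembly detection and query-sequence breaking.

A query assembly is aligned to a reference assembly; any query sequence
with more than one macro-synteny block is a correction candidate, with
putative breakpoints placed at merged-alignment boundaries between
consecutive blocks along the query.  Candidates are suppressed near
sequence termini, inside protected (GFF-annotated) features, or — when a
read-coverage profile is supplied — where read depth within a window of
the breakpoint never strays outside the expected range, which indicates
true structural variation rather than a misassembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .alignment_processing import MergedBlock, blocks_by_query
from .formats_io import (
    AgpComponent,
    AgpObject,
    SequenceRecord,
)

APPLIED = "applied"
SUPPRESSED_TERMINUS = "suppressed_terminus"
SUPPRESSED_FEATURE = "suppressed_feature"
SUPPRESSED_COVERAGE_NORMAL = "suppressed_coverage_normal"


@dataclass
class Candidate:
    position: int
    status: str
    left_ref: str = ""
    right_ref: str = ""


@dataclass
class BreakPlan:
    query_id: str
    candidates: list = field(default_factory=list)

    def applied_positions(self) -> list:
        return sorted(c.position for c in self.candidates if c.status == APPLIED)


@dataclass
class CorrectConfig:
    """Breakpoint policy.

    terminus_margin
        No break within this many bp of either query terminus (default 5 kbp).
    mode
        "intra": only break between blocks mapping to the same reference
        sequence; "inter": only between different reference sequences;
        "both": either (default).
    coverage_window
        Half-width of the closed window around a breakpoint scanned for
        abnormal read depth (default 10 kbp), clamped at sequence ends.
    min_cov / max_cov
        Depth bounds; a break survives coverage validation iff some base in
        the window is below min_cov or above max_cov.  Validation is a
        no-op when both are None (coverage evidence is opt-in).
    protected_features
        ``{query_id: [(start, end), ...]}`` half-open intervals that must
        never contain a break.
    """

    terminus_margin: int = 5_000
    mode: str = "both"
    coverage_window: int = 10_000
    min_cov: float | None = None
    max_cov: float | None = None
    protected_features: Mapping[str, Sequence[tuple]] = field(default_factory=dict)


def propose_breakpoints(
    blocks: Mapping[str, Sequence[MergedBlock]],
    query_lengths: Mapping[str, int],
    cfg: CorrectConfig | None = None,
) -> dict:
    """Candidate breakpoints for every query with >= 2 merged blocks.

    The break coordinate between consecutive blocks is the midpoint of the
    inter-block query interval (which degenerates to the shared coordinate
    when blocks abut).
    """
    cfg = cfg or CorrectConfig()
    if cfg.mode not in ("intra", "inter", "both"):
        raise ValueError(f"unknown mode {cfg.mode!r}")
    trees = {
        qid: IntervalTree.from_tuples((s, e) for s, e in ivs if e > s)
        for qid, ivs in cfg.protected_features.items()
    }
    plans: dict = {}
    for qid in sorted(blocks):
        qblocks = sorted(blocks[qid], key=lambda b: (b.query_start, b.query_end))
        plan = BreakPlan(qid)
        plans[qid] = plan
        if len(qblocks) < 2:
            continue
        qlen = query_lengths[qid]
        for prev, nxt in zip(qblocks, qblocks[1:]):
            if cfg.mode == "intra" and prev.ref_id != nxt.ref_id:
                continue
            if cfg.mode == "inter" and prev.ref_id == nxt.ref_id:
                continue
            pos = (prev.query_end + nxt.query_start) // 2
            pos = min(max(pos, 1), qlen - 1)
            if pos < cfg.terminus_margin or qlen - pos < cfg.terminus_margin:
                status = SUPPRESSED_TERMINUS
            elif qid in trees and trees[qid].overlaps(pos):
                status = SUPPRESSED_FEATURE
            else:
                status = APPLIED
            plan.candidates.append(Candidate(pos, status, prev.ref_id, nxt.ref_id))
    return plans


def coverage_from_intervals(query_len: int, intervals: Sequence[tuple]) -> np.ndarray:
    """Per-base depth from half-open read-placement intervals (an adapter for
    precomputed sorted alignment tables)."""
    depth = np.zeros(query_len, dtype=np.int32)
    for s, e in intervals:
        depth[max(0, s) : min(query_len, e)] += 1
    return depth


def validate_with_coverage(
    plan: BreakPlan,
    profile: np.ndarray,
    query_len: int,
    cfg: CorrectConfig,
) -> BreakPlan:
    """Keep a break applied only if depth within the closed window
    ``[pos - v, pos + v]`` (clamped to the sequence) is exceptionally low
    or high; otherwise mark it suppressed_coverage_normal."""
    if cfg.min_cov is None and cfg.max_cov is None:
        return plan
    if len(profile) != query_len:
        raise ValueError(
            f"coverage profile length {len(profile)} != sequence length {query_len}"
        )
    v = cfg.coverage_window
    for cand in plan.candidates:
        if cand.status != APPLIED:
            continue
        lo = max(0, cand.position - v)
        hi = min(query_len, cand.position + v + 1)
        window = profile[lo:hi]
        abnormal = False
        if cfg.min_cov is not None and (window < cfg.min_cov).any():
            abnormal = True
        if cfg.max_cov is not None and (window > cfg.max_cov).any():
            abnormal = True
        if not abnormal:
            cand.status = SUPPRESSED_COVERAGE_NORMAL
    return plan


def apply_breaks(
    sequences: Mapping[str, SequenceRecord],
    plans: Mapping[str, BreakPlan],
) -> tuple:
    """Split sequences at applied breakpoints.

    Fragments are named ``<id>:<start>-<end>`` with a 0-based half-open
    suffix; unbroken sequences keep their original name.  The returned AGP
    maps every fragment back to its source coordinates.
    """
    out_records = []
    agp = []
    for qid, rec in sequences.items():
        plan = plans.get(qid)
        positions = plan.applied_positions() if plan else []
        qlen = len(rec)
        for pos in positions:
            if not (0 < pos < qlen):
                raise ValueError(f"breakpoint {pos} out of range for {qid} ({qlen} bp)")
        if not positions:
            out_records.append(rec)
            agp.append(
                AgpObject(qid, [AgpComponent(1, qlen, 1, qid, 1, qlen, "+")])
            )
            continue
        bounds = [0] + positions + [qlen]
        rows = []
        for part, (s, e) in enumerate(zip(bounds, bounds[1:]), 1):
            frag_id = f"{qid}:{s}-{e}"
            out_records.append(SequenceRecord(frag_id, rec.sequence[s:e]))
            rows.append(AgpComponent(s + 1, e, part, frag_id, 1, e - s, "+"))
        agp.append(AgpObject(qid, rows))
    return out_records, agp


def correct_assembly(
    query_seqs: Mapping[str, SequenceRecord],
    blocks: Sequence[MergedBlock],
    cfg: CorrectConfig | None = None,
    coverage: Mapping[str, np.ndarray] | None = None,
) -> tuple:
    """Full correction pass: propose, optionally coverage-validate, break.

    Returns ``(corrected records, correction AGP, plans)``.
    """
    cfg = cfg or CorrectConfig()
    lengths = {qid: len(rec) for qid, rec in query_seqs.items()}
    plans = propose_breakpoints(blocks_by_query(blocks), lengths, cfg)
    if coverage is not None:
        for qid, plan in plans.items():
            if qid in coverage:
                validate_with_coverage(plan, coverage[qid], lengths[qid], cfg)
    records, agp = apply_breaks(query_seqs, plans)
    return records, agp, plans
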
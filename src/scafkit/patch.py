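"""Gapless assembly patching: join contigs and fill gaps in a target
assembly with sequence from a query assembly.

The target is first split at its N runs into gap-free *seqlets*, and the
original gap adjacencies seed a directed scaffold graph.  Macro-synteny
blocks of the query against the seqlets are filtered for length and
terminal proximity, then each query that spans two or more seqlets
contributes adjacency edges whose metadata records the inter-block query
interval — the sequence that will bridge the two seqlets without
introducing any N.  Query support replaces gap metadata on an existing
edge (the gap gets filled); an adjacency supported by more than one
alignment pair is discarded as ambiguous.  The graph is solved by
maximum-weight matching and the resulting chains are synthesized into
patched sequences; gap edges that no query replaced re-emit their
original N run, so an empty query leaves the target untouched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .alignment_processing import (
    FilterConfig,
    MergedBlock,
    blocks_by_query,
    process_alignments,
)
from .formats_io import (
    AgpComponent,
    AgpGap,
    AgpObject,
    SequenceRecord,
    revcomp,
)
from .scaffold_graph import (
    BEGIN,
    END,
    GraphSolution,
    ScaffoldGraph,
    Terminus,
    edge_key,
    opposite,
)

# Edge weights are a prior, not evidence strength: original gap adjacencies
# are certain (they existed in the input) so they dominate conflicting
# single-alignment query support in the matching.
GAP_EDGE_WEIGHT = 10.0
QUERY_EDGE_WEIGHT = 1.0

_GAP_RUN = re.compile(r"[Nn]+")


@dataclass
class PatchConfig:
    """Patch alignment filtering.

    terminus_distance
        A merged block must come within this many bp of a seqlet terminus
        to be usable (default 10 kbp).
    min_block_len
        Merged blocks whose target span is shorter than this are removed
        (default 50 kbp).
    max_filler_len
        Optional guard discarding adjacencies whose query filler would
        exceed this many bp (misassembled queries can imply absurd
        fillers); None disables.
    """

    terminus_distance: int = 10_000
    min_block_len: int = 50_000
    max_filler_len: int | None = None


@dataclass
class GapMeta:
    """Edge provenance: an original target gap of known length."""

    length: int


@dataclass
class PatchMeta:
    """Edge provenance: a query segment bridging two seqlets.

    ``fill_start``/``fill_end`` are query-forward coordinates of the
    inter-block interval; ``fill_end < fill_start`` encodes an overlap of
    the flanking seqlets.  ``t_from -> t_to`` is the query-forward
    traversal direction of the edge.
    """

    query_id: str
    fill_start: int
    fill_end: int
    t_from: Terminus
    t_to: Terminus


@dataclass
class GapAdjacency:
    left_id: str
    right_id: str
    gap_length: int
    known: bool = True


@dataclass
class PatchResult:
    records: list
    agp: list
    joins: list
    solution: GraphSolution | None = None


# ---------------------------------------------------------------------------


def split_at_gaps(targets: Mapping[str, SequenceRecord]) -> tuple:
    """Break target sequences at N runs.

    Returns ``(seqlets, registry)``: gap-free pieces named
    ``<id>:<start>-<end>`` (gapless inputs keep their name) and the list of
    original gap adjacencies used to initialize the patch graph.
    """
    seqlets: dict = {}
    registry: list = []
    for tid, rec in targets.items():
        runs = [m.span() for m in _GAP_RUN.finditer(rec.sequence)]
        # trim leading/trailing gap runs: they flank nothing
        pieces = []
        pos = 0
        for s, e in runs:
            if s > pos:
                pieces.append((pos, s))
            pos = e
        if pos < len(rec):
            pieces.append((pos, len(rec)))
        if not pieces:
            continue  # all-N sequence has no seqlets
        if len(pieces) == 1 and pieces[0] == (0, len(rec)):
            seqlets[tid] = rec
            continue
        names = [f"{tid}:{s}-{e}" for s, e in pieces]
        for name, (s, e) in zip(names, pieces):
            seqlets[name] = SequenceRecord(name, rec.sequence[s:e])
        for (ls, le), (rs, re_), lname, rname in zip(
            pieces, pieces[1:], names, names[1:]
        ):
            registry.append(GapAdjacency(lname, rname, rs - le))
    return seqlets, registry


def filter_patch_blocks(
    blocks: Sequence[MergedBlock],
    seqlet_lengths: Mapping[str, int],
    cfg: PatchConfig | None = None,
) -> list:
    """Keep blocks long enough and anchored at a seqlet terminus.

    A block additionally implies the seqlet is contained in the query when
    it sits interior to the query; such a block must then reach a seqlet
    terminus or it is evidence of partial, untrustworthy containment and
    is discarded.
    """
    cfg = cfg or PatchConfig()
    i = cfg.terminus_distance
    kept = []
    for b in blocks:
        tlen = seqlet_lengths[b.ref_id]
        if b.ref_span < cfg.min_block_len:
            continue
        near_target = b.ref_start <= i or (tlen - b.ref_end) <= i
        if not near_target:
            continue
        qlen = b.query_len
        near_both_query = b.query_start <= i and (qlen - b.query_end) <= i
        if not near_both_query and not near_target:
            continue
        kept.append(b)
    return kept


def build_patch_graph(
    seqlets: Mapping[str, SequenceRecord],
    registry: Sequence[GapAdjacency],
    blocks: Sequence[MergedBlock],
    cfg: PatchConfig | None = None,
) -> ScaffoldGraph:
    """Assemble the directed patch graph.

    Gap edges (original adjacencies) go in first; per query, filtered
    blocks sorted by query position add one edge per adjacent seqlet pair,
    carrying the inter-block query interval as filler metadata.  A
    query-supported edge overwrites gap metadata in place; an adjacency
    supported by more than one alignment pair is deleted entirely.
    """
    cfg = cfg or PatchConfig()
    graph = ScaffoldGraph()
    for sid in seqlets:
        graph.add_sequence(sid)
    for adj in registry:
        graph.add_edge(
            Terminus(adj.left_id, END),
            Terminus(adj.right_id, BEGIN),
            GAP_EDGE_WEIGHT,
            metadata=GapMeta(adj.gap_length),
            source="gap",
        )
    candidates = []
    support: dict = {}
    for qid, qblocks in sorted(blocks_by_query(blocks).items()):
        if len(qblocks) < 2:
            continue
        for a, b in zip(qblocks, qblocks[1:]):
            if a.ref_id == b.ref_id:
                continue
            fill_start, fill_end = a.query_end, b.query_start
            if (
                cfg.max_filler_len is not None
                and fill_end - fill_start > cfg.max_filler_len
            ):
                continue
            t_from = Terminus(a.ref_id, END if a.strand == "+" else BEGIN)
            t_to = Terminus(b.ref_id, BEGIN if b.strand == "+" else END)
            key = edge_key(t_from, t_to)
            support[key] = support.get(key, 0) + 1
            candidates.append(
                PatchMeta(qid, fill_start, fill_end, t_from, t_to)
            )
    ambiguous = {key for key, n in support.items() if n > 1}
    for key in ambiguous:
        graph.discard_edge(*key)
    for meta in candidates:
        key = edge_key(meta.t_from, meta.t_to)
        if key in ambiguous:
            continue
        if graph.has_edge(meta.t_from, meta.t_to):
            existing = graph.get_edge(meta.t_from, meta.t_to)
            if isinstance(existing.metadata, GapMeta):
                graph.add_edge(
                    meta.t_from, meta.t_to,
                    GAP_EDGE_WEIGHT + QUERY_EDGE_WEIGHT,
                    metadata=meta, source=meta.query_id, policy="replace",
                )
            # two supports on the same key were filtered above, so an
            # existing PatchMeta edge cannot recur
        else:
            graph.add_edge(
                meta.t_from, meta.t_to, QUERY_EDGE_WEIGHT,
                metadata=meta, source=meta.query_id,
            )
    return graph


# ---------------------------------------------------------------------------
# Synthesis


@dataclass
class _Part:
    source_id: str
    start: int
    end: int
    orient: str
    kind: str  # "seqlet" | "query" | "gap"

    @property
    def length(self) -> int:
        return self.end - self.start


def _seqlet_parent(name: str) -> str:
    if ":" in name:
        head, _, tail = name.rpartition(":")
        if re.fullmatch(r"\d+-\d+", tail):
            return head
    return name


def synthesize_patches(
    solution: GraphSolution,
    seqlets: Mapping[str, SequenceRecord],
    queries: Mapping[str, SequenceRecord],
    targets: Mapping[str, SequenceRecord] | None = None,
) -> PatchResult:
    """Concatenate solved chains into patched sequences.

    Query fillers are inserted verbatim (reverse-complemented when the
    chain traverses the supporting edge against its query-forward
    direction); an overlap trims the start of the downstream seqlet; gap
    edges no query replaced restore their original N run.  A chain that
    exactly reproduces an original target keeps the target's name;
    composite chains are named ``scf<NNNNN>``.
    """
    targets = targets or {}
    records: list = []
    agp: list = []
    joins: list = []
    scf_index = 0
    for chain in solution.chains:
        parts: list = []
        pending_trim = 0
        for idx, (sid, orient) in enumerate(chain.sequences):
            part = _Part(sid, 0, len(seqlets[sid]), orient, "seqlet")
            if pending_trim:
                if pending_trim >= part.length:
                    raise ValueError(
                        f"overlap of {pending_trim} bp consumes seqlet {sid}"
                    )
                if orient == "+":
                    part.start += pending_trim
                else:
                    part.end -= pending_trim
                pending_trim = 0
            parts.append(part)
            if idx == len(chain.joins):
                continue
            edge, forward = chain.joins[idx]
            meta = edge.metadata
            if isinstance(meta, GapMeta):
                parts.append(_Part("gap", 0, meta.length, "+", "gap"))
                continue
            # query-filled join
            exit_t = Terminus(sid, END if orient == "+" else BEGIN)
            query_forward = meta.t_from == exit_t
            fs, fe = meta.fill_start, meta.fill_end
            if fe > fs:
                if fe > len(queries[meta.query_id]):
                    raise ValueError(
                        f"filler {fs}-{fe} out of range for query {meta.query_id}"
                    )
                parts.append(
                    _Part(meta.query_id, fs, fe, "+" if query_forward else "-", "query")
                )
            else:
                pending_trim = fs - fe
            next_sid, next_orient = chain.sequences[idx + 1]
            joins.append(
                {
                    "left_id": sid,
                    "left_end": part.end if orient == "+" else part.start,
                    "right_id": next_sid,
                    "right_start": 0,
                    "query_id": meta.query_id,
                    "fill_start": min(fs, fe),
                    "fill_end": max(fs, fe),
                    "strand": "+" if query_forward else "-",
                    "overlap": max(0, fs - fe),
                }
            )
        # patch pending_trim recorded on last join: right_start reflects trim
        for j in joins:
            if j["overlap"] and j["right_start"] == 0:
                j["right_start"] = j["overlap"]

        sequence = _render_parts(parts, seqlets, queries)
        name = _chain_name(chain, parts, sequence, targets)
        if name is None:
            scf_index += 1
            name = f"scf{scf_index:05d}"
        records.append(SequenceRecord(name, sequence))
        agp.append(_parts_to_agp(name, parts))
    return PatchResult(records, agp, joins)


def _render_parts(parts, seqlets, queries) -> str:
    chunks = []
    for p in parts:
        if p.kind == "gap":
            chunks.append("N" * p.length)
            continue
        src = seqlets if p.kind == "seqlet" else queries
        seg = src[p.source_id].sequence[p.start : p.end]
        if p.orient == "-":
            seg = revcomp(seg)
        chunks.append(seg)
    return "".join(chunks)


def _chain_name(chain, parts, sequence, targets) -> str | None:
    """Original target name iff the chain reproduces that target exactly."""
    seqlet_parts = [p for p in parts if p.kind == "seqlet"]
    parents = {_seqlet_parent(p.source_id) for p in seqlet_parts}
    if len(parents) != 1:
        return None
    parent = parents.pop()
    rec = targets.get(parent)
    if rec is not None and rec.sequence == sequence:
        return parent
    return None


def _parts_to_agp(name: str, parts) -> AgpObject:
    rows = []
    pos = 0
    for i, p in enumerate(parts, 1):
        if p.kind == "gap":
            rows.append(
                AgpGap(pos + 1, pos + p.length, i, p.length, "scaffold", "yes", "na")
            )
        else:
            rows.append(
                AgpComponent(
                    pos + 1, pos + p.length, i, p.source_id,
                    p.start + 1, p.end, p.orient,
                )
            )
        pos += p.length
    return AgpObject(name, rows)


def patch_assembly(
    targets: Mapping[str, SequenceRecord],
    queries: Mapping[str, SequenceRecord],
    alignments: Sequence,
    cfg: PatchConfig | None = None,
    filter_cfg: FilterConfig | None = None,
) -> PatchResult:
    """Full patching pipeline.

    ``alignments`` map query sequences against the *gap-split* target
    (reference ids are seqlet names; for gapless targets these equal the
    original names).
    """
    cfg = cfg or PatchConfig()
    seqlets, registry = split_at_gaps(targets)
    merged = process_alignments(alignments, filter_cfg)
    unknown = {b.ref_id for b in merged} - set(seqlets)
    if unknown:
        raise ValueError(
            "alignment reference ids not found among target seqlets: "
            + ", ".join(sorted(unknown))
        )
    lengths = {sid: len(rec) for sid, rec in seqlets.items()}
    filtered = filter_patch_blocks(merged, lengths, cfg)
    graph = build_patch_graph(seqlets, registry, filtered, cfg)
    solution = graph.solve()
    result = synthesize_patches(solution, seqlets, queries, targets)
    result.solution = solution
    return result
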
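"""Synthetic assemblies and evaluation metrics.

Generates everything the scaffolding, correction, patching and merging
pipelines consume — a truth genome, fragmented draft assemblies with
logged misassemblies/gaps, exact whole-genome alignments, and Hi-C contact
tables — deterministically from a seed, so every module is testable
without external data.  Also houses two small evaluation utilities: the
contaminant/organelle contig-screening classifier (a pure function over
per-database coverage fractions) and the Euclidean patch-coordinate
distance used to compare patching solutions.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats_io import (
    AgpComponent,
    AgpGap,
    AgpObject,
    AlignmentRecord,
    SequenceRecord,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome(
    seed: int,
    n_chrom: int = 2,
    chrom_len: int = 1_000_000,
    repeat_fraction: float = 0.0,
) -> dict:
    """Random chromosomes ``chr1..chrN``, optionally salted with duplicated
    segments (1–5 kbp) to stress unique-anchor filtering."""
    if n_chrom < 1 or chrom_len < 1:
        raise ValueError("n_chrom and chrom_len must be positive")
    if not (0 <= repeat_fraction < 1):
        raise ValueError("repeat_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genome = {}
    for i in range(1, n_chrom + 1):
        arr = rng.choice(_BASES, size=chrom_len)
        repeat_bp = 0
        target = repeat_fraction * chrom_len
        while repeat_bp < target:
            seg_len = int(rng.integers(1_000, min(5_000, chrom_len // 2) + 1))
            src = int(rng.integers(0, chrom_len - seg_len + 1))
            dst = int(rng.integers(0, chrom_len - seg_len + 1))
            arr[dst : dst + seg_len] = arr[src : src + seg_len]
            repeat_bp += seg_len
        genome[f"chr{i}"] = SequenceRecord(f"chr{i}", arr.tobytes().decode("ascii"))
    return genome


@dataclass
class _SegPart:
    """A contiguous genome slice inside a contig (pre-flip offsets)."""

    chrom: str
    g_start: int
    g_end: int
    offset: int = 0  # position within the contig before any flip
    is_gap: bool = False  # True: the slice was replaced by Ns in the contig


@dataclass
class TruthAssembly:
    """A fragmented draft assembly with full provenance."""

    genome: Mapping[str, SequenceRecord]
    contigs: dict
    truth_agp: list
    events: list
    seed: int
    _parts: dict = field(default_factory=dict)  # contig_id -> (parts, flipped)

    def layout(self) -> dict:
        """``{chrom: [(contig_id, orient, distance_to_next), ...]}`` with the
        inter-contig deleted distance attached to the left partner."""
        out: dict = {}
        for obj in self.truth_agp:
            entries = []
            pending_gap = 0
            for row in obj.rows:
                if isinstance(row, AgpGap):
                    pending_gap += row.gap_length
                    continue
                orient = row.orientation
                if entries and entries[-1][0] == row.component_id and pending_gap == 0:
                    continue  # multi-part contig (internal N run)
                if entries:
                    cid, o, _ = entries[-1]
                    entries[-1] = (cid, o, pending_gap)
                pending_gap = 0
                entries.append((row.component_id, orient, 0))
            out[obj.object_id] = entries
        return out


def fragment_assembly(
    genome: Mapping[str, SequenceRecord],
    seed: int,
    target_n50: int = 200_000,
    gap_rate: float = 0.0,
    misassembly_rate: float = 0.0,
    inter_contig_bp: tuple = (0, 0),
    flip_prob: float = 0.5,
    gap_len_range: tuple = (50, 500),
) -> TruthAssembly:
    """Fragment a genome into a draft assembly with logged events.

    Each chromosome is cut into fragments of roughly ``target_n50`` bp.
    At each junction: with probability ``gap_rate`` the fragments stay in
    one contig separated by an N run that *replaces* the underlying
    sequence (a sized gap); otherwise the contig ends and a deleted spacer
    drawn from ``inter_contig_bp`` separates it from the next.  With
    probability ``misassembly_rate`` a contig is fused with a contig from
    another chromosome (a chimeric join).  Contigs are finally
    reverse-complemented with probability ``flip_prob``.  The truth AGP
    maps contigs back to chromosomes and reconstructs the genome exactly
    outside gap bases.
    """
    for rate in (gap_rate, misassembly_rate, flip_prob):
        if not (0 <= rate <= 1):
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    events: list = []

    per_chrom_contigs: list = []  # [(chrom, [parts])]
    for chrom in sorted(genome):
        L = len(genome[chrom])
        pos = 0
        parts: list = []
        while pos < L:
            flen = int(rng.integers(max(1, target_n50 // 2), target_n50 * 3 // 2 + 1))
            # absorb a short chromosome-end remainder instead of emitting a sliver
            if L - pos - flen < max(1, target_n50 // 2):
                flen = L - pos
            flen = min(flen, L - pos)
            parts.append(_SegPart(chrom, pos, pos + flen))
            pos += flen
            if pos >= L:
                break
            if rng.random() < gap_rate:
                glen = int(rng.integers(gap_len_range[0], gap_len_range[1] + 1))
                glen = min(glen, L - pos)
                if glen:
                    parts.append(_SegPart(chrom, pos, pos + glen, is_gap=True))
                    events.append({"type": "gap", "chrom": chrom, "start": pos, "length": glen})
                    pos += glen
            else:
                per_chrom_contigs.append((chrom, parts))
                parts = []
                spacer = int(rng.integers(inter_contig_bp[0], inter_contig_bp[1] + 1))
                spacer = min(spacer, L - pos)
                if spacer:
                    events.append(
                        {"type": "spacer", "chrom": chrom, "start": pos, "length": spacer}
                    )
                    pos += spacer
        if parts:
            per_chrom_contigs.append((chrom, parts))

    # chimeric fusions across chromosomes
    pool = list(per_chrom_contigs)
    fused: list = []
    i = 0
    while i < len(pool):
        chrom, parts = pool[i]
        i += 1
        if rng.random() < misassembly_rate:
            j = next((k for k in range(i, len(pool)) if pool[k][0] != chrom), None)
            if j is not None:
                chrom2, parts2 = pool.pop(j)
                junction = sum(p.g_end - p.g_start for p in parts)
                events.append(
                    {
                        "type": "chimera",
                        "left_chrom": chrom,
                        "right_chrom": chrom2,
                        "junction": junction,
                    }
                )
                parts = parts + parts2
        fused.append(parts)

    contigs: dict = {}
    part_index: dict = {}
    n = 0
    for parts in fused:
        n += 1
        cid = f"ctg{n:05d}"
        chunks = []
        offset = 0
        for p in parts:
            p.offset = offset
            seg_len = p.g_end - p.g_start
            if p.is_gap:
                chunks.append("N" * seg_len)
            else:
                chunks.append(genome[p.chrom].sequence[p.g_start : p.g_end])
            offset += seg_len
        seq = "".join(chunks)
        flipped = bool(rng.random() < flip_prob)
        if flipped:
            seq = revcomp(seq)
        contigs[cid] = SequenceRecord(cid, seq)
        part_index[cid] = (parts, flipped)

    # truth AGP: per chromosome, rows in genome order
    truth_agp = []
    for chrom in sorted(genome):
        placed = []  # (g_start, g_end, contig_id, c_start, c_end, orient)
        for cid, (parts, flipped) in part_index.items():
            clen = len(contigs[cid])
            for p in parts:
                if p.chrom != chrom:
                    continue
                seg_len = p.g_end - p.g_start
                if flipped:
                    cs, ce = clen - (p.offset + seg_len), clen - p.offset
                    orient = "-"
                else:
                    cs, ce = p.offset, p.offset + seg_len
                    orient = "+"
                placed.append((p.g_start, p.g_end, cid, cs, ce, orient))
        placed.sort()
        rows = []
        part_no = 0
        pos = 0
        for g_start, g_end, cid, cs, ce, orient in placed:
            if g_start > pos:  # deleted spacer
                part_no += 1
                rows.append(
                    AgpGap(pos + 1, g_start, part_no, g_start - pos, "scaffold", "no", "na")
                )
            part_no += 1
            rows.append(AgpComponent(g_start + 1, g_end, part_no, cid, cs + 1, ce, orient))
            pos = g_end
        if pos < len(genome[chrom]):
            part_no += 1
            rows.append(
                AgpGap(
                    pos + 1, len(genome[chrom]), part_no,
                    len(genome[chrom]) - pos, "scaffold", "no", "na",
                )
            )
        truth_agp.append(AgpObject(chrom, rows))

    return TruthAssembly(genome, contigs, truth_agp, events, seed, part_index)


def exact_alignments(truth: TruthAssembly) -> list:
    """Perfect query-vs-genome alignments implied by the truth layout:
    one record per contiguous (non-gap) genome slice of every contig."""
    alignments = []
    for cid, (parts, flipped) in truth._parts.items():
        clen = len(truth.contigs[cid])
        for p in parts:
            if p.is_gap:
                continue
            seg_len = p.g_end - p.g_start
            if flipped:
                qs, qe = clen - (p.offset + seg_len), clen - p.offset
                strand = "-"
            else:
                qs, qe = p.offset, p.offset + seg_len
                strand = "+"
            alignments.append(
                AlignmentRecord(
                    query_id=cid,
                    query_len=clen,
                    query_start=qs,
                    query_end=qe,
                    strand=strand,
                    ref_id=p.chrom,
                    ref_len=len(truth.genome[p.chrom]),
                    ref_start=p.g_start,
                    ref_end=p.g_end,
                    num_matches=seg_len,
                    aln_len=seg_len,
                    mapq=60,
                )
            )
    return alignments


def simulate_hic_pairs(
    truth: TruthAssembly,
    n_pairs: int,
    decay_bp: float = 50_000.0,
    seed: int = 0,
) -> list:
    """Contact pairs whose genomic separation decays exponentially.

    Endpoints are drawn on the truth genome and mapped into contig
    coordinates; pairs landing in deleted regions are rejected and
    redrawn.  Returns ``[(contig_a, pos_a, contig_b, pos_b), ...]``.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = sorted(truth.genome)
    lengths = np.array([len(truth.genome[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    # genome -> contig coordinate maps
    maps: dict = {}
    for cid, (parts, flipped) in truth._parts.items():
        clen = len(truth.contigs[cid])
        for p in parts:
            if p.is_gap:
                continue
            maps.setdefault(p.chrom, []).append(
                (p.g_start, p.g_end, cid, p.offset, flipped, clen)
            )
    for chrom in maps:
        maps[chrom].sort()
    starts = {chrom: [e[0] for e in maps[chrom]] for chrom in maps}

    def locate(chrom: str, pos: int):
        entries = maps.get(chrom)
        if not entries:
            return None
        i = bisect.bisect_right(starts[chrom], pos) - 1
        if i < 0:
            return None
        g_start, g_end, cid, offset, flipped, clen = entries[i]
        if not (g_start <= pos < g_end):
            return None
        o = offset + (pos - g_start)
        return (cid, clen - 1 - o if flipped else o)

    pairs = []
    attempts = 0
    max_attempts = max(1000, n_pairs * 100)
    while len(pairs) < n_pairs and attempts < max_attempts:
        attempts += 1
        ci = int(rng.choice(len(chroms), p=weights))
        chrom = chroms[ci]
        L = int(lengths[ci])
        p1 = int(rng.integers(0, L))
        sep = int(rng.exponential(decay_bp)) + 1
        p2 = p1 + sep if rng.random() < 0.5 else p1 - sep
        if not (0 <= p2 < L):
            continue
        a, b = locate(chrom, p1), locate(chrom, p2)
        if a is None or b is None:
            continue
        pairs.append((a[0], a[1], b[0], b[1]))
    return pairs


# ---------------------------------------------------------------------------
# Evaluation utilities


@dataclass
class ScreeningProfile:
    """Per-contig coverage fractions against the screening databases."""

    contig_id: str
    length: int
    bacterial: float = 0.0
    chloroplast: float = 0.0
    mitochondria: float = 0.0
    rdna: float = 0.0

    def __post_init__(self):
        for name in ("bacterial", "chloroplast", "mitochondria", "rdna"):
            frac = getattr(self, name)
            if not (0 <= frac <= 1):
                raise ValueError(f"{name} fraction must be in [0, 1]")


def screen_contig(profile: ScreeningProfile) -> str:
    """Classify a contig as "rDNA", "remove" or "keep".

    A contig with more than 10% rDNA coverage is a putative rDNA contig
    and is always kept.  Otherwise it is removed when more than 10% is
    bacterial, more than 20% is mitochondrial and it is shorter than
    1 Mbp, or more than 20% is chloroplast and it is shorter than 0.5 Mbp.
    """
    if profile.rdna > 0.10:
        return "rDNA"
    if profile.bacterial > 0.10:
        return "remove"
    if profile.mitochondria > 0.20 and profile.length < 1_000_000:
        return "remove"
    if profile.chloroplast > 0.20 and profile.length < 500_000:
        return "remove"
    return "keep"


def patch_distance(patch_a: Sequence[float], patch_b: Sequence[float]) -> float:
    """Euclidean distance between two patch coordinate vectors."""
    if len(patch_a) != len(patch_b):
        raise ValueError("coordinate tuples must have the same arity")
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(patch_a, patch_b)))
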
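"""Readers, writers and validators for assembly interchange formats.

Covers FASTA, AGP v2.1, PAF (minimap2 dialect, 12 mandatory columns),
MUMmer delta, GFF3 feature intervals, and assembly contiguity (nX)
statistics.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open.  AGP mandates 1-based
inclusive coordinates and GFF3 uses 1-based inclusive positions; both are
converted at the I/O boundary.  PAF is natively 0-based half-open with
query coordinates always on the forward query strand; MUMmer delta records
(1-based inclusive, reverse alignments encoded by a descending query
interval) are converted to the PAF convention so downstream logic sees a
single representation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import reverse_complement as _bio_revcomp
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.Seq import Seq as _BioSeq


class ParseError(ValueError):
    """A syntactically invalid line in an input file."""


def revcomp(sequence: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes handled)."""
    return str(_bio_revcomp(sequence))


# ---------------------------------------------------------------------------
# Sequences


@dataclass
class SequenceRecord:
    """A named nucleotide sequence."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, revcomp(self.sequence))


def read_fasta(source: Union[str, Path, TextIO]) -> dict:
    """Read a (multi-)FASTA into an ordered ``{id: SequenceRecord}`` map."""
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        records = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise ParseError(f"duplicate FASTA id {rec.id!r}")
            records[rec.id] = SequenceRecord(rec.id, str(rec.seq))
        return records
    finally:
        if close:
            handle.close()


def write_fasta(
    records: Iterable[SequenceRecord],
    dest: Union[str, Path, TextIO],
    width: int = 60,
) -> None:
    bio = [
        _BioSeqRecord(_BioSeq(r.sequence), id=r.id, description="")
        for r in records
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(bio)
    else:
        writer = SeqIO.FastaIO.FastaWriter(dest, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Pairwise alignments


@dataclass
class AlignmentRecord:
    """One pairwise alignment in 0-based half-open, query-forward coordinates.

    ``mapq`` is ``None`` when the source format carries no mapping quality
    (MUMmer delta).
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    ref_id: str
    ref_len: int
    ref_start: int
    ref_end: int
    num_matches: int
    aln_len: int
    mapq: Union[int, None] = None

    def validate(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(f"bad query interval in {self}")
        if not (0 <= self.ref_start < self.ref_end <= self.ref_len):
            raise ValueError(f"bad reference interval in {self}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand in {self}")
        if not (self.aln_len >= self.num_matches >= 0):
            raise ValueError(f"bad match counts in {self}")


def parse_paf(stream: Union[TextIO, Iterable[str]]) -> list:
    """Parse the 12 mandatory PAF columns; optional tags are ignored."""
    records = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ParseError(f"PAF line {lineno}: expected >=12 columns, got {len(cols)}")
        try:
            rec = AlignmentRecord(
                query_id=cols[0],
                query_len=int(cols[1]),
                query_start=int(cols[2]),
                query_end=int(cols[3]),
                strand=cols[4],
                ref_id=cols[5],
                ref_len=int(cols[6]),
                ref_start=int(cols[7]),
                ref_end=int(cols[8]),
                num_matches=int(cols[9]),
                aln_len=int(cols[10]),
                mapq=int(cols[11]),
            )
        except ValueError as exc:
            raise ParseError(f"PAF line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def parse_delta(stream: Union[TextIO, Iterable[str]]) -> list:
    """Parse a MUMmer delta file into :class:`AlignmentRecord` objects.

    Delta alignment headers are 1-based inclusive; reverse alignments carry
    a descending query interval.  Both are converted to the internal
    0-based half-open, query-forward convention.  ``num_matches`` is
    approximated as the reference span minus the reported error count.
    """
    records = []
    ref_id = query_id = None
    ref_len = query_len = 0
    in_distances = False
    lines = iter(stream)
    header_seen = 0
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line:
            continue
        if header_seen < 2 and not line.startswith(">"):
            # file path line then NUCMER/PROMER line
            header_seen += 1
            continue
        if line.startswith(">"):
            parts = line[1:].split()
            if len(parts) != 4:
                raise ParseError(f"delta line {lineno}: bad sequence header")
            ref_id, query_id = parts[0], parts[1]
            ref_len, query_len = int(parts[2]), int(parts[3])
            in_distances = False
            continue
        fields = line.split()
        if in_distances:
            if fields == ["0"]:
                in_distances = False
            continue
        if len(fields) == 7:
            if ref_id is None:
                raise ParseError(f"delta line {lineno}: alignment before sequence header")
            rs, re_, qs, qe, err = (int(x) for x in fields[:5])
            if qs <= qe:
                strand, q0, q1 = "+", qs - 1, qe
            else:
                strand, q0, q1 = "-", qe - 1, qs
            aln_len = re_ - rs + 1
            records.append(
                AlignmentRecord(
                    query_id=query_id,
                    query_len=query_len,
                    query_start=q0,
                    query_end=q1,
                    strand=strand,
                    ref_id=ref_id,
                    ref_len=ref_len,
                    ref_start=rs - 1,
                    ref_end=re_,
                    num_matches=max(0, aln_len - err),
                    aln_len=aln_len,
                    mapq=None,
                )
            )
            in_distances = True
        elif fields == ["0"]:
            continue
        else:
            raise ParseError(f"delta line {lineno}: unexpected record {line!r}")
    return records


def parse_alignments(stream, format: str) -> list:
    """Parse pairwise alignments from PAF or MUMmer delta text."""
    if format == "paf":
        return parse_paf(stream)
    if format == "delta":
        return parse_delta(stream)
    raise ValueError(f"unknown alignment format {format!r} (expected 'paf' or 'delta')")


# ---------------------------------------------------------------------------
# AGP v2.1

COMPONENT_TYPES = frozenset("ADFGOPW")
GAP_TYPES = frozenset({"scaffold", "contig", "centromere", "short_arm", "heterochromatin", "telomere", "repeat", "contamination"})


@dataclass
class AgpComponent:
    """A component (W etc.) row; coordinates are AGP-native 1-based inclusive."""

    object_beg: int
    object_end: int
    part_number: int
    component_id: str
    component_beg: int
    component_end: int
    orientation: str  # + - ?
    component_type: str = "W"


@dataclass
class AgpGap:
    """A gap (N/U) row.  ``known`` distinguishes N (sized) from U (unknown)."""

    object_beg: int
    object_end: int
    part_number: int
    gap_length: int
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "na"
    known: bool = True


@dataclass
class AgpObject:
    object_id: str
    rows: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.rows[-1].object_end if self.rows else 0

    def components(self) -> list:
        return [r for r in self.rows if isinstance(r, AgpComponent)]

    def gaps(self) -> list:
        return [r for r in self.rows if isinstance(r, AgpGap)]


def read_agp(stream: Union[TextIO, Iterable[str], str, Path]) -> list:
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            return read_agp(fh)
    objects: list = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"AGP line {lineno}: expected 9 columns, got {len(cols)}")
        obj_id = cols[0]
        try:
            beg, end, part = int(cols[1]), int(cols[2]), int(cols[3])
            ctype = cols[4]
            if ctype in COMPONENT_TYPES:
                row: Union[AgpComponent, AgpGap] = AgpComponent(
                    beg, end, part, cols[5], int(cols[6]), int(cols[7]), cols[8], ctype
                )
            elif ctype in ("N", "U"):
                row = AgpGap(
                    beg, end, part, int(cols[5]), cols[6], cols[7], cols[8],
                    known=(ctype == "N"),
                )
            else:
                raise ParseError(f"AGP line {lineno}: unknown component type {ctype!r}")
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"AGP line {lineno}: {exc}") from exc
        if objects and objects[-1].object_id == obj_id:
            objects[-1].rows.append(row)
        else:
            objects.append(AgpObject(obj_id, [row]))
    return objects


def write_agp(objects: Sequence[AgpObject]) -> str:
    out = io.StringIO()
    out.write("##agp-version 2.1\n")
    for obj in objects:
        for row in obj.rows:
            if isinstance(row, AgpComponent):
                cols = [
                    obj.object_id, row.object_beg, row.object_end, row.part_number,
                    row.component_type, row.component_id, row.component_beg,
                    row.component_end, row.orientation,
                ]
            else:
                cols = [
                    obj.object_id, row.object_beg, row.object_end, row.part_number,
                    "N" if row.known else "U", row.gap_length, row.gap_type,
                    row.linkage, row.evidence,
                ]
            out.write("\t".join(str(c) for c in cols) + "\n")
    return out.getvalue()


def validate_agp(objects: Sequence[AgpObject]) -> list:
    """Check AGP structural invariants; returns a (possibly empty) violation list.

    Each violation is a human-readable string carrying the object id and the
    0-based row index within the object.
    """
    violations = []
    seen_objects = set()
    for obj in objects:
        if obj.object_id in seen_objects:
            violations.append(f"{obj.object_id}: duplicate object id")
        seen_objects.add(obj.object_id)
        if not obj.rows:
            violations.append(f"{obj.object_id}: object has no rows")
            continue
        expected_beg = 1
        for i, row in enumerate(obj.rows):
            where = f"{obj.object_id} row {i}"
            if row.object_beg != expected_beg:
                violations.append(
                    f"{where}: object_beg {row.object_beg} != expected {expected_beg}"
                    " (rows must tile contiguously from 1)"
                )
            if row.object_end < row.object_beg:
                violations.append(f"{where}: object_end precedes object_beg")
            if row.part_number != i + 1:
                violations.append(f"{where}: part_number {row.part_number} != {i + 1}")
            span = row.object_end - row.object_beg + 1
            if isinstance(row, AgpGap):
                if row.gap_length != span:
                    violations.append(
                        f"{where}: gap_length mismatch (gap_length {row.gap_length},"
                        f" object span {span})"
                    )
                if row.linkage not in ("yes", "no"):
                    violations.append(f"{where}: bad linkage {row.linkage!r}")
            else:
                comp_span = row.component_end - row.component_beg + 1
                if row.component_beg < 1 or row.component_end < row.component_beg:
                    violations.append(f"{where}: bad component interval")
                elif comp_span != span:
                    violations.append(
                        f"{where}: span-length mismatch (component span {comp_span},"
                        f" object span {span})"
                    )
                if row.orientation not in ("+", "-", "?"):
                    violations.append(f"{where}: bad orientation {row.orientation!r}")
            expected_beg = row.object_end + 1
    return violations


def build_fasta_from_agp(
    objects: Sequence[AgpObject],
    components: Mapping[str, SequenceRecord],
) -> list:
    """Materialize AGP objects as sequences.

    ``-`` components are reverse-complemented; ``?`` is treated as ``+``;
    gaps are rendered as runs of ``N``.
    """
    out = []
    for obj in objects:
        parts = []
        for i, row in enumerate(obj.rows):
            if isinstance(row, AgpGap):
                parts.append("N" * row.gap_length)
                continue
            comp = components.get(row.component_id)
            if comp is None:
                raise KeyError(
                    f"{obj.object_id} row {i}: component {row.component_id!r} not found"
                )
            if row.component_end > len(comp):
                raise ValueError(
                    f"{obj.object_id} row {i}: component_end {row.component_end}"
                    f" exceeds length of {row.component_id} ({len(comp)})"
                )
            seg = comp.sequence[row.component_beg - 1 : row.component_end]
            if row.orientation == "-":
                seg = revcomp(seg)
            parts.append(seg)
        out.append(SequenceRecord(obj.object_id, "".join(parts)))
    return out


# ---------------------------------------------------------------------------
# GFF3 intervals


def read_gff_intervals(stream: Union[TextIO, Iterable[str], str, Path]) -> dict:
    """Extract ``{seqid: [(start, end), ...]}`` from GFF3 (0-based half-open).

    Only columns 1 (seqid), 4 (start) and 5 (end) are consumed; everything
    else in the file is ignored.
    """
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            return read_gff_intervals(fh)
    intervals: dict = {}
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 5:
            raise ParseError(f"GFF3 line {lineno}: expected >=5 columns")
        try:
            start, end = int(cols[3]) - 1, int(cols[4])
        except ValueError as exc:
            raise ParseError(f"GFF3 line {lineno}: {exc}") from exc
        intervals.setdefault(cols[0], []).append((start, end))
    return intervals


# ---------------------------------------------------------------------------
# Contiguity statistics


def nx_statistics(lengths: Sequence[int], x: float) -> int:
    """nX statistic: the smallest length L such that sequences of length >= L
    sum to at least x% of the assembly (N50 for x=50).
    """
    if not lengths:
        raise ValueError("nx_statistics requires a nonempty length list")
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    if any(l < 1 for l in lengths):
        raise ValueError("all lengths must be >= 1")
    total = sum(lengths)
    threshold = total * (x / 100.0)
    cum = 0
    for l in sorted(lengths, reverse=True):
        cum += l
        if cum + 1e-9 >= threshold:
            return l
    return min(lengths)  # unreachable for valid x
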
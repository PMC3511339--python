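"""Sequence and annotation I/O with a single internal coordinate convention.

All coordinates inside the package are 0-based half-open intervals. Published
tables of binding sites use 1-based inclusive "From-to" pairs; conversion
happens only at the I/O boundary (:func:`to_report_coords` /
:func:`parse_report_coords`).

The noncoding-extraction step reproduces what a noncoding sequence retrieval
system does once the locus sequence and its coding annotation are in hand:
merge the coding intervals and return the complement as maximal noncoding
segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

DNA_ALPHABET = frozenset("ACGTN")

__all__ = [
    "GenomicInterval",
    "AnnotatedSequence",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_bed",
    "extract_noncoding",
    "merge_intervals",
    "to_report_coords",
    "parse_report_coords",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named sequence, 0-based."""

    sequence_name: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on "
                f"{self.sequence_name!r}: need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the intersection with ``other`` (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class AnnotatedSequence:
    """A named species sequence with coding/exon annotation.

    ``residues`` are normalised to upper-case ``A/C/G/T/N``; ``mask_intervals``
    optionally holds additional regions (e.g. soft-masked repeats) to exclude
    from noncoding extraction alongside the coding intervals.
    """

    species: str
    name: str
    residues: str
    coding_intervals: list[GenomicInterval] = field(default_factory=list)
    mask_intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.name!r} contains characters outside "
                f"A/C/G/T/N: {sorted(bad)!r}"
            )
        for iv in list(self.coding_intervals) + list(self.mask_intervals):
            if iv.end > len(self.residues):
                raise ValidationError(
                    f"annotation [{iv.start}, {iv.end}) exceeds length "
                    f"{len(self.residues)} of sequence {self.name!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def _normalise_residues(raw: str, name: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise FormatError(
            f"record {name!r} contains non-DNA characters {sorted(bad)!r}"
        )
    return seq


def read_fasta(
    path: str | Path,
    species: str | None = None,
    mask_lowercase: bool = False,
) -> list[AnnotatedSequence]:
    """Read a (multi-)FASTA file into annotation-free records.

    Residues are upper-cased and U is mapped to T. With ``mask_lowercase``
    the lower-case (soft-masked) runs of each record are recorded as
    ``mask_intervals`` so they can be excluded from noncoding extraction.
    Raises :class:`FormatError` for an empty file or a file whose first
    non-blank line is not a FASTA header.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(
                f"{path}: malformed FASTA, first line is not a header: "
                f"{first.strip()!r}"
            )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        mask = _lowercase_runs(rec.id, raw) if mask_lowercase else []
        records.append(
            AnnotatedSequence(
                species=species or rec.id,
                name=rec.id,
                residues=_normalise_residues(raw, rec.id),
                mask_intervals=mask,
            )
        )
    return records


def _lowercase_runs(name: str, raw: str) -> list[GenomicInterval]:
    runs: list[GenomicInterval] = []
    start = None
    for i, ch in enumerate(raw):
        if ch.islower():
            if start is None:
                start = i
        elif start is not None:
            runs.append(GenomicInterval(name, start, i))
            start = None
    if start is not None:
        runs.append(GenomicInterval(name, start, len(raw)))
    return runs


def write_fasta(records: Iterable[AnnotatedSequence], path: str | Path) -> None:
    """Write records as FASTA, preserving input order (deterministic)."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.name, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_annotation(path: str | Path, dialect: str) -> list[GenomicInterval]:
    """Read coding/exon intervals from BED or GFF3.

    BED coordinates are taken as-is (already 0-based half-open); GFF3 starts
    are converted by subtracting 1 and features are filtered to types
    ``CDS``/``exon``. An interval with ``end <= start`` raises
    :class:`ValidationError` naming the offending line.
    """
    dialect = dialect.upper()
    if dialect not in ("BED", "GFF3"):
        raise ValidationError(f"unknown annotation dialect {dialect!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "BED":
                    if len(fields) < 3:
                        raise FormatError(
                            f"{path}:{lineno}: BED needs >= 3 columns"
                        )
                    name, start, end = fields[0], int(fields[1]), int(fields[2])
                    strand = fields[5] if len(fields) >= 6 else "."
                else:
                    if len(fields) != 9:
                        raise FormatError(
                            f"{path}:{lineno}: GFF3 needs 9 columns"
                        )
                    if fields[2] not in ("CDS", "exon"):
                        continue
                    name = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: interval end {end} <= start {start}"
                )
            if strand not in ("+", "-", "."):
                strand = "."
            intervals.append(GenomicInterval(name, start, end, strand))
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
    header: str | None = None,
) -> None:
    """Write BED6 with deterministic ordering (as given)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED convention)\n")
        if header:
            fh.write(f"# {header}\n")
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i + 1}"
            score = int(round(scores[i])) if scores is not None else 0
            fh.write(
                f"{iv.sequence_name}\t{iv.start}\t{iv.end}\t{name}\t"
                f"{score}\t{iv.strand}\n"
            )


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge overlapping or adjacent intervals (strand-blind)."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(
                    last.sequence_name, last.start, iv.end
                )
        else:
            merged.append(GenomicInterval(iv.sequence_name, iv.start, iv.end))
    return merged


def extract_noncoding(
    seq: AnnotatedSequence,
) -> list[tuple[GenomicInterval, str]]:
    """Complement of the merged coding (+ mask) intervals over the sequence.

    Coding is masked on both strands — annotation strand is ignored. Returns
    maximal noncoding intervals with their subsequences, in coordinate order.
    """
    masked = merge_intervals(
        list(seq.coding_intervals) + list(seq.mask_intervals)
    )
    out: list[tuple[GenomicInterval, str]] = []
    cursor = 0
    for iv in masked:
        if iv.start > cursor:
            nc = GenomicInterval(seq.name, cursor, iv.start)
            out.append((nc, seq.residues[nc.start:nc.end]))
        cursor = max(cursor, iv.end)
    if cursor < len(seq):
        nc = GenomicInterval(seq.name, cursor, len(seq))
        out.append((nc, seq.residues[nc.start:nc.end]))
    return out


def to_report_coords(iv: GenomicInterval) -> tuple[int, int]:
    """Render an interval as the 1-based inclusive ``(from, to)`` pair used in
    published binding-site tables."""
    return iv.start + 1, iv.end


def parse_report_coords(
    sequence_name: str, frm: int, to: int, strand: str = "."
) -> GenomicInterval:
    """Inverse of :func:`to_report_coords`."""
    return GenomicInterval(sequence_name, frm - 1, to, strand)
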
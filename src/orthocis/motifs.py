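"""Binding-site motif models, scanning, and in-silico site mutagenesis.

Two motif representations are supported:

* an IUPAC degenerate consensus (e.g. the AP-1 heptamer ``TGASTCA`` or the
  NFkB decamer ``GGGRNNYYCC``) — a window is a hit iff every position is
  IUPAC-compatible;
* a position-count matrix with a similarity score
  ``sum_k counts[k, observed base] / sum_k max(counts[k, :])`` and a hit
  threshold (default 0.85). This is a transparent surrogate for the
  proprietary matrix-similarity scores of commercial TFBS scanners: it
  preserves their ranking behaviour while keeping every number auditable.

Every motif designates a *core* — its most informative contiguous positions,
conventionally rendered upper-case inside an otherwise lower-case site
sequence. The core drives the in-silico mutagenesis operations:
:func:`delete_core` excises it, and :func:`disrupted_sites` tests whether a
sequence variant touches it.

Scanning evaluates both strands; reverse-strand hits are reported in
plus-strand coordinates, with the motif-strand word recoverable via
:func:`revcomp` — matching the convention of published binding-site tables
whose ``(-)`` rows print the reverse complement of the plus-strand segment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, ValidationError
from .seqio import GenomicInterval

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "U": "A",
}
_COMP_TABLE = str.maketrans(
    {**_COMPLEMENT, **{k.lower(): v.lower() for k, v in _COMPLEMENT.items()}}
)
_BASES = "ACGT"
_SEQ_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

__all__ = [
    "Motif",
    "MotifHit",
    "revcomp",
    "load_motif_library",
    "write_motif_library",
    "default_motif_library",
    "scan_motifs",
    "delete_core",
    "disrupted_sites",
    "consensus_indicator_matrix",
]


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (case-preserving involution)."""
    for ch in seq:
        if ch.upper() not in _COMPLEMENT:
            raise ValidationError(f"cannot complement character {ch!r}")
    return seq.translate(_COMP_TABLE)[::-1]


@dataclass(frozen=True)
class Motif:
    """A binding-site model: IUPAC consensus or position-count matrix.

    ``core`` is a 0-based half-open position interval within the motif;
    ``score_threshold`` is the minimum matrix-similarity fraction for a
    matrix hit (ignored for consensus motifs, whose hits score 1.0).
    """

    family: str
    matrix_name: str
    consensus: str | None = None
    counts: np.ndarray | None = None  # shape (width, 4), columns A C G T
    core: tuple[int, int] = (0, 0)
    score_threshold: float = 0.85

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.counts is None):
            raise ValidationError(
                f"motif {self.matrix_name!r}: exactly one of consensus or "
                "counts must be given"
            )
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC_SETS)
            if bad:
                raise ValidationError(
                    f"motif {self.matrix_name!r}: unknown IUPAC codes "
                    f"{sorted(bad)!r}"
                )
            object.__setattr__(self, "consensus", self.consensus.upper())
        else:
            counts = np.asarray(self.counts, dtype=float)
            if counts.ndim != 2 or counts.shape[1] != 4:
                raise ValidationError(
                    f"motif {self.matrix_name!r}: counts must be (width, 4)"
                )
            if (counts < 0).any() or (counts.sum(axis=1) <= 0).any():
                raise ValidationError(
                    f"motif {self.matrix_name!r}: each position's counts "
                    "must be non-negative and sum to a positive total"
                )
            object.__setattr__(self, "counts", counts)
        cs, ce = self.core
        if self.core == (0, 0):
            object.__setattr__(self, "core", (0, self.width))
        elif not (0 <= cs < ce <= self.width):
            raise ValidationError(
                f"motif {self.matrix_name!r}: core {self.core} outside "
                f"width {self.width}"
            )
        if not (0 < self.score_threshold <= 1):
            raise ValidationError(
                f"motif {self.matrix_name!r}: score_threshold must be in "
                f"(0, 1], got {self.score_threshold}"
            )

    @property
    def width(self) -> int:
        if self.consensus is not None:
            return len(self.consensus)
        return self.counts.shape[0]

    @property
    def core_width(self) -> int:
        return self.core[1] - self.core[0]


@dataclass(frozen=True)
class MotifHit:
    """A stranded placement of a motif on a sequence.

    ``interval`` is always on the plus strand of the scanned sequence;
    ``plus_word`` is the plus-strand subsequence (lower-case).
    """

    motif: Motif
    interval: GenomicInterval
    strand: str
    plus_word: str
    score: float

    def __post_init__(self) -> None:
        if self.interval.length != self.motif.width:
            raise ValidationError("hit interval length != motif width")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"hit strand must be +/-, got {self.strand!r}")

    def core_interval(self) -> GenomicInterval:
        """The motif core in plus-strand sequence coordinates."""
        s = self.interval.start
        w = self.motif.width
        cs, ce = self.motif.core
        if self.strand == "+":
            return GenomicInterval(self.interval.sequence_name, s + cs, s + ce)
        return GenomicInterval(
            self.interval.sequence_name, s + w - ce, s + w - cs
        )

    @property
    def matched_sequence(self) -> str:
        """Plus-strand subsequence with core positions upper-cased."""
        core = self.core_interval()
        s = self.interval.start
        word = self.plus_word.lower()
        lo, hi = core.start - s, core.end - s
        return word[:lo] + word[lo:hi].upper() + word[hi:]

    @property
    def display_sequence(self) -> str:
        """The motif-strand word, core upper-cased — what a published
        binding-site table prints in its Sequence column."""
        if self.strand == "+":
            return self.matched_sequence
        return revcomp(self.matched_sequence)


# ---------------------------------------------------------------------------
# motif library I/O

def load_motif_library(path: str | Path) -> list[Motif]:
    """Load motifs from a consensus TSV or a TRANSFAC-like matrix file.

    The format is sniffed from the first non-comment line: ``ID `` starts a
    matrix file, otherwise a 4-column TSV
    ``family<TAB>matrix_name<TAB>IUPAC<TAB>core=a-b`` (core 1-based
    inclusive, optional 5th column ``threshold=x``) is assumed.
    Duplicate matrix names raise :class:`FormatError`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    first = next(
        (ln for ln in lines if ln.strip() and not ln.startswith("#")), ""
    )
    motifs = (
        _parse_matrix_lines(lines, path)
        if first.startswith("ID")
        else _parse_consensus_lines(lines, path)
    )
    seen: set[str] = set()
    for m in motifs:
        if m.matrix_name in seen:
            raise FormatError(f"{path}: duplicate matrix name {m.matrix_name!r}")
        seen.add(m.matrix_name)
    return motifs


def _parse_core_token(token: str, lineno: int, path: Path) -> tuple[int, int]:
    if not token.startswith("core="):
        raise FormatError(f"{path}:{lineno}: expected core=a-b, got {token!r}")
    try:
        a, b = token[5:].split("-")
        return int(a) - 1, int(b)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: bad core spec {token!r}") from exc


def _parse_consensus_lines(lines: list[str], path: Path) -> list[Motif]:
    motifs = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise FormatError(
                f"{path}:{lineno}: consensus TSV needs >= 4 columns"
            )
        family, name, iupac = fields[0], fields[1], fields[2]
        core = _parse_core_token(fields[3], lineno, path)
        threshold = 0.85
        if len(fields) >= 5 and fields[4].startswith("threshold="):
            threshold = float(fields[4][10:])
        try:
            motifs.append(
                Motif(family=family, matrix_name=name, consensus=iupac,
                      core=core, score_threshold=threshold)
            )
        except ValidationError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return motifs


def _parse_matrix_lines(lines: list[str], path: Path) -> list[Motif]:
    motifs = []
    name = family = None
    rows: list[list[float]] = []
    core: tuple[int, int] | None = None
    threshold = 0.85
    start_line = 0

    def flush(lineno: int) -> None:
        nonlocal name, family, rows, core, threshold
        if name is None:
            return
        if not rows:
            raise FormatError(f"{path}:{lineno}: matrix {name!r} has no rows")
        try:
            motifs.append(
                Motif(
                    family=family or name,
                    matrix_name=name,
                    counts=np.array(rows, dtype=float),
                    core=core or (0, 0),
                    score_threshold=threshold,
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        name = family = None
        rows, core, threshold = [], None, 0.85

    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        tag, _, rest = line.partition(" ")
        rest = rest.strip()
        if tag == "ID":
            flush(lineno)
            name, start_line = rest, lineno
        elif tag == "BF":
            family = rest
        elif tag == "P0":
            if rest.split() != ["A", "C", "G", "T"]:
                raise FormatError(
                    f"{path}:{lineno}: P0 header must be 'A C G T'"
                )
        elif tag == "CO":
            core = _parse_core_token(f"core={rest}", lineno, path)
        elif tag == "TH":
            threshold = float(rest)
        elif tag == "//":
            flush(lineno)
        elif tag.isdigit():
            vals = rest.split()
            if len(vals) != 4:
                raise FormatError(
                    f"{path}:{lineno}: matrix row needs 4 counts (A C G T)"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
        else:
            raise FormatError(f"{path}:{lineno}: unknown line tag {tag!r}")
    flush(len(lines) + 1)
    if not motifs:
        raise FormatError(f"{path}: no matrices found (line {start_line})")
    return motifs


def write_motif_library(motifs: Sequence[Motif], path: str | Path) -> None:
    """Write a library; consensus motifs as TSV, matrix motifs TRANSFAC-like.

    A library must be homogeneous in representation (the two formats cannot
    share one file).
    """
    kinds = {m.consensus is None for m in motifs}
    if len(kinds) > 1:
        raise ValidationError(
            "cannot mix consensus and matrix motifs in one library file"
        )
    with open(path, "w") as fh:
        if not motifs or not kinds.pop():
            fh.write("# family\tmatrix_name\tIUPAC\tcore=a-b\tthreshold=x\n")
            for m in motifs:
                cs, ce = m.core
                fh.write(
                    f"{m.family}\t{m.matrix_name}\t{m.consensus}\t"
                    f"core={cs + 1}-{ce}\tthreshold={m.score_threshold}\n"
                )
        else:
            for m in motifs:
                fh.write(f"ID {m.matrix_name}\nBF {m.family}\nP0 A C G T\n")
                for i, row in enumerate(m.counts, start=1):
                    vals = " ".join(f"{v:g}" for v in row)
                    fh.write(f"{i:02d} {vals}\n")
                cs, ce = m.core
                fh.write(f"CO {cs + 1}-{ce}\n")
                fh.write(f"TH {m.score_threshold:g}\n//\n")


def default_motif_library() -> list[Motif]:
    """The built-in consensus library: the AP-1 TPA-response-element
    heptamer (near-palindromic, so it hits both strands of an
    inverted-repeat locus) and an NFkB decamer."""
    return [
        Motif(family="V$AP-1F", matrix_name="V$AP-1.01",
              consensus="TGASTCA", core=(0, 7)),
        Motif(family="V$NFKB", matrix_name="V$NFKAPPAB.01",
              consensus="GGGRNNYYCC", core=(0, 4)),
    ]


def consensus_indicator_matrix(consensus: str) -> np.ndarray:
    """Indicator count matrix of an IUPAC consensus (1 for allowed bases).

    With ``score_threshold = 1.0`` matrix scanning of this matrix equals
    consensus scanning.
    """
    counts = np.zeros((len(consensus), 4))
    for i, code in enumerate(consensus.upper()):
        for base in IUPAC_SETS[code]:
            counts[i, _BASES.index(base)] = 1.0
    return counts


# ---------------------------------------------------------------------------
# scanning

def _encode_seq(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        code = _SEQ_CODE.get(ch)
        if code is None:
            raise ValidationError(f"non-DNA character {ch!r} in scan sequence")
        out[i] = code
    return out


def _scan_plus(codes: np.ndarray, motif: Motif) -> tuple[np.ndarray, np.ndarray]:
    """Start positions and scores of plus-strand hits on encoded sequence."""
    w = motif.width
    n = codes.shape[0]
    if n < w:
        return np.empty(0, dtype=int), np.empty(0)
    nwin = n - w + 1
    if motif.consensus is not None:
        ok = np.ones(nwin, dtype=bool)
        for k, code in enumerate(motif.consensus):
            # an N in the sequence is compatible only with motif position N
            allowed = np.zeros(5, dtype=bool)
            for base in IUPAC_SETS[code]:
                allowed[_SEQ_CODE[base]] = True
            allowed[4] = code == "N"
            ok &= allowed[codes[k:k + nwin]]
        starts = np.flatnonzero(ok)
        return starts, np.ones(starts.shape[0])
    counts5 = np.hstack([motif.counts, np.zeros((w, 1))])  # N scores 0
    scores = np.zeros(nwin)
    for k in range(w):
        scores += counts5[k, codes[k:k + nwin]]
    scores /= motif.counts.max(axis=1).sum()
    starts = np.flatnonzero(scores >= motif.score_threshold)
    return starts, scores[starts]


def scan_motifs(
    seq: str,
    lib: Iterable[Motif],
    offset: int = 0,
    sequence_name: str = "seq",
) -> list[MotifHit]:
    """Scan every window of each motif's width on both strands.

    Hit coordinates are plus-strand, shifted by ``offset`` (the position of
    ``seq`` within its parent frame). All hits are reported, including
    overlapping ones; output is sorted by start, then strand (+ before -),
    then matrix name.
    """
    if not seq:
        raise ValidationError("cannot scan an empty sequence")
    seq_u = seq.upper()
    codes_fwd = _encode_seq(seq_u)
    codes_rev = _encode_seq(revcomp(seq_u))
    n = len(seq_u)
    hits: list[MotifHit] = []
    for motif in lib:
        w = motif.width
        for strand, codes in (("+", codes_fwd), ("-", codes_rev)):
            starts, scores = _scan_plus(codes, motif)
            for s, sc in zip(starts.tolist(), scores.tolist()):
                plus_start = s if strand == "+" else n - w - s
                hits.append(
                    MotifHit(
                        motif=motif,
                        interval=GenomicInterval(
                            sequence_name,
                            plus_start + offset,
                            plus_start + w + offset,
                            strand,
                        ),
                        strand=strand,
                        plus_word=seq_u[plus_start:plus_start + w].lower(),
                        score=float(sc),
                    )
                )
    hits.sort(
        key=lambda h: (h.interval.start, h.strand, h.motif.matrix_name)
    )
    return hits


# ---------------------------------------------------------------------------
# in-silico mutagenesis

def delete_core(seq: str, hit: MotifHit, offset: int = 0) -> str:
    """Excise the hit's core positions from ``seq`` (which starts at
    ``offset`` in the hit's coordinate frame). The sequence shortens by the
    core length."""
    core = hit.core_interval()
    lo, hi = core.start - offset, core.end - offset
    if not (0 <= lo < hi <= len(seq)):
        raise ValidationError(
            f"hit core [{core.start}, {core.end}) outside sequence frame "
            f"[{offset}, {offset + len(seq)})"
        )
    return seq[:lo] + seq[hi:]


def disrupted_sites(
    variant: GenomicInterval,
    hits: Iterable[MotifHit],
    region: str = "core",
) -> list[MotifHit]:
    """Hits a sequence variant disrupts.

    ``region="core"`` (default) returns hits whose core intersects the
    variant — the sites a mutation would be expected to abolish.
    ``region="flank"`` returns hits the variant touches only outside the
    core (reported separately as flank-only contacts).
    """
    if region not in ("core", "flank"):
        raise ValidationError(f"region must be core/flank, got {region!r}")
    out = []
    for h in hits:
        core_touched = h.core_interval().overlap(variant) > 0
        if region == "core" and core_touched:
            out.append(h)
        elif (
            region == "flank"
            and not core_touched
            and h.interval.overlap(variant) > 0
        ):
            out.append(h)
    return out
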
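"""Global pairwise alignment of orthologous noncoding sequence.

Whole-locus orthology screens historically used anchored aligners on ~100-kb
loci; at the scale this package targets (individual noncoding segments of a
locus) an exact global affine-gap aligner is both feasible and preferable,
and precomputed alignments from an external aligner can be imported instead
(aligned-FASTA or MAF).

The aligner is a Gotoh three-state dynamic program (match state plus one gap
state per sequence), jitted with numba, with optional banding around the
main diagonal. Tie-breaking is fixed — at equal score prefer a
match/mismatch column, then a gap in the target, then a gap in the baseline
— so output is deterministic for fixed inputs and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
from numba import njit
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import BandError, FormatError, ValidationError
from .seqio import AnnotatedSequence, GenomicInterval

GAP = "-"
_NEG = -1e18
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

__all__ = [
    "AlignParams",
    "PairwiseAlignment",
    "align_pair",
    "score_alignment",
    "import_alignment",
    "export_alignment",
    "column_of",
    "project_interval",
]


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for global affine-gap alignment.

    A gap of length ``k`` costs ``gap_open + (k - 1) * gap_extend``; terminal
    gaps are charged like internal ones (true global alignment). ``band``
    limits the dynamic program to cells with ``|i - j| <= band``
    (``None`` = unlimited).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 4.0
    gap_extend: float = 1.0
    band: int | None = None

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValidationError(
                "need gap_open >= gap_extend >= 0, got "
                f"open={self.gap_open}, extend={self.gap_extend}"
            )
        if self.band is not None and self.band < 0:
            raise ValidationError("band must be non-negative or None")


@dataclass
class PairwiseAlignment:
    """Gapped alignment of a baseline and a target sequence.

    ``baseline_offset``/``target_offset`` place the aligned subsequences in
    their parent coordinate frames, so residue coordinates passed to
    :func:`column_of` / :func:`project_interval` are parent-frame (absolute).
    """

    baseline_name: str
    target_name: str
    baseline_aligned: str
    target_aligned: str
    score: float | None = None
    baseline_offset: int = 0
    target_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.baseline_aligned) != len(self.target_aligned):
            raise ValidationError(
                "aligned strings differ in length: "
                f"{len(self.baseline_aligned)} vs {len(self.target_aligned)}"
            )
        for k, (x, y) in enumerate(
            zip(self.baseline_aligned, self.target_aligned)
        ):
            if x == GAP and y == GAP:
                raise ValidationError(f"column {k} is gap in both sequences")

    @property
    def columns(self) -> int:
        return len(self.baseline_aligned)

    @cached_property
    def baseline_seq(self) -> str:
        return self.baseline_aligned.replace(GAP, "")

    @cached_property
    def target_seq(self) -> str:
        return self.target_aligned.replace(GAP, "")

    # residue index (0-based, within the aligned subsequence) -> column
    @cached_property
    def _b_res2col(self) -> np.ndarray:
        return np.flatnonzero(_nongap_mask(self.baseline_aligned))

    @cached_property
    def _t_res2col(self) -> np.ndarray:
        return np.flatnonzero(_nongap_mask(self.target_aligned))

    # column -> residue index, or -1 at gap columns
    @cached_property
    def _b_col2res(self) -> np.ndarray:
        return _col2res(self.baseline_aligned)

    @cached_property
    def _t_col2res(self) -> np.ndarray:
        return _col2res(self.target_aligned)

    def swapped(self) -> "PairwiseAlignment":
        """The same alignment with baseline and target roles exchanged."""
        return PairwiseAlignment(
            baseline_name=self.target_name,
            target_name=self.baseline_name,
            baseline_aligned=self.target_aligned,
            target_aligned=self.baseline_aligned,
            score=self.score,
            baseline_offset=self.target_offset,
            target_offset=self.baseline_offset,
        )


def _nongap_mask(aligned: str) -> np.ndarray:
    arr = np.frombuffer(aligned.encode("ascii"), dtype=np.uint8)
    return arr != ord(GAP)

def _col2res(aligned: str) -> np.ndarray:
    mask = _nongap_mask(aligned)
    out = np.cumsum(mask) - 1
    out[~mask] = -1
    return out


@njit(cache=True)
def _gotoh_kernel(a, b, match, mismatch, gap_open, gap_extend, band):
    """Three-state affine DP. Returns (score, end_state, tbM, tbX, tbY).

    States: 0 = M (diagonal), 1 = X (gap in target, consumes baseline),
    2 = Y (gap in baseline, consumes target). Predecessor-state preference
    at ties is M > X > Y throughout.
    """
    n = a.shape[0]
    m = b.shape[0]
    tbM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tbX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tbY = np.zeros((n + 1, m + 1), dtype=np.uint8)

    prevM = np.full(m + 1, _NEG)
    prevX = np.full(m + 1, _NEG)
    prevY = np.full(m + 1, _NEG)
    curM = np.full(m + 1, _NEG)
    curX = np.full(m + 1, _NEG)
    curY = np.full(m + 1, _NEG)

    # row 0
    curM[0] = 0.0
    hi0 = m if band < 0 else min(m, band)
    for j in range(1, hi0 + 1):
        curY[j] = -(gap_open + (j - 1) * gap_extend)
        tbY[0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        prevM, curM = curM, prevM
        prevX, curX = curX, prevX
        prevY, curY = curY, prevY
        curM[:] = _NEG
        curX[:] = _NEG
        curY[:] = _NEG
        lo = 0 if band < 0 else max(0, i - band)
        hi = m if band < 0 else min(m, i + band)
        if lo == 0:
            curX[0] = -(gap_open + (i - 1) * gap_extend)
            tbX[i, 0] = 0 if i == 1 else 1
            lo = 1
        for j in range(lo, hi + 1):
            ai = a[i - 1]
            bj = b[j - 1]
            sub = match if (ai == bj and ai < 4) else mismatch
            # M: diagonal predecessor, preference M > X > Y
            best = prevM[j - 1]
            state = 0
            if prevX[j - 1] > best:
                best = prevX[j - 1]
                state = 1
            if prevY[j - 1] > best:
                best = prevY[j - 1]
                state = 2
            if best > _NEG / 2:
                curM[j] = best + sub
                tbM[i, j] = state
            # X: vertical predecessor (i-1, j)
            best = prevM[j] - gap_open
            state = 0
            if prevX[j] - gap_extend > best:
                best = prevX[j] - gap_extend
                state = 1
            if prevY[j] - gap_open > best:
                best = prevY[j] - gap_open
                state = 2
            if best > _NEG / 2:
                curX[j] = best
                tbX[i, j] = state
            # Y: horizontal predecessor (i, j-1)
            best = curM[j - 1] - gap_open
            state = 0
            if curX[j - 1] - gap_open > best:
                best = curX[j - 1] - gap_open
                state = 1
            if curY[j - 1] - gap_extend > best:
                best = curY[j - 1] - gap_extend
                state = 2
            if best > _NEG / 2:
                curY[j] = best
                tbY[i, j] = state

    score = curM[m]
    end_state = 0
    if curX[m] > score:
        score = curX[m]
        end_state = 1
    if curY[m] > score:
        score = curY[m]
        end_state = 2
    return score, end_state, tbM, tbX, tbY


def _encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        code = _CODE.get(ch)
        if code is None:
            raise ValidationError(f"non-DNA character {ch!r} in sequence")
        out[i] = code
    return out


def align_pair(
    a: str | AnnotatedSequence,
    b: str | AnnotatedSequence,
    params: AlignParams | None = None,
    baseline_name: str | None = None,
    target_name: str | None = None,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of ``a`` (baseline) and ``b``.

    Deterministic for fixed inputs and parameters. With a band too narrow to
    connect the matrix corners (``band < |len(a) - len(b)|``) raises
    :class:`BandError` suggesting a wider band.
    """
    params = params or AlignParams()
    if isinstance(a, AnnotatedSequence):
        baseline_name = baseline_name or a.name
        a = a.residues
    if isinstance(b, AnnotatedSequence):
        target_name = target_name or b.name
        b = b.residues
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    band = -1 if params.band is None else params.band
    if band >= 0 and band < abs(len(a) - len(b)):
        raise BandError(
            f"band {band} cannot connect sequences of lengths "
            f"{len(a)} and {len(b)}; use band >= {abs(len(a) - len(b))}"
        )
    score, state, tbM, tbX, tbY = _gotoh_kernel(
        _encode(a),
        _encode(b),
        float(params.match),
        float(params.mismatch),
        float(params.gap_open),
        float(params.gap_extend),
        band,
    )
    if score < _NEG / 2:
        raise BandError(f"band {band} admits no global alignment path")
    # traceback
    i, j = len(a), len(b)
    cols_a: list[str] = []
    cols_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            state = tbM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            cols_a.append(a[i - 1])
            cols_b.append(GAP)
            state = tbX[i, j]
            i -= 1
        else:
            cols_a.append(GAP)
            cols_b.append(b[j - 1])
            state = tbY[i, j]
            j -= 1
    return PairwiseAlignment(
        baseline_name=baseline_name or "baseline",
        target_name=target_name or "target",
        baseline_aligned="".join(reversed(cols_a)),
        target_aligned="".join(reversed(cols_b)),
        score=float(score),
    )


def score_alignment(aln: PairwiseAlignment, params: AlignParams) -> float:
    """Recompute the affine score of an emitted alignment (self-consistency
    check for the aligner; also scores imported alignments)."""
    score = 0.0
    prev = ""
    for x, y in zip(aln.baseline_aligned, aln.target_aligned):
        if x == GAP or y == GAP:
            kind = "X" if y == GAP else "Y"
            score -= params.gap_extend if prev == kind else params.gap_open
            prev = kind
        else:
            ok = x == y and x in "ACGT"
            score += params.match if ok else params.mismatch
            prev = "M"
    return score


def column_of(
    aln: PairwiseAlignment, species: str, residue_index: int
) -> int:
    """Column index holding the given residue (parent-frame coordinate) of
    ``species`` in {"baseline", "target"}."""
    if species == "baseline":
        r2c, off, ln = aln._b_res2col, aln.baseline_offset, len(aln.baseline_seq)
    elif species == "target":
        r2c, off, ln = aln._t_res2col, aln.target_offset, len(aln.target_seq)
    else:
        raise ValidationError(f"species must be baseline/target, got {species!r}")
    i = residue_index - off
    if not (0 <= i < ln):
        raise ValidationError(
            f"residue index {residue_index} outside aligned {species} range "
            f"[{off}, {off + ln})"
        )
    return int(r2c[i])


def project_interval(
    aln: PairwiseAlignment,
    iv: GenomicInterval,
    source: str = "baseline",
) -> tuple[GenomicInterval | None, float]:
    """Project an interval through the alignment onto the other species.

    Returns the minimal interval in the other species spanning all non-gap
    partners of ``iv``'s residues, plus the coverage fraction (residues of
    ``iv`` aligned to a residue rather than a gap, over ``iv``'s length).
    If no residue has a partner the projection is empty: ``(None, 0.0)``.
    """
    if source == "baseline":
        r2c, off = aln._b_res2col, aln.baseline_offset
        c2r_other, off_other = aln._t_col2res, aln.target_offset
        other_name = aln.target_name
        n = len(aln.baseline_seq)
    elif source == "target":
        r2c, off = aln._t_res2col, aln.target_offset
        c2r_other, off_other = aln._b_col2res, aln.baseline_offset
        other_name = aln.baseline_name
        n = len(aln.target_seq)
    else:
        raise ValidationError(f"source must be baseline/target, got {source!r}")
    s, e = iv.start - off, iv.end - off
    if not (0 <= s < e <= n):
        raise ValidationError(
            f"interval [{iv.start}, {iv.end}) outside aligned {source} range "
            f"[{off}, {off + n})"
        )
    partners = c2r_other[r2c[s:e]]
    aligned = partners >= 0
    coverage = float(aligned.sum()) / (e - s)
    if not aligned.any():
        return None, 0.0
    lo = int(partners[aligned].min()) + off_other
    hi = int(partners[aligned].max()) + 1 + off_other
    return GenomicInterval(other_name, lo, hi, iv.strand), coverage


def import_alignment(path: str | Path, dialect: str) -> PairwiseAlignment:
    """Import a precomputed pairwise alignment (aligned-FASTA or MAF).

    Aligned-FASTA must hold exactly two records. MAF blocks must each hold
    exactly two sequences; blocks are sorted by baseline start and must be
    contiguous on both sequences (otherwise downstream coordinate maps would
    be wrong), then concatenated.
    """
    dialect = dialect.lower()
    path = Path(path)
    if dialect in ("fasta", "aligned-fasta"):
        try:
            msa = AlignIO.read(str(path), "fasta")
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        if len(msa) != 2:
            raise FormatError(
                f"{path}: aligned-FASTA must hold exactly 2 records, "
                f"found {len(msa)}"
            )
        return PairwiseAlignment(
            baseline_name=msa[0].id,
            target_name=msa[1].id,
            baseline_aligned=str(msa[0].seq).upper(),
            target_aligned=str(msa[1].seq).upper(),
        )
    if dialect == "maf":
        blocks = list(AlignIO.parse(str(path), "maf"))
        if not blocks:
            raise FormatError(f"{path}: no MAF blocks found")
        for blk in blocks:
            if len(blk) != 2:
                raise FormatError(
                    f"{path}: MAF block must hold exactly 2 sequences, "
                    f"found {len(blk)}"
                )
        blocks.sort(key=lambda blk: blk[0].annotations["start"])
        b_name = blocks[0][0].id
        t_name = blocks[0][1].id
        b_off = int(blocks[0][0].annotations["start"])
        t_off = int(blocks[0][1].annotations["start"])
        b_parts: list[str] = []
        t_parts: list[str] = []
        b_next, t_next = b_off, t_off
        for blk in blocks:
            if blk[0].id != b_name or blk[1].id != t_name:
                raise FormatError(f"{path}: inconsistent sequence names across blocks")
            bs = int(blk[0].annotations["start"])
            ts = int(blk[1].annotations["start"])
            if bs != b_next or ts != t_next:
                raise FormatError(
                    f"{path}: MAF blocks are not contiguous "
                    f"(expected starts {b_next}/{t_next}, got {bs}/{ts})"
                )
            b_parts.append(str(blk[0].seq).upper())
            t_parts.append(str(blk[1].seq).upper())
            b_next += int(blk[0].annotations["size"])
            t_next += int(blk[1].annotations["size"])
        return PairwiseAlignment(
            baseline_name=b_name,
            target_name=t_name,
            baseline_aligned="".join(b_parts),
            target_aligned="".join(t_parts),
            baseline_offset=b_off,
            target_offset=t_off,
        )
    raise ValidationError(f"unknown alignment dialect {dialect!r}")


def export_alignment(
    aln: PairwiseAlignment, path: str | Path, dialect: str
) -> None:
    """Write the alignment as aligned-FASTA or a single-block MAF."""
    dialect = dialect.lower()
    if dialect in ("fasta", "aligned-fasta"):
        msa = MultipleSeqAlignment(
            [
                SeqRecord(Seq(aln.baseline_aligned), id=aln.baseline_name,
                          description=""),
                SeqRecord(Seq(aln.target_aligned), id=aln.target_name,
                          description=""),
            ]
        )
        AlignIO.write(msa, str(path), "fasta")
        return
    if dialect == "maf":
        def rec(aligned: str, name: str, offset: int) -> SeqRecord:
            size = len(aligned.replace(GAP, ""))
            return SeqRecord(
                Seq(aligned),
                id=name,
                annotations={
                    "start": offset,
                    "size": size,
                    "strand": "+",
                    "srcSize": offset + size,
                },
            )
        msa = MultipleSeqAlignment(
            [
                rec(aln.baseline_aligned, aln.baseline_name, aln.baseline_offset),
                rec(aln.target_aligned, aln.target_name, aln.target_offset),
            ]
        )
        AlignIO.write(msa, str(path), "maf")
        return
    raise ValidationError(f"unknown alignment dialect {dialect!r}")
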
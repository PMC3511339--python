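"""Conserved-region calling by windowed percent identity.

A conserved noncoding element is operationally defined here exactly as in
identity-based orthology screens: a run of baseline sequence where a sliding
window of ``window`` baseline residues exceeds ``min_identity`` percent
identity against the aligned ortholog, merged into maximal regions of at
least ``min_span`` baseline bp. Each region gets the conservation score

    score = percent_identity + length / 60

with identity on the 0-100 scale and length in baseline bp, which rewards
both similarity and span when ranking candidate regulatory elements.

Identity is computed over alignment columns: within a window's column span,
a column counts as a match only when baseline and target carry the same
unambiguous residue; gap and N columns stay in the denominator and never
match, so indels register as non-conservation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import PairwiseAlignment, project_interval
from .errors import ValidationError
from .seqio import GenomicInterval, to_report_coords, write_bed

__all__ = [
    "ConservationParams",
    "ConservedRegion",
    "identity_profile",
    "call_conserved_regions",
    "score_region",
    "rank_regions",
    "write_regions_bed",
    "write_regions_tsv",
]


@dataclass(frozen=True)
class ConservationParams:
    """Thresholds for conserved-region calling.

    Defaults implement the ">70% identity over a 100 bp span" criterion:
    identity strictly above ``min_identity`` (percent), spans of at least
    ``min_span`` baseline bp, windows of ``window`` baseline residues
    stepped by ``step``.
    """

    min_identity: float = 70.0
    min_span: int = 100
    window: int = 100
    step: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 100):
            raise ValidationError(
                f"min_identity must be in (0, 100], got {self.min_identity}"
            )
        if not (self.min_span >= self.window >= 1):
            raise ValidationError(
                f"need min_span >= window >= 1, got span={self.min_span}, "
                f"window={self.window}"
            )
        if self.step < 1:
            raise ValidationError(f"step must be >= 1, got {self.step}")


@dataclass(frozen=True)
class ConservedRegion:
    """A maximal conserved block with per-species intervals and score."""

    baseline_interval: GenomicInterval
    target_interval: GenomicInterval | None
    length: int
    percent_identity: float
    score: float


def score_region(percent_identity: float, length: float) -> float:
    """Conservation score: ``percent_identity + length / 60``.

    ``percent_identity`` on the 0-100 scale, ``length`` in baseline bp.
    Strictly increasing in both arguments.
    """
    if percent_identity < 0 or length < 0:
        raise ValidationError(
            f"negative inputs to score_region: identity={percent_identity}, "
            f"length={length}"
        )
    return float(percent_identity) + float(length) / 60.0


def _column_stats(aln: PairwiseAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-column match indicator and baseline residue->column map."""
    b = np.frombuffer(aln.baseline_aligned.encode("ascii"), dtype=np.uint8)
    t = np.frombuffer(aln.target_aligned.encode("ascii"), dtype=np.uint8)
    unambiguous = np.isin(b, np.frombuffer(b"ACGT", dtype=np.uint8))
    match = (b == t) & unambiguous
    return match, aln._b_res2col


def identity_profile(
    aln: PairwiseAlignment, params: ConservationParams | None = None
) -> list[tuple[int, float]]:
    """Windowed percent identity along the baseline.

    One entry per window of ``window`` consecutive baseline residues
    (stepped by ``step``): ``(baseline window start, identity percent)``,
    identity computed over the alignment columns spanned by the window.
    Window starts are parent-frame (include ``baseline_offset``).
    """
    params = params or ConservationParams()
    starts, idents = _identity_arrays(aln, params)
    return list(zip(starts.tolist(), idents.tolist()))


def _identity_arrays(
    aln: PairwiseAlignment, params: ConservationParams
) -> tuple[np.ndarray, np.ndarray]:
    n = len(aln.baseline_seq)
    w = params.window
    if n < w:
        raise ValidationError(
            f"baseline ungapped length {n} is shorter than window {w}"
        )
    match, r2c = _column_stats(aln)
    csum = np.concatenate(([0], np.cumsum(match)))
    starts = np.arange(0, n - w + 1, params.step)
    col_lo = r2c[starts]
    col_hi = r2c[starts + w - 1] + 1
    idents = 100.0 * (csum[col_hi] - csum[col_lo]) / (col_hi - col_lo)
    return starts + aln.baseline_offset, idents


def call_conserved_regions(
    aln: PairwiseAlignment, params: ConservationParams | None = None
) -> list[ConservedRegion]:
    """Merge passing windows into maximal conserved regions.

    Windows with identity strictly above ``min_identity`` are merged when
    their baseline spans overlap or abut. Each merged run becomes one region
    whose identity is recomputed over the merged column span (window
    averages would double-count overlaps). When the recomputed identity of a
    run fails the threshold — low-identity flanks of edge windows can dilute
    an otherwise strong core — the weaker edge window is trimmed and the run
    re-evaluated, so the emitted region is the high-identity core of the
    run. A region is retained only if its baseline length is at least
    ``min_span`` and its identity clears ``min_identity``. Regions are
    disjoint on the baseline and reported in coordinate order.
    """
    params = params or ConservationParams()
    starts, idents = _identity_arrays(aln, params)
    match, r2c = _column_stats(aln)
    csum = np.concatenate(([0], np.cumsum(match)))
    off = aln.baseline_offset
    w = params.window

    ident_of = dict(zip(starts.tolist(), idents.tolist()))
    passing = idents > params.min_identity
    regions: list[ConservedRegion] = []
    run: list[int] = []  # passing window starts of the current merged run
    for s in starts[passing].tolist():
        if run and s > run[-1] + w:  # neither overlapping nor abutting
            region = _finish_region(aln, run, ident_of, params, csum, r2c, off)
            if region is not None:
                regions.append(region)
            run = []
        run.append(int(s))
    if run:
        region = _finish_region(aln, run, ident_of, params, csum, r2c, off)
        if region is not None:
            regions.append(region)
    return regions


def _finish_region(
    aln: PairwiseAlignment,
    run: list[int],
    ident_of: dict[int, float],
    params: ConservationParams,
    csum: np.ndarray,
    r2c: np.ndarray,
    off: int,
) -> ConservedRegion | None:
    w = params.window
    while run:
        start, end = run[0], run[-1] + w
        if end - start < params.min_span:
            return None
        col_lo = int(r2c[start - off])
        col_hi = int(r2c[end - 1 - off]) + 1
        identity = 100.0 * (csum[col_hi] - csum[col_lo]) / (col_hi - col_lo)
        if identity > params.min_identity:
            break
        # trim the weaker edge window and re-evaluate the core
        if ident_of[run[0]] <= ident_of[run[-1]]:
            run = run[1:]
        else:
            run = run[:-1]
    else:
        return None
    length = end - start
    baseline_iv = GenomicInterval(aln.baseline_name, start, end)
    target_iv, _cov = project_interval(aln, baseline_iv, source="baseline")
    return ConservedRegion(
        baseline_interval=baseline_iv,
        target_interval=target_iv,
        length=length,
        percent_identity=float(identity),
        score=score_region(identity, length),
    )


def rank_regions(
    regions: Sequence[ConservedRegion], top_k: int | None = None
) -> list[ConservedRegion]:
    """Descending by score; ties broken by greater length, then smaller
    baseline start. Returns the first ``top_k`` (all if None)."""
    ranked = sorted(
        regions,
        key=lambda r: (-r.score, -r.length, r.baseline_interval.start),
    )
    return ranked if top_k is None else ranked[:top_k]


def write_regions_bed(
    regions: Sequence[ConservedRegion], path: str | Path
) -> None:
    """BED6 on the baseline: name = CR rank, score = region score x 10
    rounded, strand '.'. Regions are written in rank order."""
    ranked = rank_regions(regions)
    write_bed(
        [r.baseline_interval for r in ranked],
        path,
        names=[f"CR{i + 1}" for i in range(len(ranked))],
        scores=[r.score * 10 for r in ranked],
        header="conserved regions; score column = conservation score x 10",
    )


def write_regions_tsv(
    regions: Sequence[ConservedRegion], path: str | Path
) -> None:
    """TSV with per-species intervals (1-based inclusive rendering),
    length, identity and score, in rank order."""
    ranked = rank_regions(regions)
    rows = []
    for i, r in enumerate(ranked):
        b_from, b_to = to_report_coords(r.baseline_interval)
        if r.target_interval is not None:
            t_from, t_to = to_report_coords(r.target_interval)
            t_name = r.target_interval.sequence_name
        else:
            t_from = t_to = pd.NA
            t_name = ""
        rows.append(
            {
                "name": f"CR{i + 1}",
                "baseline_sequence": r.baseline_interval.sequence_name,
                "baseline_from": b_from,
                "baseline_to": b_to,
                "target_sequence": t_name,
                "target_from": t_from,
                "target_to": t_to,
                "length_bp": r.length,
                "percent_identity": round(r.percent_identity, 4),
                "score": round(r.score, 4),
            }
        )
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive (from/to columns)\n")
        pd.DataFrame(
            rows,
            columns=[
                "name", "baseline_sequence", "baseline_from", "baseline_to",
                "target_sequence", "target_from", "target_to",
                "length_bp", "percent_identity", "score",
            ],
        ).to_csv(fh, sep="\t", index=False)
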
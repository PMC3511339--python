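"""Cross-species TFBS conservation: pair motif hits through an alignment.

A binding site is called conserved when the same motif hits orthologous
positions in both species: the target hit is projected onto the baseline
through the alignment and paired with the baseline hit of the same matrix
that it overlaps best, requiring a minimum reciprocal overlap (and, by
default, the same strand). Conservation is thus positional — sequence
agreement is already enforced by the motif match itself.

The report writer emits the five columns of a conventional conserved-TFBS
table — family, matrix, From-to (1-based inclusive, relative to the
conserved region's start), strand as ``(+)``/``(-)``, and the site sequence
with the core upper-cased — plus machine-readable absolute coordinates and
scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import PairwiseAlignment, project_interval
from .errors import FormatError, ValidationError
from .motifs import Motif, MotifHit
from .seqio import GenomicInterval, to_report_coords, write_bed

__all__ = [
    "ConservedTFBS",
    "pair_conserved_hits",
    "write_conserved_table",
    "parse_conserved_table",
    "write_conserved_bed",
]


@dataclass(frozen=True)
class ConservedTFBS:
    """A pair of orthologous motif hits matched through the alignment."""

    motif: Motif
    baseline_hit: MotifHit
    target_hit: MotifHit
    strand_agreement: bool
    reciprocal_overlap: float

    def __post_init__(self) -> None:
        if (
            self.baseline_hit.motif.matrix_name
            != self.target_hit.motif.matrix_name
        ):
            raise ValidationError(
                "paired hits must share a matrix name, got "
                f"{self.baseline_hit.motif.matrix_name!r} vs "
                f"{self.target_hit.motif.matrix_name!r}"
            )
        if not (0 <= self.reciprocal_overlap <= 1):
            raise ValidationError(
                f"reciprocal_overlap {self.reciprocal_overlap} outside [0, 1]"
            )


def pair_conserved_hits(
    base_hits: Sequence[MotifHit],
    targ_hits: Sequence[MotifHit],
    aln: PairwiseAlignment,
    min_overlap: float = 0.5,
    require_strand: bool = True,
) -> list[ConservedTFBS]:
    """Greedily pair same-matrix hits across species.

    Each target hit is projected onto the baseline; candidate pairs need
    reciprocal overlap >= ``min_overlap`` (overlap relative to each hit's
    own width, minimum of the two) and, if ``require_strand``, equal
    strands. Pairs are accepted greedily by descending overlap (ties by
    smaller baseline start, then smaller target start), each hit in at most
    one pair. Output sorted by baseline start.
    """
    for h in base_hits:
        if h.interval.sequence_name != aln.baseline_name:
            raise ValidationError(
                f"baseline hit on unknown frame {h.interval.sequence_name!r} "
                f"(alignment baseline is {aln.baseline_name!r})"
            )
    for h in targ_hits:
        if h.interval.sequence_name != aln.target_name:
            raise ValidationError(
                f"target hit on unknown frame {h.interval.sequence_name!r} "
                f"(alignment target is {aln.target_name!r})"
            )
    candidates: list[tuple[float, int, int, int, int]] = []
    projections: dict[int, GenomicInterval | None] = {}
    for tj, th in enumerate(targ_hits):
        proj, _cov = project_interval(aln, th.interval, source="target")
        projections[tj] = proj
    for bi, bh in enumerate(base_hits):
        for tj, th in enumerate(targ_hits):
            if bh.motif.matrix_name != th.motif.matrix_name:
                continue
            if require_strand and bh.strand != th.strand:
                continue
            proj = projections[tj]
            if proj is None:
                continue
            ov = bh.interval.overlap(proj)
            recip = min(
                ov / bh.interval.length, ov / th.interval.length
            )
            if recip >= min_overlap and recip > 0:
                candidates.append(
                    (recip, bh.interval.start, th.interval.start, bi, tj)
                )
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_b: set[int] = set()
    used_t: set[int] = set()
    pairs: list[ConservedTFBS] = []
    for recip, _bs, _ts, bi, tj in candidates:
        if bi in used_b or tj in used_t:
            continue
        used_b.add(bi)
        used_t.add(tj)
        bh, th = base_hits[bi], targ_hits[tj]
        pairs.append(
            ConservedTFBS(
                motif=bh.motif,
                baseline_hit=bh,
                target_hit=th,
                strand_agreement=bh.strand == th.strand,
                reciprocal_overlap=float(recip),
            )
        )
    pairs.sort(key=lambda p: (p.baseline_hit.interval.start,
                              p.baseline_hit.strand,
                              p.motif.matrix_name))
    return pairs


_COLUMNS = [
    "family", "matrix", "from", "to", "strand", "sequence",
    "baseline_abs_start", "baseline_abs_end",
    "target_abs_start", "target_abs_end",
    "reciprocal_overlap", "baseline_score", "target_score",
]


def write_conserved_table(
    pairs: Sequence[ConservedTFBS],
    path: str | Path,
    frame_offset: int = 0,
) -> None:
    """Write the conserved-TFBS table.

    The five leading columns mirror the printed layout (From-to 1-based
    inclusive and relative to ``frame_offset``, typically the conserved
    region's start); absolute 0-based coordinates and scores follow as
    machine columns.
    """
    rows = []
    for p in pairs:
        bh = p.baseline_hit
        frm, to = to_report_coords(bh.interval.shifted(-frame_offset))
        rows.append(
            {
                "family": p.motif.family,
                "matrix": p.motif.matrix_name,
                "from": frm,
                "to": to,
                "strand": f"({bh.strand})",
                "sequence": bh.matched_sequence if bh.strand == "+"
                else bh.display_sequence,
                "baseline_abs_start": bh.interval.start,
                "baseline_abs_end": bh.interval.end,
                "target_abs_start": p.target_hit.interval.start,
                "target_abs_end": p.target_hit.interval.end,
                "reciprocal_overlap": round(p.reciprocal_overlap, 4),
                "baseline_score": round(bh.score, 4),
                "target_score": round(p.target_hit.score, 4),
            }
        )
    with open(path, "w") as fh:
        fh.write(
            "# from/to: 1-based inclusive, relative to frame_offset="
            f"{frame_offset}; *_abs_*: 0-based half-open\n"
        )
        pd.DataFrame(rows, columns=_COLUMNS).to_csv(fh, sep="\t", index=False)


def parse_conserved_table(
    path: str | Path,
) -> pd.DataFrame:
    """Read back a conserved-TFBS table (coordinates and strands intact)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_conserved_bed(
    pairs: Sequence[ConservedTFBS], path: str | Path
) -> None:
    """BED6 of the baseline-side conserved sites."""
    write_bed(
        [p.baseline_hit.interval for p in pairs],
        path,
        names=[p.motif.matrix_name for p in pairs],
        scores=[p.reciprocal_overlap * 1000 for p in pairs],
        header="conserved TFBS (baseline side); score = reciprocal overlap x 1000",
    )
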
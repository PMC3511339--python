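"""Synthetic orthologous locus pairs with known truth.

No public accessions exist for the loci that motivated this package, so
every pipeline stage is validated on simulated ortholog pairs instead: a
uniform-random baseline sequence, a target derived from it by per-base
substitution (uniform over the three alternatives — a Jukes-Cantor-like
model where *identity*, not evolutionary distance, is the controlled
quantity, because the detection criterion is raw percent identity) plus
geometric-length indels, with

* planted high-identity blocks (the ground-truth conserved regions),
* planted motif instances written verbatim into one or both species —
  including an AP-1-like inverted-repeat pair and an NFkB-like decamer,
  mirroring the site content of a real conserved regulatory element.

Indels are suppressed inside planted motif spans so truth hit coordinates
remain exact. A single RNG stream seeded once drives all randomness; the
seed is recorded in the truth record, and identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .conservation import ConservedRegion
from .errors import ValidationError
from .seqio import AnnotatedSequence, GenomicInterval

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "PlantedBlock",
    "PlantedMotif",
    "SimulationConfig",
    "TruthBlock",
    "TruthMotif",
    "TruthRecord",
    "RecoveryMetrics",
    "simulate_ortholog_pair",
    "evaluate_recovery",
    "make_table2_fixture",
    "Table2Fragment",
]


@dataclass(frozen=True)
class PlantedBlock:
    """A conserved block to plant: baseline position, length, identity."""

    position: int
    length: int
    identity: float


@dataclass(frozen=True)
class PlantedMotif:
    """A motif instance written verbatim at ``position`` in the baseline.

    ``scope`` is ``"both"`` (also preserved verbatim in the target) or
    ``"baseline-only"`` (the target copy diverges like its surroundings).
    """

    name: str
    sequence: str
    position: int
    scope: str = "both"
    strand: str = "+"


def _default_blocks() -> list[PlantedBlock]:
    return [
        PlantedBlock(400, 250, 0.85),
        PlantedBlock(1200, 400, 0.80),
        PlantedBlock(2100, 300, 0.90),
    ]


def _default_motifs() -> list[PlantedMotif]:
    # an AP-1 inverted-repeat pair plus an NFkB decamer inside the middle
    # planted block, emulating the site content of a conserved cis-element
    return [
        PlantedMotif("AP1_fwd", "TGACTCA", 1250),
        PlantedMotif("AP1_inv", "TGAGTCA", 1310),
        PlantedMotif("NFKB", "GGGAAATTCC", 1400),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults define the package's study conditions.

    ``background_identity`` is the neutral divergence level (fraction);
    planted block identities must exceed it. ``indel_rate`` is the per-base
    probability of starting an indel, with geometric lengths of mean
    ``indel_mean_length``.
    """

    seed: int = 0
    baseline_length: int = 3000
    background_identity: float = 0.45
    indel_rate: float = 0.02
    indel_mean_length: float = 2.0
    planted_blocks: list[PlantedBlock] = field(default_factory=_default_blocks)
    planted_motifs: list[PlantedMotif] = field(default_factory=_default_motifs)
    coding_intervals: list[GenomicInterval] = field(default_factory=list)
    baseline_name: str = "baseline"
    target_name: str = "target"

    def __post_init__(self) -> None:
        for p in (self.background_identity, self.indel_rate):
            if not (0 <= p <= 1):
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.indel_mean_length < 1:
            raise ValidationError("indel_mean_length must be >= 1")
        spans: list[tuple[int, int, str]] = []
        for b in self.planted_blocks:
            if not (self.background_identity < b.identity <= 1):
                raise ValidationError(
                    f"block identity {b.identity} must be in "
                    f"({self.background_identity}, 1]"
                )
            spans.append((b.position, b.position + b.length, "block"))
        for m in self.planted_motifs:
            if m.scope not in ("both", "baseline-only"):
                raise ValidationError(f"unknown motif scope {m.scope!r}")
            spans.append(
                (m.position, m.position + len(m.sequence), "motif")
            )
        for s, e, kind in spans:
            if not (0 <= s < e <= self.baseline_length):
                raise ValidationError(
                    f"planted {kind} [{s}, {e}) outside "
                    f"[0, {self.baseline_length})"
                )
        # same-kind planted elements must not overlap (motifs may sit
        # inside blocks — that is the point)
        for kind in ("block", "motif"):
            ks = sorted(x for x in spans if x[2] == kind)
            for (s1, e1, _), (s2, _e2, _) in zip(ks, ks[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"planted {kind}s overlap at [{s2}, {e1})"
                    )
        for iv in self.coding_intervals:
            if iv.end > self.baseline_length:
                raise ValidationError("coding interval outside sequence")
            for s, e, kind in spans:
                if max(iv.start, s) < min(iv.end, e):
                    raise ValidationError(
                        f"coding interval [{iv.start}, {iv.end}) overlaps "
                        f"planted {kind} [{s}, {e})"
                    )


@dataclass(frozen=True)
class TruthBlock:
    baseline_interval: GenomicInterval
    target_interval: GenomicInterval | None
    identity: float


@dataclass(frozen=True)
class TruthMotif:
    name: str
    sequence: str
    scope: str
    strand: str
    baseline_interval: GenomicInterval
    target_interval: GenomicInterval | None


@dataclass(frozen=True)
class TruthRecord:
    """Planted truth of one simulated pair, plus the generating config."""

    blocks: list[TruthBlock]
    motifs: list[TruthMotif]
    config: SimulationConfig


def simulate_ortholog_pair(
    cfg: SimulationConfig,
) -> tuple[AnnotatedSequence, AnnotatedSequence, TruthRecord]:
    """Generate a (baseline, target, truth) triple; reproducible from seed."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.baseline_length
    baseline = _BASES[rng.integers(0, 4, L)].copy()
    for m in cfg.planted_motifs:
        word = m.sequence.upper()
        if set(word) - set("ACGT"):
            raise ValidationError(
                f"planted motif {m.name!r} must be over A/C/G/T"
            )
        baseline[m.position:m.position + len(word)] = np.frombuffer(
            word.encode("ascii"), dtype=np.uint8
        )

    identity = np.full(L, cfg.background_identity)
    for b in cfg.planted_blocks:
        identity[b.position:b.position + b.length] = b.identity
    sub_protect = np.zeros(L, dtype=bool)   # no substitutions
    indel_protect = np.zeros(L, dtype=bool)  # no indels (any planted motif)
    for m in cfg.planted_motifs:
        span = slice(m.position, m.position + len(m.sequence))
        indel_protect[span] = True
        if m.scope == "both":
            sub_protect[span] = True

    target_chars: list[int] = []
    b2t = np.full(L, -1, dtype=np.int64)
    p_mean = 1.0 / cfg.indel_mean_length
    i = 0
    t = 0
    while i < L:
        if not indel_protect[i] and rng.random() < cfg.indel_rate:
            k = int(rng.geometric(p_mean))
            if rng.random() < 0.5:
                ins = rng.integers(0, 4, k)
                target_chars.extend(_BASES[ins].tolist())
                t += k
            else:
                j = i
                while j < L and j < i + k and not indel_protect[j]:
                    j += 1
                i = j
                continue
        base = int(baseline[i])
        if not sub_protect[i] and rng.random() < 1.0 - identity[i]:
            alt = [b for b in _BASES.tolist() if b != base]
            base = alt[int(rng.integers(0, 3))]
        b2t[i] = t
        target_chars.append(base)
        t += 1
        i += 1

    target = bytes(target_chars).decode("ascii")
    baseline_str = baseline.tobytes().decode("ascii")

    def map_interval(iv: GenomicInterval) -> GenomicInterval | None:
        mapped = b2t[iv.start:iv.end]
        mapped = mapped[mapped >= 0]
        if mapped.size == 0:
            return None
        return GenomicInterval(
            cfg.target_name, int(mapped.min()), int(mapped.max()) + 1,
            iv.strand,
        )

    truth_blocks = []
    for b in cfg.planted_blocks:
        biv = GenomicInterval(cfg.baseline_name, b.position,
                              b.position + b.length)
        truth_blocks.append(TruthBlock(biv, map_interval(biv), b.identity))
    truth_motifs = []
    for m in cfg.planted_motifs:
        biv = GenomicInterval(
            cfg.baseline_name, m.position, m.position + len(m.sequence),
            m.strand,
        )
        tiv = map_interval(biv) if m.scope == "both" else None
        truth_motifs.append(
            TruthMotif(m.name, m.sequence.upper(), m.scope, m.strand, biv, tiv)
        )

    base_coding = [
        GenomicInterval(cfg.baseline_name, iv.start, iv.end, iv.strand)
        for iv in cfg.coding_intervals
    ]
    targ_coding = [
        mapped
        for iv in base_coding
        if (mapped := map_interval(iv)) is not None
    ]
    baseline_seq = AnnotatedSequence(
        species=cfg.baseline_name, name=cfg.baseline_name,
        residues=baseline_str, coding_intervals=base_coding,
    )
    target_seq = AnnotatedSequence(
        species=cfg.target_name, name=cfg.target_name,
        residues=target, coding_intervals=targ_coding,
    )
    return baseline_seq, target_seq, TruthRecord(
        blocks=truth_blocks, motifs=truth_motifs, config=cfg
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    """Planted-block recovery of a set of called conserved regions."""

    precision: float
    recall: float
    mean_boundary_error: float  # NaN when nothing matched
    n_truth: int
    n_called: int
    n_matched: int
    frac_boundaries_within_tolerance: float


def evaluate_recovery(
    truth: TruthRecord | Sequence[GenomicInterval],
    called: Sequence[ConservedRegion | GenomicInterval],
    tolerance: int = 100,
) -> RecoveryMetrics:
    """Match calls to planted blocks and score recovery.

    A call matches a truth block iff their reciprocal overlap is >= 0.5;
    matching is greedy by descending reciprocal overlap, one-to-one.
    Boundary error is the mean absolute difference of matched start/end
    coordinates; ``tolerance`` only feeds the within-tolerance fraction.
    """
    if isinstance(truth, TruthRecord):
        truth_ivs = [b.baseline_interval for b in truth.blocks]
    else:
        truth_ivs = list(truth)
    called_ivs = [
        c.baseline_interval if isinstance(c, ConservedRegion) else c
        for c in called
    ]
    cands = []
    for i, tv in enumerate(truth_ivs):
        for j, cv in enumerate(called_ivs):
            ov = tv.overlap(cv)
            recip = min(ov / tv.length, ov / cv.length) if ov else 0.0
            if recip >= 0.5:
                cands.append((recip, i, j))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_t: set[int] = set()
    used_c: set[int] = set()
    errors: list[int] = []
    for _recip, i, j in cands:
        if i in used_t or j in used_c:
            continue
        used_t.add(i)
        used_c.add(j)
        errors.append(abs(truth_ivs[i].start - called_ivs[j].start))
        errors.append(abs(truth_ivs[i].end - called_ivs[j].end))
    n_matched = len(used_t)
    return RecoveryMetrics(
        precision=n_matched / len(called_ivs) if called_ivs else 1.0,
        recall=n_matched / len(truth_ivs) if truth_ivs else 1.0,
        mean_boundary_error=float(np.mean(errors)) if errors else float("nan"),
        n_truth=len(truth_ivs),
        n_called=len(called_ivs),
        n_matched=n_matched,
        frac_boundaries_within_tolerance=(
            float(np.mean([e <= tolerance for e in errors]))
            if errors else float("nan")
        ),
    )


@dataclass(frozen=True)
class Table2Fragment:
    """A published conserved-element fragment used as a regression fixture.

    ``offset`` is the 0-based start of the fragment in its region frame, so
    1-based report coordinates of hits inside it are directly comparable
    with the printed From-to spans in ``expected``:
    ``(matrix_name, from, to, strands)``.
    """

    offset: int
    sequence: str
    expected: tuple[tuple[str, int, int, tuple[str, ...]], ...]


def make_table2_fixture() -> list[Table2Fragment]:
    """Fragments of a published mouse conserved-element table, with the
    printed binding-site spans for the AP-1 and NFkB rows.

    The AP-1 sites are listed at the same span on both strands (the
    inverted-repeat double listing); the NFkB decamer is a plus-strand row.
    """
    return [
        Table2Fragment(
            offset=121,
            sequence="tgtgactcagc",
            expected=(("V$AP-1.01", 122, 132, ("+", "-")),),
        ),
        Table2Fragment(
            offset=614,
            sequence="cctgactcact",
            expected=(("V$AP-1.01", 615, 625, ("+", "-")),),
        ),
        Table2Fragment(
            offset=724,
            sequence="ctgggaaatccct",
            expected=(("V$NFKAPPAB.01", 725, 737, ("+",)),),
        ),
    ]
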
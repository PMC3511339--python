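"""Synthetic ortholog generator: determinism, realized identity, recovery
scoring, and the printed-table fixture."""

import numpy as np
import pytest

from orthocis.align import align_pair
from orthocis.conservation import ConservationParams, call_conserved_regions
from orthocis.errors import ValidationError
from orthocis.motifs import default_motif_library, revcomp, scan_motifs
from orthocis.seqio import GenomicInterval
from orthocis.simulate import (PlantedBlock, PlantedMotif, SimulationConfig,
                               evaluate_recovery, make_table2_fixture,
                               simulate_ortholog_pair)
from orthocis.tfbs import pair_conserved_hits


def test_perfect_identity_no_indels_copies_baseline():
    cfg = SimulationConfig(
        seed=3, baseline_length=500, background_identity=1.0, indel_rate=0.0,
        planted_blocks=[], planted_motifs=[],
    )
    baseline, target, _ = simulate_ortholog_pair(cfg)
    assert baseline.residues == target.residues


def test_same_seed_reproduces_different_seed_differs():
    def make(seed):
        return SimulationConfig(
            seed=seed, baseline_length=800,
            planted_blocks=[PlantedBlock(200, 300, 0.9)], planted_motifs=[],
        )

    b1, t1, _ = simulate_ortholog_pair(make(11))
    b2, t2, _ = simulate_ortholog_pair(make(11))
    b3, t3, _ = simulate_ortholog_pair(make(12))
    assert (b1.residues, t1.residues) == (b2.residues, t2.residues)
    assert (b1.residues, t1.residues) != (b3.residues, t3.residues)


def test_planted_motifs_written_verbatim_in_both_species():
    cfg = SimulationConfig(seed=5, baseline_length=1000,
                           planted_blocks=[PlantedBlock(300, 400, 0.9)],
                           planted_motifs=[PlantedMotif("AP1", "TGACTCA",
                                                        400)])
    baseline, target, truth = simulate_ortholog_pair(cfg)
    (m,) = truth.motifs
    biv, tiv = m.baseline_interval, m.target_interval
    assert baseline.residues[biv.start:biv.end] == "TGACTCA"
    assert target.residues[tiv.start:tiv.end] == "TGACTCA"


def test_realized_block_identity_tracks_configuration():
    """Aligned identity over each planted block stays within 5 points of
    the configured value for blocks >= 200 bp, averaged over 20 seeds."""
    deviations = []
    for seed in range(20):
        cfg = SimulationConfig(
            seed=seed, baseline_length=1200,
            planted_blocks=[PlantedBlock(300, 400, 0.85)],
            planted_motifs=[],
        )
        baseline, target, truth = simulate_ortholog_pair(cfg)
        aln = align_pair(baseline, target)
        block = truth.blocks[0].baseline_interval
        params = ConservationParams(min_identity=1, min_span=block.length,
                                    window=block.length)
        sub = aln  # identity over the block's column span via the profile
        cols = [k for k, ch in enumerate(aln.baseline_aligned) if ch != "-"]
        lo, hi = cols[block.start], cols[block.end - 1] + 1
        matches = sum(
            1 for k in range(lo, hi)
            if aln.baseline_aligned[k] == aln.target_aligned[k]
        )
        deviations.append(100 * matches / (hi - lo) - 85.0)
    assert abs(np.mean(deviations)) <= 5.0


def test_overlapping_planted_elements_rejected():
    with pytest.raises(ValidationError, match="overlap"):
        SimulationConfig(planted_blocks=[PlantedBlock(100, 300, 0.9),
                                         PlantedBlock(200, 300, 0.9)])
    with pytest.raises(ValidationError):
        SimulationConfig(
            coding_intervals=[GenomicInterval("baseline", 1300, 1400)]
        )


def test_block_identity_must_exceed_background():
    with pytest.raises(ValidationError, match="identity"):
        SimulationConfig(planted_blocks=[PlantedBlock(100, 200, 0.40)])


def test_recovery_metrics_trivial_cases():
    truth = [GenomicInterval("b", 100, 300), GenomicInterval("b", 500, 700)]
    perfect = evaluate_recovery(truth, truth)
    assert (perfect.precision, perfect.recall) == (1.0, 1.0)
    assert perfect.mean_boundary_error == 0.0
    none = evaluate_recovery(truth, [])
    assert none.recall == 0.0 and none.n_matched == 0


def test_recovery_matches_brute_force_matching(rng):
    truth = [GenomicInterval("b", 100, 300), GenomicInterval("b", 500, 800)]
    for _ in range(30):
        called = []
        for iv in truth:
            if rng.random() < 0.8:
                ds = int(rng.integers(-60, 60))
                de = int(rng.integers(-60, 60))
                s, e = iv.start + ds, iv.end + de
                if e - s > 0:
                    called.append(GenomicInterval("b", max(0, s), e))
        if rng.random() < 0.3:
            called.append(GenomicInterval("b", 1000, 1100))  # false positive
        m = evaluate_recovery(truth, called)
        # oracle: count truth blocks with some call at reciprocal overlap
        # >= 0.5 (calls here never compete for the same block)
        matched = 0
        errors = []
        used = set()
        for iv in truth:
            best = None
            for j, cv in enumerate(called):
                if j in used:
                    continue
                ov = iv.overlap(cv)
                recip = min(ov / iv.length, ov / cv.length) if ov else 0
                if recip >= 0.5 and (best is None or recip > best[0]):
                    best = (recip, j)
            if best:
                used.add(best[1])
                matched += 1
                cv = called[best[1]]
                errors += [abs(iv.start - cv.start), abs(iv.end - cv.end)]
        assert m.n_matched == matched
        assert m.recall == pytest.approx(matched / len(truth))
        if called:
            assert m.precision == pytest.approx(matched / len(called))
        if errors:
            assert m.mean_boundary_error == pytest.approx(np.mean(errors))


def test_motifs_planted_in_both_species_survive_as_conserved_pairs():
    """With no indels, every planted motif is recovered as a cross-species
    pair with reciprocal overlap >= 0.8."""
    lib = default_motif_library()
    for seed in range(5):
        cfg = SimulationConfig(seed=seed, indel_rate=0.0)
        baseline, target, truth = simulate_ortholog_pair(cfg)
        aln = align_pair(baseline, target)
        bhits = scan_motifs(baseline.residues, lib,
                            sequence_name=baseline.name)
        thits = scan_motifs(target.residues, lib, sequence_name=target.name)
        pairs = pair_conserved_hits(bhits, thits, aln)
        for m in truth.motifs:
            covering = [
                p for p in pairs
                if p.baseline_hit.interval.overlap(m.baseline_interval) > 0
            ]
            assert covering, f"planted motif {m.name} lost (seed {seed})"
            assert all(p.reciprocal_overlap >= 0.8 for p in covering)


def test_full_pipeline_recall_on_strongly_conserved_blocks():
    """Planted identity >= background + 25 points and length >= 150 bp give
    recall 1.0 through align + region calling, over 20 seeds."""
    total_truth = total_matched = 0
    for seed in range(20):
        cfg = SimulationConfig(seed=500 + seed, baseline_length=2000,
                               planted_blocks=[PlantedBlock(300, 150, 0.80),
                                               PlantedBlock(1200, 300, 0.90)],
                               planted_motifs=[])
        baseline, target, truth = simulate_ortholog_pair(cfg)
        aln = align_pair(baseline, target)
        regions = call_conserved_regions(aln, ConservationParams())
        m = evaluate_recovery(truth, regions)
        total_truth += m.n_truth
        total_matched += m.n_matched
    assert total_matched == total_truth


def test_table2_fixture_contents():
    fragments = make_table2_fixture()
    by_offset = {f.offset: f for f in fragments}
    assert by_offset[121].sequence == "tgtgactcagc"
    assert by_offset[614].sequence == "cctgactcact"
    assert by_offset[724].sequence == "ctgggaaatccct"
    assert by_offset[121].expected[0][:3] == ("V$AP-1.01", 122, 132)
    assert by_offset[724].expected[0][:3] == ("V$NFKAPPAB.01", 725, 737)
    # the paired-strand listing is the printed reverse complement
    assert revcomp(by_offset[121].sequence) == "gctgagtcaca"
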
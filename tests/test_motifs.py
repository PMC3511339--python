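"""Motif models, IUPAC reverse complement, scanning, core mutagenesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import naive_scan_consensus, naive_scan_matrix
from orthocis.errors import FormatError, ValidationError
from orthocis.motifs import (Motif, consensus_indicator_matrix,
                             default_motif_library, delete_core,
                             disrupted_sites, load_motif_library, revcomp,
                             scan_motifs, write_motif_library)
from orthocis.seqio import GenomicInterval

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


def test_revcomp_matches_printed_strand_pair():
    # the inverted-repeat site listed on both strands of a published table
    assert revcomp("tgtgactcagc") == "gctgagtcaca"


@settings(derandomize=True, deadline=None, max_examples=60)
@given(seq=st.text(alphabet="ACGTRYSWKMBDHVN", min_size=0, max_size=40))
def test_revcomp_is_an_involution(seq):
    assert revcomp(revcomp(seq)) == seq


def test_revcomp_handles_n_and_rejects_invalid():
    assert revcomp("N") == "N"
    with pytest.raises(ValidationError):
        revcomp("AXG")


def test_consensus_library_round_trip(tmp_path):
    lib = default_motif_library()
    p = tmp_path / "lib.tsv"
    write_motif_library(lib, p)
    back = load_motif_library(p)
    assert [(m.family, m.matrix_name, m.consensus, m.core) for m in back] == [
        (m.family, m.matrix_name, m.consensus, m.core) for m in lib
    ]


def test_matrix_library_round_trip(tmp_path):
    counts = np.array(
        [[10, 0, 0, 0], [0, 0, 0, 10], [2, 2, 4, 2], [0, 10, 0, 0]]
    )
    m = Motif(family="F", matrix_name="M1", counts=counts, core=(1, 3),
              score_threshold=0.8)
    p = tmp_path / "lib.transfac"
    write_motif_library([m], p)
    (back,) = load_motif_library(p)
    assert np.array_equal(back.counts, counts)
    assert back.core == (1, 3)
    assert back.score_threshold == 0.8


def test_consensus_tsv_parses_width_and_core(tmp_path):
    p = tmp_path / "lib.tsv"
    p.write_text("AP1\tV$AP-1.01\tTGASTCA\tcore=1-7\n")
    (m,) = load_motif_library(p)
    assert m.width == 7 and m.core == (0, 7)


@pytest.mark.parametrize(
    "content,message",
    [
        ("AP1\tM1\tTGAXTCA\tcore=1-7\n", "IUPAC"),
        ("AP1\tM1\tTGASTCA\tcore=1-7\nAP1\tM1\tTGASTCA\tcore=1-7\n",
         "duplicate"),
        ("ID M1\nP0 A C G T\n01 1 0 0\n//\n", "4 counts"),
    ],
)
def test_library_format_errors(tmp_path, content, message):
    p = tmp_path / "bad"
    p.write_text(content)
    with pytest.raises(FormatError, match=message):
        load_motif_library(p)


def test_empty_library_scans_to_empty_hit_list():
    assert scan_motifs("ACGTACGT", []) == []


def test_scan_matches_naive_consensus_oracle(rng):
    consensi = ["TGASTCA", "GGGRNNYYCC", "RYN", "ACGT"]
    for _ in range(25):
        seq = "".join(rng.choice(list("ACGTN"), rng.integers(10, 60),
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        for cons in consensi:
            motif = Motif(family="F", matrix_name="M", consensus=cons)
            hits = scan_motifs(seq, [motif])
            got = sorted((h.interval.start, h.strand) for h in hits)
            assert got == naive_scan_consensus(seq, cons)


def test_scan_matches_naive_matrix_oracle(rng):
    for _ in range(15):
        w = int(rng.integers(3, 8))
        counts = rng.integers(0, 10, (w, 4)).astype(float) + 0.5
        motif = Motif(family="F", matrix_name="M", counts=counts,
                      score_threshold=0.8)
        seq = "".join(rng.choice(list("ACGT"), rng.integers(15, 60)))
        hits = scan_motifs(seq, [motif])
        got = sorted(
            (h.interval.start, h.strand, h.score) for h in hits
        )
        expected = naive_scan_matrix(seq, counts.tolist(), 0.8)
        assert [(s, st_) for s, st_, _ in got] == [
            (s, st_) for s, st_, _ in expected
        ]
        assert [sc for _, _, sc in got] == pytest.approx(
            [sc for _, _, sc in expected]
        )


def test_strand_symmetry_of_scanning(rng):
    motif = Motif(family="F", matrix_name="M", consensus="TGASTCA")
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGT"), 50))
        fwd = scan_motifs(seq, [motif])
        rev = scan_motifs(revcomp(seq), [motif])
        n = len(seq)
        w = motif.width
        mirrored = sorted(
            (n - h.interval.end, "+" if h.strand == "-" else "-")
            for h in rev
        )
        assert mirrored == sorted(
            (h.interval.start, h.strand) for h in fwd
        )


def test_every_hit_word_satisfies_the_motif_on_its_strand(rng):
    lib = default_motif_library()
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGT"), 80))
        for h in scan_motifs(seq, lib):
            word = h.plus_word.upper()
            if h.strand == "-":
                word = revcomp(word)
            for ch, code in zip(word, h.motif.consensus):
                assert ch in dict(
                    A="A", C="C", G="G", T="T", R="AG", Y="CT", S="CG",
                    W="AT", K="GT", M="AC", B="CGT", D="AGT", H="ACT",
                    V="ACG", N="ACGT",
                )[code]


def test_consensus_scan_is_indicator_matrix_scan_at_threshold_one(rng):
    cons = "TGASTCA"
    consensus_motif = Motif(family="F", matrix_name="C", consensus=cons)
    matrix_motif = Motif(
        family="F", matrix_name="Mx",
        counts=consensus_indicator_matrix(cons), score_threshold=1.0,
    )
    for _ in range(15):
        seq = "".join(rng.choice(list("ACGT"), 60))
        a = [(h.interval.start, h.strand)
             for h in scan_motifs(seq, [consensus_motif])]
        b = [(h.interval.start, h.strand)
             for h in scan_motifs(seq, [matrix_motif])]
        assert a == b


def test_offset_shifts_reported_coordinates():
    motif = Motif(family="F", matrix_name="M", consensus="TGACTCA")
    hits = scan_motifs("ttgactcatt".upper(), [motif], offset=100)
    starts = {h.interval.start for h in hits}
    assert starts == {101}


def test_hit_rendering_uppercases_core():
    motif = Motif(family="F", matrix_name="M", consensus="TGASTCA",
                  core=(2, 5))
    (fwd, rev) = scan_motifs("ttgactcag", [motif])
    assert fwd.strand == "+" and fwd.matched_sequence == "tgACTca"
    # reverse-strand hit displays the revcomp word, core upper-cased
    assert rev.strand == "-"
    assert rev.display_sequence == revcomp(rev.matched_sequence)


def test_delete_core_removes_the_only_site():
    motif = Motif(family="F", matrix_name="M", consensus="TGACTCA")
    seq = "AAATGACTCAAAA"
    (hit, *_) = scan_motifs(seq, [motif])
    mutated = delete_core(seq, hit)
    assert len(mutated) == len(seq) - 7
    assert scan_motifs(mutated, [motif]) == []


def test_delete_one_of_two_cores_leaves_the_other(rng):
    motif = Motif(family="F", matrix_name="M", consensus="TGACTCA")
    seq = "TGACTCA" + "TTTTTTTT" + "TGACTCA"
    hits = [h for h in scan_motifs(seq, [motif]) if h.strand == "+"]
    assert len(hits) == 2
    mutated = delete_core(seq, hits[0])
    left = [h for h in scan_motifs(mutated, [motif]) if h.strand == "+"]
    assert len(left) == 1
    assert left[0].interval.start == hits[1].interval.start - 7


def test_delete_core_at_sequence_edge():
    motif = Motif(family="F", matrix_name="M", consensus="TGACTCA")
    seq = "TGACTCAGG"
    hit = next(h for h in scan_motifs(seq, [motif]) if h.strand == "+")
    assert delete_core(seq, hit) == "GG"
    with pytest.raises(ValidationError):
        delete_core("TGA", hit)


def test_disrupted_sites_matches_interval_intersection_oracle(rng):
    lib = default_motif_library()
    seq = "".join(rng.choice(list("ACGT"), 60)) + "TGACTCA" + "GGGAAATTCC"
    hits = scan_motifs(seq, lib)
    assert hits
    for _ in range(40):
        s = int(rng.integers(0, len(seq) - 5))
        variant = GenomicInterval("seq", s, s + 5)
        got = disrupted_sites(variant, hits)
        oracle = [
            h for h in hits
            if max(h.core_interval().start, variant.start)
            < min(h.core_interval().end, variant.end)
        ]
        assert got == oracle
        for h in disrupted_sites(variant, hits, region="flank"):
            assert h.interval.overlap(variant) > 0
            assert h.core_interval().overlap(variant) == 0


def test_variant_away_from_all_cores_reports_nothing():
    lib = default_motif_library()
    seq = "TTTTTTTTTTTTTTT" + "TGACTCA"
    hits = scan_motifs(seq, lib)
    clear = disrupted_sites(GenomicInterval("seq", 2, 7), hits)
    assert clear == []
    on_core = disrupted_sites(GenomicInterval("seq", 15, 20), hits)
    assert {h.motif.matrix_name for h in on_core} == {"V$AP-1.01"}
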
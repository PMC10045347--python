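import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from arescan.motif import (
    MotifFormatError,
    MotifHit,
    PFM,
    ScanStats,
    build_pssm,
    parse_jaspar_pfm,
    relative_score,
    scan_sequence,
    score_window,
)
from arescan.sequences import reverse_complement

from conftest import TOY_PFM_TEXT, brute_force_scan, hits_as_set, random_sequence

# ---------------------------------------------------------------------------
# parsing


class TestParseJaspar:
    def test_vendored_record_width(self, ma0150):
        assert ma0150.width == 11
        assert ma0150.motif_id == "MA0150.1"

    def test_toy_round_trip(self):
        pfm = parse_jaspar_pfm(TOY_PFM_TEXT)
        assert pfm.width == 2
        assert pfm.counts.tolist() == [[3, 0], [0, 3], [0, 0], [0, 0]]

    def test_bare_dialect(self):
        pfm = parse_jaspar_pfm(">X\n3 0\n0 3\n0 0\n0 0\n")
        assert pfm.counts.tolist() == [[3, 0], [0, 3], [0, 0], [0, 0]]

    def test_unequal_row_lengths(self):
        text = ">X\nA [ 1 2 3 ]\nC [ 1 2 3 ]\nG [ 1 2 ]\nT [ 1 2 3 ]\n"
        with pytest.raises(MotifFormatError, match="unequal"):
            parse_jaspar_pfm(text)

    def test_missing_base_row(self):
        text = ">X\nA [ 1 2 ]\nC [ 1 2 ]\nG [ 1 2 ]\n"
        with pytest.raises(MotifFormatError, match="missing"):
            parse_jaspar_pfm(text)

    def test_negative_count(self):
        text = ">X\nA [ 1 -2 ]\nC [ 1 2 ]\nG [ 1 2 ]\nT [ 1 2 ]\n"
        with pytest.raises(MotifFormatError):
            parse_jaspar_pfm(text)

    def test_non_numeric_count(self):
        text = ">X\nA [ 1 z ]\nC [ 1 2 ]\nG [ 1 2 ]\nT [ 1 2 ]\n"
        with pytest.raises(MotifFormatError, match="non-numeric"):
            parse_jaspar_pfm(text)

    def test_empty_record(self):
        with pytest.raises(MotifFormatError):
            parse_jaspar_pfm("")


# ---------------------------------------------------------------------------
# PSSM construction


class TestBuildPssm:
    def test_uniform_column_scores_zero(self):
        pfm = parse_jaspar_pfm(">X\nA [ 5 ]\nC [ 5 ]\nG [ 5 ]\nT [ 5 ]\n")
        pssm = build_pssm(pfm)
        assert np.allclose(pssm.scores, 0.0)

    def test_toy_derived_values(self, toy_pssm):
        # col 1: (3+1)/(3+4)/0.25 = 16/7 for A; (0+1)/7/0.25 = 4/7 otherwise
        assert toy_pssm.scores[0, 0] == pytest.approx(math.log2(16 / 7))
        for i in (1, 2, 3):
            assert toy_pssm.scores[i, 0] == pytest.approx(math.log2(4 / 7))
        assert toy_pssm.max_score == pytest.approx(2 * math.log2(16 / 7))
        assert toy_pssm.min_score == pytest.approx(2 * math.log2(4 / 7))

    def test_ma0150_all_finite(self, ma0150, ma0150_pssm):
        assert (ma0150.counts == 0).any()  # zeros present in the raw counts
        assert np.isfinite(ma0150_pssm.scores).all()

    def test_zero_pseudocount_with_zero_count_errors(self, toy_pfm):
        with pytest.raises(ValueError, match="log\\(0\\)"):
            build_pssm(toy_pfm, pseudocount=0)

    def test_zero_pseudocount_without_zeros_ok(self):
        pfm = parse_jaspar_pfm(">X\nA [ 1 ]\nC [ 2 ]\nG [ 3 ]\nT [ 4 ]\n")
        pssm = build_pssm(pfm, pseudocount=0)
        assert np.isfinite(pssm.scores).all()

    def test_zero_background_errors(self, toy_pfm):
        with pytest.raises(ValueError, match="positive"):
            build_pssm(toy_pfm, background=[0.5, 0.5, 0.0, 0.0])

    def test_background_must_sum_to_one(self, toy_pfm):
        with pytest.raises(ValueError, match="sum to 1"):
            build_pssm(toy_pfm, background=[0.3, 0.3, 0.3, 0.3])

    def test_negative_pseudocount_errors(self, toy_pfm):
        with pytest.raises(ValueError):
            build_pssm(toy_pfm, pseudocount=-1)


# ---------------------------------------------------------------------------
# scoring


class TestScoreWindow:
    def test_toy_max(self, toy_pssm):
        assert score_window(toy_pssm, "AC") == pytest.approx(toy_pssm.max_score)

    def test_toy_min(self, toy_pssm):
        assert score_window(toy_pssm, "TT") == pytest.approx(toy_pssm.min_score)

    def test_all_zero_column_contributes_zero(self):
        pfm = parse_jaspar_pfm(">X\nA [ 3 0 ]\nC [ 0 0 ]\nG [ 0 0 ]\nT [ 0 0 ]\n")
        pssm = build_pssm(pfm)
        # column 2 has equal (pseudo-counted) frequencies: contributes 0
        assert score_window(pssm, "AA") == pytest.approx(pssm.scores[0, 0])

    def test_wrong_length(self, toy_pssm):
        with pytest.raises(ValueError, match="length"):
            score_window(toy_pssm, "ACG")

    def test_non_acgt(self, toy_pssm):
        with pytest.raises(ValueError, match="non-ACGT"):
            score_window(toy_pssm, "AN")


class TestRelativeScore:
    def test_max_is_one(self, toy_pssm):
        assert relative_score(toy_pssm, toy_pssm.max_score) == 1.0

    def test_min_is_zero(self, toy_pssm):
        assert relative_score(toy_pssm, toy_pssm.min_score) == 0.0

    def test_toy_midpoint(self, toy_pssm):
        # "AT": one best column + one worst column lands exactly halfway
        assert relative_score(toy_pssm, score_window(toy_pssm, "AT")) == pytest.approx(0.5)

    def test_out_of_range(self, toy_pssm):
        with pytest.raises(ValueError, match="outside"):
            relative_score(toy_pssm, toy_pssm.max_score + 1.0)

    def test_monotone(self, ma0150_pssm):
        grid = np.linspace(ma0150_pssm.min_score, ma0150_pssm.max_score, 25)
        rels = [relative_score(ma0150_pssm, a) for a in grid]
        assert all(x <= y for x, y in zip(rels, rels[1:]))


# ---------------------------------------------------------------------------
# scanning


class TestScanSequence:
    def test_toy_forward_only(self, toy_pssm):
        hits = scan_sequence(toy_pssm, "AACA", threshold=0.8, both_strands=False)
        assert len(hits) == 1
        (h,) = hits
        assert (h.start, h.end, h.sequence, h.strand) == (1, 3, "AC", "+")
        assert h.relative_score == 1.0

    def test_toy_both_strands_same_hit(self, toy_pssm):
        hits = scan_sequence(toy_pssm, "AACA", threshold=0.8, both_strands=True)
        assert hits_as_set(hits) == brute_force_scan(toy_pssm, "AACA", 0.8)
        assert len(hits) == 1

    def test_too_short(self, ma0150_pssm):
        assert scan_sequence(ma0150_pssm, "ACGT") == []

    def test_sorted_by_start_then_strand(self, ma0150_pssm):
        rng = np.random.default_rng(7)
        seq = random_sequence(rng, 2000)
        hits = scan_sequence(ma0150_pssm, seq, threshold=0.5)
        keys = [(h.start, h.strand) for h in hits]
        assert keys == sorted(keys)

    def test_non_acgt_windows_skipped(self, toy_pssm):
        stats = ScanStats()
        hits = scan_sequence(toy_pssm, "ANACA", threshold=0.0, both_strands=False, stats=stats)
        assert all("N" not in h.sequence for h in hits)
        assert {h.start for h in hits} == {2, 3}
        assert stats.windows_skipped == 2  # offsets 0 and 1 contain the N

    def test_minus_strand_reports_matched_mer(self, toy_pssm):
        # GT on forward = AC (the consensus) on reverse
        hits = scan_sequence(toy_pssm, "GGTG", threshold=0.99)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].sequence == "AC"
        assert (hits[0].start, hits[0].end) == (1, 3)

    def test_offset_and_chrom_propagate(self, toy_pssm):
        hits = scan_sequence(toy_pssm, "AACA", chrom="chr9", offset=100, both_strands=False)
        assert hits[0].chrom == "chr9"
        assert (hits[0].start, hits[0].end) == (101, 103)

    def test_bad_threshold(self, toy_pssm):
        with pytest.raises(ValueError):
            scan_sequence(toy_pssm, "AACA", threshold=1.5)


# ---------------------------------------------------------------------------
# properties

count_rows = st.lists(st.integers(0, 40), min_size=2, max_size=11)


@st.composite
def random_pfm(draw):
    width = draw(st.integers(2, 11))
    counts = [
        [draw(st.integers(0, 40)) for _ in range(width)] for _ in range(4)
    ]
    return PFM(motif_id="RND", counts=np.array(counts))


@st.composite
def random_background(draw):
    raw = [draw(st.floats(0.05, 1.0)) for _ in range(4)]
    total = sum(raw)
    return [x / total for x in raw]


@given(pfm=random_pfm(), data=st.data())
@settings(max_examples=60, deadline=None)
def test_scan_matches_brute_force(pfm, data):
    pssm = build_pssm(pfm)
    assume(pssm.max_score > pssm.min_score)
    seq = data.draw(st.text(alphabet="ACGTN", min_size=0, max_size=200))
    threshold = data.draw(st.sampled_from([0.0, 0.5, 0.8, 0.95]))
    hits = scan_sequence(pssm, seq, threshold=threshold, both_strands=True)
    assert hits_as_set(hits) == brute_force_scan(pssm, seq, threshold)


@given(pfm=random_pfm(), background=random_background(), pseudocount=st.floats(0.1, 5.0))
@settings(max_examples=60, deadline=None)
def test_argmax_argmin_fixed_points(pfm, background, pseudocount):
    pssm = build_pssm(pfm, background=background, pseudocount=pseudocount)
    assume(pssm.max_score > pssm.min_score)
    assert relative_score(pssm, score_window(pssm, pssm.consensus())) == 1.0
    assert relative_score(pssm, score_window(pssm, pssm.anticonsensus())) == 0.0


@given(pfm=random_pfm(), data=st.data())
@settings(max_examples=40, deadline=None)
def test_relative_score_in_unit_interval(pfm, data):
    pssm = build_pssm(pfm)
    assume(pssm.max_score > pssm.min_score)
    window = data.draw(st.text(alphabet="ACGT", min_size=pssm.width, max_size=pssm.width))
    rel = relative_score(pssm, score_window(pssm, window))
    assert 0.0 <= rel <= 1.0


@given(pfm=random_pfm(), data=st.data())
@settings(max_examples=40, deadline=None)
def test_strand_symmetry(pfm, data):
    pssm = build_pssm(pfm)
    assume(pssm.max_score > pssm.min_score)
    seq = data.draw(st.text(alphabet="ACGT", min_size=pssm.width, max_size=120))
    fwd = scan_sequence(pssm, seq, threshold=0.8)
    rev = scan_sequence(pssm, reverse_complement(seq), threshold=0.8)
    flipped = {
        (len(seq) - h.end, len(seq) - h.start, "+" if h.strand == "-" else "-",
         round(h.relative_score, 12))
        for h in rev
    }
    assert hits_as_set(fwd) == flipped


def test_ma0150_consensus_scores_one(ma0150_pssm):
    assert ma0150_pssm.consensus() == "ATGACTCAGCA"
    rel = relative_score(ma0150_pssm, score_window(ma0150_pssm, "ATGACTCAGCA"))
    assert rel == 1.0


def test_motif_hit_validation():
    with pytest.raises(ValueError):
        MotifHit("chr1", 0, 5, "ACGT", 0.0, 0.5, "+")
    with pytest.raises(ValueError):
        MotifHit("chr1", 0, 4, "ACGT", 0.0, 0.5, "x")
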
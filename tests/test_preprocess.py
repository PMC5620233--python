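"""Primer trimming and overlap-aware base-quality refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcseq.preprocess import (
    QUALITY_CAP,
    QUALITY_FLOOR,
    AmpliconReadPair,
    MateRead,
    StructuralError,
    preprocess_pair,
    preprocess_sam,
    refine_overlap_qualities,
    reverse_complement,
    trim_primer,
)
from ctcseq.simulate import simulate_amplicon_read_pairs

PRIMER = "ACGTACGTACGTACGTACGTA"  # 21 bp
assert len(PRIMER) == 21


def _read(seq, qual=30, start=100, chrom="chr1", is_reverse=False):
    return MateRead(chrom, seq, tuple([qual] * len(seq)), start, is_reverse)


def _mutate(seq, n):
    out = list(seq)
    for i in range(n):
        out[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[i]]
    return "".join(out)


class TestTrimPrimer:
    def test_exact_match_trimmed(self):
        read = _read(PRIMER + "GGGG")
        out = trim_primer(read, {"chr1": [PRIMER]})
        assert out.sequence == "GGGG"
        assert out.start == 100 + 21

    def test_four_of_21_mismatches_trimmed(self):
        # 4/21 = 0.190 <= 0.20
        read = _read(_mutate(PRIMER, 4) + "GGGG")
        out = trim_primer(read, {"chr1": [PRIMER]})
        assert out.sequence == "GGGG"

    def test_five_of_21_mismatches_not_trimmed(self):
        # 5/21 = 0.238 > 0.20
        read = _read(_mutate(PRIMER, 5) + "GGGG")
        out = trim_primer(read, {"chr1": [PRIMER]})
        assert out == read

    def test_longest_matching_primer_wins(self):
        short, long_ = PRIMER[:10], PRIMER
        read = _read(PRIMER + "GG")
        out = trim_primer(read, {"chr1": [short, long_]})
        assert out.sequence == "GG"

    def test_reverse_strand_trims_three_prime_end_of_stored_sequence(self):
        # stored reference-forward; the sequencing 5' end is the right edge
        stored = "GGGG" + reverse_complement(PRIMER)
        read = _read(stored, start=500, is_reverse=True)
        out = trim_primer(read, {"chr1": [PRIMER]})
        assert out.sequence == "GGGG"
        assert out.start == 500  # unchanged for reverse reads

    def test_primer_on_other_chromosome_ignored(self):
        read = _read(PRIMER + "GGGG", chrom="chr2")
        assert trim_primer(read, {"chr1": [PRIMER]}) == read

    def test_read_shorter_than_every_primer_is_noop(self):
        read = _read(PRIMER[:10])
        assert trim_primer(read, {"chr1": [PRIMER]}) == read


class TestRefineOverlapQualities:
    def _pair(self, seq1, q1, seq2, q2, start1=100, start2=100):
        return AmpliconReadPair(
            "p",
            MateRead("chr1", seq1, tuple(q1), start1),
            MateRead("chr1", seq2, tuple(q2), start2, is_reverse=True),
        )

    def test_agreement_sums_and_caps(self):
        pair = self._pair("AC", [30, 40], "AC", [30, 35])
        out = refine_overlap_qualities(pair)
        assert out.mate1.qualities == (60, 60)  # 30+30=60, 40+35 capped
        assert out.mate2.qualities == (60, 60)

    def test_disagreement_keeps_difference_floored(self):
        pair = self._pair("A", [30], "C", [20])
        out = refine_overlap_qualities(pair)
        assert out.mate1.qualities == (10,)  # 30-20
        assert out.mate2.qualities == (QUALITY_FLOOR,)

    def test_disagreement_tie_goes_to_mate1(self):
        pair = self._pair("A", [30], "C", [30])
        out = refine_overlap_qualities(pair)
        assert out.mate1.qualities == (QUALITY_FLOOR,)  # max(30-30, 2)
        assert out.mate2.qualities == (QUALITY_FLOOR,)

    def test_partial_overlap_leaves_flanks_unchanged(self):
        # mate1 covers 100-103, mate2 covers 102-105; overlap = [102, 104)
        pair = self._pair("AAAA", [30] * 4, "ATTT", [20] * 4, start1=100, start2=102)
        out = refine_overlap_qualities(pair)
        assert out.mate1.qualities == (30, 30, 50, 10)
        assert out.mate2.qualities == (50, 2, 20, 20)

    def test_non_overlapping_pair_unchanged(self):
        pair = self._pair("AAAA", [30] * 4, "TTTT", [20] * 4, start1=100, start2=300)
        assert refine_overlap_qualities(pair) == pair

    def test_mates_on_different_chromosomes_error(self):
        pair = AmpliconReadPair(
            "p",
            MateRead("chr1", "AA", (30, 30), 100),
            MateRead("chr2", "AA", (30, 30), 100),
        )
        with pytest.raises(StructuralError):
            refine_overlap_qualities(pair)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None)
def test_quality_monotonicity_and_saturation(seed):
    """Agreement never lowers quality, disagreement never raises it, and a
    second application only changes positions already at cap/floor."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 30))
    shift = int(rng.integers(0, n))  # mate2 start offset -> partial overlap
    seq1 = "".join(rng.choice(list("ACGT"), size=n))
    seq2 = "".join(rng.choice(list("ACGT"), size=n))
    q1 = tuple(int(q) for q in rng.integers(2, 41, size=n))
    q2 = tuple(int(q) for q in rng.integers(2, 41, size=n))
    pair = AmpliconReadPair(
        "p",
        MateRead("chr1", seq1, q1, 100),
        MateRead("chr1", seq2, q2, 100 + shift, is_reverse=True),
    )
    once = refine_overlap_qualities(pair)
    lo, hi = pair.overlap
    for refpos in range(lo, hi):
        i1, i2 = refpos - 100, refpos - 100 - shift
        agree = seq1[i1] == seq2[i2]
        if agree:
            assert once.mate1.qualities[i1] >= q1[i1]
            assert once.mate2.qualities[i2] >= q2[i2]
        else:
            assert once.mate1.qualities[i1] <= max(q1[i1], QUALITY_FLOOR)
            assert once.mate2.qualities[i2] <= max(q2[i2], QUALITY_FLOOR)
        assert QUALITY_FLOOR <= once.mate1.qualities[i1] <= QUALITY_CAP
    # saturation: refinement is not idempotent in general, but any position
    # already at the cap (agreement) or the floor (disagreement, weaker mate)
    # is a fixed point of a second application
    twice = refine_overlap_qualities(once)
    for refpos in range(lo, hi):
        i1, i2 = refpos - 100, refpos - 100 - shift
        if once.mate1.qualities[i1] in (QUALITY_CAP, QUALITY_FLOOR) and \
                once.mate2.qualities[i2] in (QUALITY_CAP, QUALITY_FLOOR):
            assert twice.mate1.qualities[i1] == once.mate1.qualities[i1]
            assert twice.mate2.qualities[i2] == once.mate2.qualities[i2]
    # outside the overlap nothing may change
    assert once.mate1.qualities[:max(0, lo - 100)] == q1[:max(0, lo - 100)]


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_trim_and_refine_commute_when_primer_outside_overlap(seed):
    """On amplicons where the primer prefix lies outside the mate overlap,
    primer trimming and overlap refinement commute."""
    rng = np.random.default_rng(seed)
    pairs = simulate_amplicon_read_pairs(
        1, amplicon_length=158, read_length=100, primer=PRIMER,
        error_rate=0.0, rng=rng,
    )
    # reads of 100 bp on a 158 bp amplicon overlap on [58, 100); the 21 bp
    # primers sit at each amplicon end, outside the overlap.
    pair = pairs[0]
    primers = {"chr1": [PRIMER]}
    a = refine_overlap_qualities(
        AmpliconReadPair(
            pair.name,
            trim_primer(pair.mate1, primers),
            trim_primer(pair.mate2, primers),
        )
    )
    refined = refine_overlap_qualities(pair)
    b = AmpliconReadPair(
        pair.name,
        trim_primer(refined.mate1, primers),
        trim_primer(refined.mate2, primers),
    )
    assert a == b


def test_preprocess_sam_round_trip(tmp_path, rng):
    """SAM in, trimmed + refined SAM out, via the real pysam plumbing."""
    pairs = simulate_amplicon_read_pairs(
        3, amplicon_length=158, read_length=150, primer=PRIMER,
        error_rate=0.0, rng=rng,
    )
    header = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"
    lines = [header.rstrip("\n")]
    for p in pairs:
        for mate, flag in ((p.mate1, 99), (p.mate2, 147)):
            qual = "".join(chr(q + 33) for q in mate.qualities)
            lines.append(
                f"{p.name}\t{flag}\tchr1\t{mate.start}\t60\t"
                f"{len(mate.sequence)}M\t=\t1\t158\t{mate.sequence}\t{qual}"
            )
    in_sam = tmp_path / "in.sam"
    in_sam.write_text("\n".join(lines) + "\n")
    out_sam = tmp_path / "out.sam"
    n = preprocess_sam(str(in_sam), {"chr1": [PRIMER]}, str(out_sam))
    assert n == 3
    import pysam

    with pysam.AlignmentFile(str(out_sam)) as fh:
        segs = list(fh)
    assert len(segs) == 6
    for seg in segs:
        # primer hard-trimmed from the sequencing 5' end of each mate
        assert len(seg.query_sequence) == 150 - 21
        # agreement in the overlap must have boosted qualities to the cap
        assert max(seg.query_qualities) == QUALITY_CAP
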
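"""Read-level refinements for overlapping amplicon mates.

Amplicon products here are shorter than twice the read length, so paired
150 bp reads overlap in the middle of the product. Two refinements exploit
this before variant calling:

* :func:`refine_overlap_qualities` — where the mates overlap, concordant
  bases corroborate each other (qualities are summed, capped at Q60) and
  discordant bases are penalized (the stronger mate keeps the quality
  difference, floored at Q2; the weaker mate drops to Q2).
* :func:`trim_primer` — the 5' end of a read is hard-trimmed when it matches
  any PCR primer designed for the same chromosome within a 20% Hamming
  mismatch allowance, so primer-encoded bases never enter pileups.

Reads are modelled as ungapped alignments (sequence, per-base Phred
qualities, 1-based start, strand), which is adequate for short amplicon
products; CIGAR-aware soft-clip handling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import pysam

__all__ = [
    "MateRead",
    "AmpliconReadPair",
    "StructuralError",
    "QUALITY_CAP",
    "QUALITY_FLOOR",
    "trim_primer",
    "refine_overlap_qualities",
    "preprocess_pair",
    "preprocess_sam",
]

QUALITY_CAP = 60
QUALITY_FLOOR = 2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class StructuralError(ValueError):
    """Mates that cannot form an overlapping amplicon pair (e.g. different chrom)."""


@dataclass(frozen=True)
class MateRead:
    """One mate, stored in reference-forward orientation (SAM convention)."""

    chrom: str
    sequence: str
    qualities: Tuple[int, ...]
    start: int  # 1-based alignment start
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities lengths differ")
        if self.start < 1:
            raise ValueError("alignment start must be >= 1")

    @property
    def end(self) -> int:
        """1-based exclusive end of the ungapped alignment."""
        return self.start + len(self.sequence)


@dataclass(frozen=True)
class AmpliconReadPair:
    name: str
    mate1: MateRead
    mate2: MateRead

    @property
    def overlap(self) -> Tuple[int, int]:
        """Overlapping reference interval [start, end), 1-based; empty if end<=start."""
        return (
            max(self.mate1.start, self.mate2.start),
            min(self.mate1.end, self.mate2.end),
        )


def trim_primer(
    read: MateRead,
    primers: Mapping[str, Sequence[str]],
    max_mismatch_frac: float = 0.20,
) -> MateRead:
    """Hard-trim the longest primer matching the read's 5' prefix.

    A primer of length L matches when the Hamming distance between it and the
    read's 5'-most L bases (in sequencing orientation) is at most
    ``max_mismatch_frac * L``. At most one trim is applied per read. For
    forward-strand reads the alignment start advances by the trimmed length;
    for reverse-strand reads the 5' end is the high-coordinate end, so the
    start is unchanged. A read shorter than every primer is returned as-is.
    """
    candidates = primers.get(read.chrom, ())
    oriented = (
        reverse_complement(read.sequence) if read.is_reverse else read.sequence
    )
    best_len = 0
    for primer in candidates:
        L = len(primer)
        if L == 0 or L > len(oriented) or L <= best_len:
            continue
        mismatches = sum(a != b for a, b in zip(oriented[:L], primer))
        if mismatches / L <= max_mismatch_frac:
            best_len = L
    if best_len == 0:
        return read
    if read.is_reverse:
        return replace(
            read,
            sequence=read.sequence[:-best_len],
            qualities=read.qualities[:-best_len],
        )
    return replace(
        read,
        sequence=read.sequence[best_len:],
        qualities=read.qualities[best_len:],
        start=read.start + best_len,
    )


def refine_overlap_qualities(pair: AmpliconReadPair) -> AmpliconReadPair:
    """Adjust base qualities where the two mates overlap on the reference.

    Agreeing bases: both mates get ``min(q1 + q2, 60)``. Disagreeing bases:
    the higher-quality mate keeps ``max(q_high - q_low, 2)`` and the other
    mate is floored at Q2; on a quality tie mate 1 is treated as the stronger
    mate. Positions outside the overlap are unchanged. Raises
    :class:`StructuralError` if the mates sit on different chromosomes.
    """
    m1, m2 = pair.mate1, pair.mate2
    if m1.chrom != m2.chrom:
        raise StructuralError(
            f"mates of {pair.name!r} on different chromosomes: "
            f"{m1.chrom} vs {m2.chrom}"
        )
    lo, hi = pair.overlap
    if hi <= lo:
        return pair
    q1, q2 = list(m1.qualities), list(m2.qualities)
    for refpos in range(lo, hi):
        i1, i2 = refpos - m1.start, refpos - m2.start
        b1, b2 = m1.sequence[i1], m2.sequence[i2]
        if b1 == b2:
            boosted = min(q1[i1] + q2[i2], QUALITY_CAP)
            q1[i1] = q2[i2] = boosted
        else:
            if q1[i1] >= q2[i2]:  # tie goes to mate 1
                q1[i1] = max(q1[i1] - q2[i2], QUALITY_FLOOR)
                q2[i2] = QUALITY_FLOOR
            else:
                q2[i2] = max(q2[i2] - q1[i1], QUALITY_FLOOR)
                q1[i1] = QUALITY_FLOOR
    return AmpliconReadPair(
        pair.name,
        replace(m1, qualities=tuple(q1)),
        replace(m2, qualities=tuple(q2)),
    )


def preprocess_pair(
    pair: AmpliconReadPair,
    primers: Mapping[str, Sequence[str]],
    max_mismatch_frac: float = 0.20,
) -> AmpliconReadPair:
    """Primer-trim both mates, then refine overlap qualities."""
    trimmed = AmpliconReadPair(
        pair.name,
        trim_primer(pair.mate1, primers, max_mismatch_frac),
        trim_primer(pair.mate2, primers, max_mismatch_frac),
    )
    return refine_overlap_qualities(trimmed)


# ---------------------------------------------------------------------------
# SAM plumbing
# ---------------------------------------------------------------------------

def _pairs_from_sam(path: str) -> Tuple[pysam.AlignmentHeader, List[Tuple[pysam.AlignedSegment, pysam.AlignedSegment]]]:
    by_name: Dict[str, pysam.AlignedSegment] = {}
    pairs: List[Tuple[pysam.AlignedSegment, pysam.AlignedSegment]] = []
    with pysam.AlignmentFile(path, "r") as fh:
        header = fh.header.copy()
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            mate = by_name.pop(seg.query_name, None)
            if mate is None:
                by_name[seg.query_name] = seg
            else:
                first, second = (mate, seg) if mate.is_read1 else (seg, mate)
                pairs.append((first, second))
    return header, pairs


def _to_mate(seg: pysam.AlignedSegment) -> MateRead:
    return MateRead(
        chrom=seg.reference_name,
        sequence=seg.query_sequence,
        qualities=tuple(seg.query_qualities),
        start=seg.reference_start + 1,
        is_reverse=seg.is_reverse,
    )


def preprocess_sam(
    in_sam: str,
    primers: Mapping[str, Sequence[str]],
    out_sam: str,
    max_mismatch_frac: float = 0.20,
) -> int:
    """Apply primer trimming and overlap refinement to every proper pair.

    Reads the input SAM, processes each mapped primary pair, and writes a SAM
    with updated sequences, qualities and positions. Returns the number of
    pairs processed. Assumes ungapped amplicon alignments (CIGAR rewritten to
    a full match over the trimmed length).
    """
    header, pairs = _pairs_from_sam(in_sam)
    n = 0
    with pysam.AlignmentFile(out_sam, "w", header=header) as out:
        for seg1, seg2 in pairs:
            pair = AmpliconReadPair(seg1.query_name, _to_mate(seg1), _to_mate(seg2))
            refined = preprocess_pair(pair, primers, max_mismatch_frac)
            for seg, mate in ((seg1, refined.mate1), (seg2, refined.mate2)):
                seg.query_sequence = mate.sequence
                seg.query_qualities = list(mate.qualities)
                seg.reference_start = mate.start - 1
                seg.cigartuples = [(0, len(mate.sequence))]
                out.write(seg)
            n += 1
    return n
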
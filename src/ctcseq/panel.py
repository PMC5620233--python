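"""Amplicon panel definition and per-patient clinical records.

Panel regions use BED convention: 0-based, half-open intervals. Variant
positions (1-based) fall inside a region iff ``start <= pos - 1 < end``.
"""

from __future__ import annotations

import bisect
import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

__all__ = ["Region", "Panel", "ClinicalRecord", "reference_base"]

_BASES = "ACGT"


def reference_base(chrom: str, pos: int) -> str:
    """Deterministic synthetic reference base for a locus.

    The pipeline carries no genome sequence; this hash-derived base stands in
    for the reference so that every generator draws a consistent ref allele at
    a given locus (and so that chance key collisions between samples remain
    possible, as they are on a real genome).
    """
    return _BASES[zlib.crc32(f"{chrom}:{pos}".encode()) % 4]


@dataclass(frozen=True, order=True)
class Region:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    gene: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class Panel:
    """Targeted regions plus the per-chromosome PCR primer sequences."""

    def __init__(
        self,
        regions: Sequence[Region],
        primers: Optional[Dict[str, List[str]]] = None,
    ) -> None:
        self.regions: Tuple[Region, ...] = tuple(
            sorted(regions, key=lambda r: (r.chrom, r.start))
        )
        self.primers: Dict[str, List[str]] = {
            chrom: list(seqs) for chrom, seqs in (primers or {}).items()
        }
        self._trees: Dict[str, IntervalTree] = {}
        prev: Dict[str, Region] = {}
        for r in self.regions:
            if r.chrom in prev and r.start < prev[r.chrom].end:
                raise ValueError(
                    f"overlapping panel regions on {r.chrom}: "
                    f"{prev[r.chrom]} and {r}"
                )
            prev[r.chrom] = r
            self._trees.setdefault(r.chrom, IntervalTree())[r.start : r.end] = r.gene
        # cumulative offsets for mapping a panel-wide coordinate to a locus
        self._cum: List[int] = [0]
        for r in self.regions:
            self._cum.append(self._cum[-1] + r.length)

    @property
    def total_length(self) -> int:
        return self._cum[-1]

    @property
    def genes(self) -> List[str]:
        seen: List[str] = []
        for r in self.regions:
            if r.gene not in seen:
                seen.append(r.gene)
        return seen

    def locus_at(self, offset: int) -> Tuple[str, int]:
        """Map a panel-wide offset in [0, total_length) to (chrom, 1-based pos)."""
        if not 0 <= offset < self.total_length:
            raise IndexError(f"offset {offset} outside panel of {self.total_length} bp")
        i = bisect.bisect_right(self._cum, offset) - 1
        r = self.regions[i]
        return r.chrom, r.start + (offset - self._cum[i]) + 1

    def gene_at(self, chrom: str, pos: int) -> Optional[str]:
        """Gene whose region contains the 1-based position, or None (off-target)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos - 1]
        if not hits:
            return None
        return next(iter(hits)).data

    def __eq__(self, other) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return self.regions == other.regions and self.primers == other.primers


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical covariates used in the association analyses.

    ``cea`` is the serum carcinoembryonic antigen level in ng/ml (>= 5 is
    conventionally abnormal); ``dukes`` is the Dukes' stage A-D; ``msi`` is
    microsatellite status. Missing values are None.
    """

    patient_id: str
    age: Optional[int] = None
    dukes: Optional[str] = None
    cea: Optional[float] = None
    msi: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cea is not None and self.cea < 0:
            raise ValueError(f"CEA must be >= 0, got {self.cea}")
        if self.dukes is not None and self.dukes not in ("A", "B", "C", "D"):
            raise ValueError(f"Dukes' stage must be A-D, got {self.dukes!r}")
        if self.msi is not None and self.msi not in ("MSI", "MSS"):
            raise ValueError(f"MSI status must be MSI or MSS, got {self.msi!r}")
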
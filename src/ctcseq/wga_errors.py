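"""Characterization of whole-genome-amplification artifacts.

Amplified normal-tissue DNA, called against its unamplified counterpart,
yields variants that are by construction WGA errors. Errors seen in two or
more independent amplifications ("recurrent") form a blacklist that is
removed from every sample; the remainder are random non-recurrent errors.
The module also estimates how often a surviving error would, by chance,
match a somatic mutation of the same patient's tumor — the false-positive
tumor-match rate.
"""

from __future__ import annotations

import os
import statistics
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .variants import (
    GenomicVariant,
    ObservedVariant,
    PairingError,
    SampleRole,
    SampleVariantSet,
)

__all__ = [
    "InsufficientControlsError",
    "UndefinedRateError",
    "ErrorCallSet",
    "BlacklistEntry",
    "Blacklist",
    "ErrorVafSummary",
    "FpMatchRate",
    "call_amplification_errors",
    "build_blacklist",
    "summarize_error_vafs",
    "estimate_fp_match_rate",
    "write_blacklist",
    "read_blacklist",
]

Key = Tuple[str, int, str, str]


class InsufficientControlsError(ValueError):
    """Fewer than two amplified-normal error sets: recurrence is undefined."""


class UndefinedRateError(ZeroDivisionError):
    """No retained error variants: the match rate has an empty denominator."""


@dataclass
class ErrorCallSet:
    """WGA error calls of one patient's amplified normal sample."""

    patient_id: str
    errors: List[ObservedVariant]

    def keys(self) -> frozenset:
        return frozenset(ov.variant.key for ov in self.errors)

    def __len__(self) -> int:
        return len(self.errors)


def call_amplification_errors(
    amplified: SampleVariantSet, unamplified: SampleVariantSet
) -> ErrorCallSet:
    """Variants present in the amplified sample but absent from the matched
    unamplified normal — i.e. errors introduced by the amplification."""
    if amplified.patient_id != unamplified.patient_id:
        raise PairingError(
            f"amplified sample {amplified.sample_id} (patient "
            f"{amplified.patient_id}) does not match unamplified sample "
            f"{unamplified.sample_id} (patient {unamplified.patient_id})"
        )
    germline = unamplified.keys()
    errors = [ov for ov in amplified if ov.variant.key not in germline]
    return ErrorCallSet(patient_id=amplified.patient_id, errors=errors)


@dataclass(frozen=True)
class BlacklistEntry:
    n_samples: int
    vaf_median: float


class Blacklist:
    """Recurrent WGA-error variant keys with recurrence count and VAF summary."""

    def __init__(self, entries: Mapping[Key, BlacklistEntry], min_recurrence: int = 2):
        self.min_recurrence = min_recurrence
        self.entries: Dict[Key, BlacklistEntry] = dict(entries)
        for key, e in self.entries.items():
            if e.n_samples < min_recurrence:
                raise ValueError(
                    f"blacklist entry {key} seen in {e.n_samples} sample(s), "
                    f"below min_recurrence={min_recurrence}"
                )

    def __contains__(self, item) -> bool:
        if isinstance(item, ObservedVariant):
            item = item.variant
        if isinstance(item, GenomicVariant):
            item = item.key
        return item in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Blacklist):
            return NotImplemented
        return (
            self.entries == other.entries
            and self.min_recurrence == other.min_recurrence
        )

    @classmethod
    def empty(cls) -> "Blacklist":
        return cls({}, min_recurrence=2)


def build_blacklist(
    error_sets: Sequence[ErrorCallSet], min_recurrence: int = 2
) -> Blacklist:
    """Blacklist every key observed in >= ``min_recurrence`` distinct error sets."""
    if len(error_sets) < 2:
        raise InsufficientControlsError(
            f"need >= 2 amplified-normal error sets to define recurrence, "
            f"got {len(error_sets)}"
        )
    counts: Dict[Key, int] = {}
    vafs: Dict[Key, List[float]] = {}
    for es in error_sets:
        seen: Dict[Key, float] = {}
        for ov in es.errors:
            seen[ov.variant.key] = ov.vaf  # one incidence per sample per key
        for key, vaf in seen.items():
            counts[key] = counts.get(key, 0) + 1
            vafs.setdefault(key, []).append(vaf)
    entries = {
        key: BlacklistEntry(n_samples=c, vaf_median=statistics.median(vafs[key]))
        for key, c in counts.items()
        if c >= min_recurrence
    }
    return Blacklist(entries, min_recurrence=min_recurrence)


@dataclass
class ErrorVafSummary:
    """VAF medians and counts of the recurrent / non-recurrent partitions.

    A median is None when its partition is empty (undefined, not zero).
    """

    recurrent_vaf_median: Optional[float]
    nonrecurrent_vaf_median: Optional[float]
    n_recurrent: int
    n_nonrecurrent: int


def summarize_error_vafs(
    error_sets: Sequence[ErrorCallSet], blacklist: Blacklist
) -> ErrorVafSummary:
    """Partition every error observation by blacklist membership."""
    recurrent: List[float] = []
    nonrecurrent: List[float] = []
    for es in error_sets:
        for ov in es.errors:
            (recurrent if ov.variant.key in blacklist else nonrecurrent).append(ov.vaf)
    return ErrorVafSummary(
        recurrent_vaf_median=statistics.median(recurrent) if recurrent else None,
        nonrecurrent_vaf_median=statistics.median(nonrecurrent) if nonrecurrent else None,
        n_recurrent=len(recurrent),
        n_nonrecurrent=len(nonrecurrent),
    )


@dataclass
class FpMatchRate:
    n_match: int
    n_total: int
    rate_percent: float  # 100 * n_match / n_total, one decimal


def estimate_fp_match_rate(
    error_sets: Sequence[ErrorCallSet],
    blacklist: Blacklist,
    tumor_sets: Mapping[str, SampleVariantSet] | Sequence[SampleVariantSet],
    min_vaf: float = 0.01,
) -> FpMatchRate:
    """False-positive tumor-match rate of surviving WGA errors.

    The denominator counts error variants that survive the filters applied to
    real samples (VAF strictly above ``min_vaf`` and key not blacklisted);
    the numerator counts those whose key matches a somatic variant in the
    same patient's tumor.
    """
    if not isinstance(tumor_sets, Mapping):
        tumor_sets = {t.patient_id: t for t in tumor_sets}
    n_total = 0
    n_match = 0
    for es in error_sets:
        tumor = tumor_sets.get(es.patient_id)
        if tumor is None:
            raise PairingError(f"no paired tumor sample for patient {es.patient_id}")
        tumor_keys = tumor.keys()
        for ov in es.errors:
            if ov.vaf <= min_vaf or ov.variant.key in blacklist:
                continue
            n_total += 1
            if ov.variant.key in tumor_keys:
                n_match += 1
    if n_total == 0:
        raise UndefinedRateError(
            "no error variants survive the filters; match rate is undefined"
        )
    return FpMatchRate(
        n_match=n_match,
        n_total=n_total,
        rate_percent=round(100.0 * n_match / n_total, 1),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_BL_COLUMNS = ("chrom", "pos", "ref", "alt", "n_samples", "vaf_median")


def write_blacklist(blacklist: Blacklist, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#min_recurrence={blacklist.min_recurrence}\n")
        fh.write("\t".join(_BL_COLUMNS) + "\n")
        for key in sorted(blacklist.entries):
            e = blacklist.entries[key]
            chrom, pos, ref, alt = key
            fh.write(
                f"{chrom}\t{pos}\t{ref}\t{alt}\t{e.n_samples}\t{e.vaf_median:.6g}\n"
            )


def read_blacklist(path: str | os.PathLike) -> Blacklist:
    entries: Dict[Key, BlacklistEntry] = {}
    min_recurrence = 2
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#min_recurrence="):
                    min_recurrence = int(line.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if tuple(fields) == _BL_COLUMNS:
                continue
            chrom, pos, ref, alt, n_samples, vaf_median = fields
            entries[(chrom, int(pos), ref, alt)] = BlacklistEntry(
                n_samples=int(n_samples), vaf_median=float(vaf_median)
            )
    return Blacklist(entries, min_recurrence=min_recurrence)
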
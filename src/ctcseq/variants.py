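"""Variant domain model: genomic variants, observed calls, per-sample call sets.

Conventions
-----------
Variant positions are 1-based (VCF convention). ``pos`` is the reference
position of the first base of ``ref``. Indels are stored in minimal left-most
representation with a single anchor base (see :func:`normalize_variant`), so
that set operations across samples (tumor/CTC intersection, blacklist removal)
are well defined regardless of how a caller chose to spell an indel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Tuple

__all__ = [
    "InvalidVariantError",
    "PairingError",
    "VariantClass",
    "GenomicVariant",
    "ObservedVariant",
    "SampleRole",
    "SampleVariantSet",
    "normalize_variant",
    "variants_match",
]

_BASES = frozenset("ACGT")


class InvalidVariantError(ValueError):
    """A variant violates its structural invariants (e.g. ref == alt)."""


class PairingError(ValueError):
    """Two sample sets that must belong together (same patient) do not."""


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    MNV = "MNV"  # equal-length multi-base substitution


@dataclass(frozen=True, order=True)
class GenomicVariant:
    """A genomic sequence variant in VCF-style coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InvalidVariantError("chrom must be non-empty")
        if self.pos < 1:
            raise InvalidVariantError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele:
                raise InvalidVariantError(f"{name} allele must be non-empty")
            if not set(allele) <= _BASES:
                raise InvalidVariantError(
                    f"{name} allele {allele!r} contains non-ACGT characters"
                )
        if self.ref == self.alt:
            raise InvalidVariantError(
                f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}"
            )

    @property
    def vclass(self) -> VariantClass:
        lr, la = len(self.ref), len(self.alt)
        if lr == la == 1:
            return VariantClass.SNV
        if la > lr:
            return VariantClass.INS
        if lr > la:
            return VariantClass.DEL
        return VariantClass.MNV

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


def normalize_variant(v: GenomicVariant) -> GenomicVariant:
    """Return the minimal, left-anchored representation of ``v``.

    Shared suffix bases are trimmed first, then shared prefix bases (advancing
    ``pos``); one anchor base is always retained for indels. The operation is
    idempotent. Raises :class:`InvalidVariantError` if the alleles are
    identical after trimming (which can only happen for invalid input since
    the constructor already rejects ref == alt).
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise InvalidVariantError(f"variant {v} trims to ref == alt")
    if ref == v.ref and alt == v.alt and pos == v.pos:
        return v
    return GenomicVariant(v.chrom, pos, ref, alt)


def variants_match(a: GenomicVariant, b: GenomicVariant) -> bool:
    """True iff the two variants share a normalized (chrom, pos, ref, alt)."""
    return normalize_variant(a).key == normalize_variant(b).key


@dataclass(frozen=True)
class ObservedVariant:
    """One called variant in one sample, with read support."""

    variant: GenomicVariant
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise InvalidVariantError(f"depth must be >= 1, got {self.depth}")
        if not 0 <= self.alt_count <= self.depth:
            raise InvalidVariantError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
            )

    @property
    def vaf(self) -> float:
        """Variant allele frequency, alt_count / depth."""
        return self.alt_count / self.depth

    def normalized(self) -> "ObservedVariant":
        nv = normalize_variant(self.variant)
        if nv is self.variant:
            return self
        return replace(self, variant=nv)


class SampleRole(str, enum.Enum):
    TUMOR = "TUMOR"
    NORMAL = "NORMAL"
    AMPLIFIED_NORMAL = "AMPLIFIED_NORMAL"
    CTC_WGA = "CTC_WGA"


class DuplicateVariantError(ValueError):
    """Two variants in one sample share a normalized key."""


class SampleVariantSet:
    """All variants called in one sample.

    Variants are stored normalized and are unique by normalized key.
    Iteration is in sorted key order, so serialization is deterministic.
    """

    def __init__(
        self,
        sample_id: str,
        patient_id: str,
        role: SampleRole,
        variants: Iterable[ObservedVariant] = (),
        replicate_index: Optional[int] = None,
    ) -> None:
        role = SampleRole(role)
        if role is SampleRole.CTC_WGA:
            if replicate_index is None:
                replicate_index = 1
            if replicate_index < 1:
                raise ValueError("replicate_index must be >= 1")
        elif replicate_index is not None:
            raise ValueError(
                f"replicate_index is only meaningful for CTC_WGA, not {role.value}"
            )
        self.sample_id = sample_id
        self.patient_id = patient_id
        self.role = role
        self.replicate_index = replicate_index
        self._by_key: dict[Tuple[str, int, str, str], ObservedVariant] = {}
        for ov in variants:
            self.add(ov)

    def add(self, ov: ObservedVariant) -> None:
        ov = ov.normalized()
        key = ov.variant.key
        if key in self._by_key:
            raise DuplicateVariantError(
                f"duplicate normalized key {key} in sample {self.sample_id}"
            )
        self._by_key[key] = ov

    # -- set-like interface -------------------------------------------------
    def keys(self) -> frozenset:
        return frozenset(self._by_key)

    def get(self, key) -> Optional[ObservedVariant]:
        if isinstance(key, GenomicVariant):
            key = normalize_variant(key).key
        return self._by_key.get(key)

    def __contains__(self, key) -> bool:
        if isinstance(key, GenomicVariant):
            key = normalize_variant(key).key
        if isinstance(key, ObservedVariant):
            key = key.normalized().variant.key
        return key in self._by_key

    def __iter__(self) -> Iterator[ObservedVariant]:
        for key in sorted(self._by_key):
            yield self._by_key[key]

    def __len__(self) -> int:
        return len(self._by_key)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SampleVariantSet):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.patient_id == other.patient_id
            and self.role == other.role
            and self.replicate_index == other.replicate_index
            and self._by_key == other._by_key
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SampleVariantSet({self.sample_id!r}, patient={self.patient_id!r}, "
            f"role={self.role.value}, n={len(self)})"
        )

    def subset(self, keep, sample_id: Optional[str] = None) -> "SampleVariantSet":
        """New set with the variants for which ``keep(ov)`` is true."""
        return SampleVariantSet(
            sample_id or self.sample_id,
            self.patient_id,
            self.role,
            (ov for ov in self if keep(ov)),
            replicate_index=self.replicate_index,
        )
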
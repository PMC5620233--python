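"""Mutation spectrum: substitution-class frequencies of an SNV set.

By default single-nucleotide substitutions are collapsed to a pyrimidine
reference base, giving the six canonical classes C>A, C>G, C>T, T>A, T>C,
T>G (a G>A change is the same event as C>T read from the other strand).
Colorectal tumors show a predominant C>T class. A 12-class mode without
strand collapsing is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

from .variants import GenomicVariant, ObservedVariant, VariantClass

__all__ = [
    "SUBSTITUTION_CLASSES",
    "ZeroSnvError",
    "SpectrumProfile",
    "compute_spectrum",
    "dominant_class",
]

SUBSTITUTION_CLASSES: Tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

_RAW_CLASSES: Tuple[str, ...] = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


class ZeroSnvError(ValueError):
    """No SNVs in the input: the spectrum is undefined, not all-zero."""


@dataclass
class SpectrumProfile:
    """Normalized substitution-class frequencies."""

    frequencies: Dict[str, float]
    n_snvs: int
    n_non_snv: int = 0
    collapsed: bool = True

    def __post_init__(self) -> None:
        if self.n_snvs > 0:
            total = sum(self.frequencies.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total}, expected 1")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("negative class frequency")


def _collapse(ref: str, alt: str) -> str:
    if ref in ("C", "T"):
        return f"{ref}>{alt}"
    return f"{_COMP[ref]}>{_COMP[alt]}"


def compute_spectrum(
    variants: Iterable[GenomicVariant | ObservedVariant],
    collapse_strands: bool = True,
) -> SpectrumProfile:
    """Class frequencies over the SNVs of ``variants``.

    Non-SNVs (indels, multi-base substitutions) are ignored but counted in
    ``n_non_snv``. Raises :class:`ZeroSnvError` when no SNV is present.
    """
    classes = SUBSTITUTION_CLASSES if collapse_strands else _RAW_CLASSES
    counts = {c: 0 for c in classes}
    n_snvs = 0
    n_non_snv = 0
    for v in variants:
        if isinstance(v, ObservedVariant):
            v = v.variant
        if v.vclass is not VariantClass.SNV:
            n_non_snv += 1
            continue
        label = _collapse(v.ref, v.alt) if collapse_strands else f"{v.ref}>{v.alt}"
        counts[label] += 1
        n_snvs += 1
    if n_snvs == 0:
        raise ZeroSnvError("no SNVs in input; spectrum is undefined")
    return SpectrumProfile(
        frequencies={c: counts[c] / n_snvs for c in classes},
        n_snvs=n_snvs,
        n_non_snv=n_non_snv,
        collapsed=collapse_strands,
    )


def dominant_class(p: SpectrumProfile) -> str:
    """The argmax substitution class; ties break by fixed class order."""
    if p.n_snvs <= 0:
        raise ZeroSnvError("dominant class undefined for an empty spectrum")
    classes = SUBSTITUTION_CLASSES if p.collapsed else _RAW_CLASSES
    return max(classes, key=lambda c: (p.frequencies.get(c, 0.0), -classes.index(c)))
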
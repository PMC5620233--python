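"""The CTC somatic-mutation calling cascade.

Order of operations on each CTC-WGA sample: remove blacklisted recurrent WGA
errors, keep variants with allele frequency strictly above 1%, then intersect
with the matched primary tumor's somatic variants (the conservative
tumor-matched call set). Variants found concordantly in two independent WGA
replicates but absent from both the blacklist and the tumor are reported
separately as candidate disseminated-subclone ("CTC-private") mutations.
Every stage is counted in a :class:`FilterTrace` so the funnel is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

from .variants import (
    GenomicVariant,
    ObservedVariant,
    PairingError,
    SampleRole,
    SampleVariantSet,
)
from .wga_errors import Blacklist

__all__ = [
    "FilterTrace",
    "PrivateCall",
    "PatientFilterResult",
    "DetectionSummary",
    "remove_blacklisted",
    "apply_af_threshold",
    "tumor_matched_calls",
    "replicate_concordant_private",
    "filter_ctc_sample",
    "cohort_detection_summary",
    "detection_percent",
]


@dataclass
class FilterTrace:
    """Per-stage variant counts for one CTC sample."""

    input: int
    after_blacklist: int
    after_af_threshold: int
    tumor_matched: Optional[int] = None
    replicate_concordant_private: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.input >= self.after_blacklist >= self.after_af_threshold >= 0:
            raise ValueError(
                f"non-monotone filter funnel: {self.input} -> "
                f"{self.after_blacklist} -> {self.after_af_threshold}"
            )
        if self.tumor_matched is not None and not (
            0 <= self.tumor_matched <= self.after_af_threshold
        ):
            raise ValueError(
                f"tumor_matched {self.tumor_matched} exceeds "
                f"after_af_threshold {self.after_af_threshold}"
            )


def remove_blacklisted(s: SampleVariantSet, b: Blacklist) -> SampleVariantSet:
    """Drop every variant whose normalized key is blacklisted."""
    return s.subset(lambda ov: ov.variant.key not in b)


def apply_af_threshold(s: SampleVariantSet, min_vaf: float = 0.01) -> SampleVariantSet:
    """Keep variants with VAF strictly greater than ``min_vaf``."""
    if not 0 <= min_vaf < 1:
        raise ValueError(f"min_vaf must be in [0, 1), got {min_vaf}")
    return s.subset(lambda ov: ov.vaf > min_vaf)


def tumor_matched_calls(
    ctc: SampleVariantSet, tumor: SampleVariantSet
) -> SampleVariantSet:
    """Intersection by normalized key; VAFs are reported from the CTC sample."""
    if ctc.patient_id != tumor.patient_id:
        raise PairingError(
            f"CTC sample {ctc.sample_id} (patient {ctc.patient_id}) does not "
            f"match tumor sample {tumor.sample_id} (patient {tumor.patient_id})"
        )
    tumor_keys = tumor.keys()
    return ctc.subset(lambda ov: ov.variant.key in tumor_keys)


@dataclass(frozen=True)
class PrivateCall:
    """A replicate-concordant CTC variant absent from tumor and blacklist.

    ``vaf`` is the mean of the two replicate VAFs (a summary, not a count
    ratio, which is why this is not an :class:`ObservedVariant`).
    """

    variant: GenomicVariant
    vaf: float
    rep1: ObservedVariant
    rep2: ObservedVariant


def replicate_concordant_private(
    rep1: SampleVariantSet,
    rep2: SampleVariantSet,
    tumor: SampleVariantSet,
    b: Blacklist,
) -> List[PrivateCall]:
    """Candidate disseminated-subclone mutations.

    Variants present in both independent WGA replicates of the same CTC
    capture, not blacklisted, and not matching any tumor variant. Both
    replicates are expected to be allele-frequency thresholded already.
    """
    if not (rep1.patient_id == rep2.patient_id == tumor.patient_id):
        raise PairingError(
            "replicates and tumor must come from one patient: "
            f"{rep1.patient_id}, {rep2.patient_id}, {tumor.patient_id}"
        )
    if rep1.sample_id == rep2.sample_id:
        raise PairingError(f"replicates must be distinct samples: {rep1.sample_id}")
    tumor_keys = tumor.keys()
    out: List[PrivateCall] = []
    for key in sorted(rep1.keys() & rep2.keys()):
        if key in b or key in tumor_keys:
            continue
        ov1, ov2 = rep1.get(key), rep2.get(key)
        out.append(
            PrivateCall(
                variant=ov1.variant,
                vaf=(ov1.vaf + ov2.vaf) / 2.0,
                rep1=ov1,
                rep2=ov2,
            )
        )
    return out


def filter_ctc_sample(
    ctc: SampleVariantSet,
    blacklist: Blacklist,
    tumor: Optional[SampleVariantSet] = None,
    min_vaf: float = 0.01,
) -> Tuple[SampleVariantSet, FilterTrace]:
    """Run blacklist -> AF threshold -> (optional) tumor matching on one sample."""
    after_bl = remove_blacklisted(ctc, blacklist)
    after_af = apply_af_threshold(after_bl, min_vaf)
    if tumor is None:
        trace = FilterTrace(len(ctc), len(after_bl), len(after_af))
        return after_af, trace
    matched = tumor_matched_calls(after_af, tumor)
    trace = FilterTrace(len(ctc), len(after_bl), len(after_af), len(matched))
    return matched, trace


@dataclass
class PatientFilterResult:
    """Filter traces for all CTC samples of one patient."""

    patient_id: str
    sample_traces: List[FilterTrace] = field(default_factory=list)

    @property
    def detected(self) -> bool:
        return any((t.tumor_matched or 0) > 0 for t in self.sample_traces)


@dataclass
class DetectionSummary:
    n_detected: int
    n_total: int
    percent: int  # rounded to the nearest integer
    mean_variants_per_ctc_sample: Optional[float]


def detection_percent(n_detected: int, n_total: int) -> int:
    """Cohort detection rate in percent, rounded to the nearest integer."""
    if n_total <= 0:
        raise ValueError("detection rate undefined for an empty cohort")
    return int(round(100.0 * n_detected / n_total))


def cohort_detection_summary(
    results: Iterable[PatientFilterResult],
) -> DetectionSummary:
    """Cohort-level detection rate and mean retained variants per CTC sample.

    A patient counts as detected iff any of its CTC samples has >= 1
    tumor-matched call. The per-sample mean uses the post-blacklist,
    post-threshold, pre-matching count.
    """
    results = list(results)
    if not results:
        raise ValueError("cohort_detection_summary needs at least one patient")
    n_detected = sum(1 for r in results if r.detected)
    retained = [t.after_af_threshold for r in results for t in r.sample_traces]
    return DetectionSummary(
        n_detected=n_detected,
        n_total=len(results),
        percent=detection_percent(n_detected, len(results)),
        mean_variants_per_ctc_sample=(
            sum(retained) / len(retained) if retained else None
        ),
    )
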
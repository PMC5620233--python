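"""End-to-end pipeline orchestration and cohort reporting.

``run_pipeline`` executes: cohort generation (synthetic mode) or loading
(file mode) -> WGA-error blacklist construction from amplified normals ->
per-sample filter cascade (blacklist removal, >1% AF threshold, tumor
matching, replicate-concordant private calls) -> mutation spectrum of the
pooled tumor-matched calls -> clinical associations -> per-gene alteration
table. Every reported number is recomputable from the serialized
intermediates, and all randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .clinical import AssociationError, AssociationResult, associate_af_with_clinical
from .filtering import (
    DetectionSummary,
    FilterTrace,
    PatientFilterResult,
    PrivateCall,
    cohort_detection_summary,
    filter_ctc_sample,
    replicate_concordant_private,
)
from .io import (
    read_clinical_csv,
    read_panel_bed,
    read_primers_tsv,
    read_variant_table,
    write_variant_table,
)
from .panel import ClinicalRecord, Panel
from .simulate import Cohort, CohortConfig, generate_cohort, write_cohort
from .spectrum import SpectrumProfile, ZeroSnvError, compute_spectrum
from .variants import SampleRole, SampleVariantSet
from .wga_errors import (
    Blacklist,
    ErrorCallSet,
    FpMatchRate,
    UndefinedRateError,
    build_blacklist,
    call_amplification_errors,
    estimate_fp_match_rate,
    summarize_error_vafs,
    write_blacklist,
)

__all__ = [
    "PipelineError",
    "PatientSamples",
    "PipelineReport",
    "run_pipeline",
    "run_pipeline_from_files",
    "gene_alteration_table",
]

OFF_TARGET_LABEL = "off-target"


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PatientSamples:
    patient_id: str
    tumor: Optional[SampleVariantSet] = None
    normal: Optional[SampleVariantSet] = None
    amplified_normal: Optional[SampleVariantSet] = None
    ctc_samples: List[SampleVariantSet] = field(default_factory=list)


@dataclass
class PipelineReport:
    version: str
    seed: Optional[int]
    config: Optional[dict]
    n_patients: int
    blacklist_size: int
    error_vaf_summary: Optional[dict]
    fp_match_rate: Optional[dict]
    detection: dict
    spectrum: Optional[dict]
    associations: Dict[str, dict]
    gene_table: List[dict]
    patient_traces: Dict[str, List[dict]]
    private_calls: Dict[str, List[dict]]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def gene_alteration_table(
    calls_by_sample: Mapping[str, SampleVariantSet], panel: Panel
) -> pd.DataFrame:
    """Percent of samples altered per gene (sample-level indicator).

    A sample is altered in a gene when >= 1 of its calls falls in the gene's
    panel regions; a call outside every region is counted under the
    ``off-target`` row (with a warning). Percentages carry one decimal.
    """
    n_samples = len(calls_by_sample)
    altered: Dict[str, set] = {g: set() for g in panel.genes}
    off_target: set = set()
    n_off_target_calls = 0
    for sample_id, calls in calls_by_sample.items():
        for ov in calls:
            gene = panel.gene_at(ov.variant.chrom, ov.variant.pos)
            if gene is None:
                off_target.add(sample_id)
                n_off_target_calls += 1
            else:
                altered[gene].add(sample_id)
    if n_off_target_calls:
        warnings.warn(
            f"{n_off_target_calls} call(s) outside all panel regions",
            stacklevel=2,
        )
    rows = [
        {
            "gene": g,
            "n_samples_altered": len(samples),
            "percent": round(100.0 * len(samples) / n_samples, 1) if n_samples else 0.0,
        }
        for g, samples in altered.items()
    ]
    if off_target:
        rows.append(
            {
                "gene": OFF_TARGET_LABEL,
                "n_samples_altered": len(off_target),
                "percent": round(100.0 * len(off_target) / n_samples, 1),
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "n_samples_altered", "percent"])
    return df.sort_values(
        ["n_samples_altered", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Core analysis over in-memory samples
# ---------------------------------------------------------------------------

def _analyze(
    patients: Sequence[PatientSamples],
    clinical: Sequence[ClinicalRecord],
    panel: Panel,
    *,
    min_recurrence: int = 2,
    min_vaf: float = 0.01,
    config_echo: Optional[dict] = None,
    seed: Optional[int] = None,
    out_dir: Optional[str] = None,
) -> PipelineReport:
    # -- stage: blacklist ----------------------------------------------------
    try:
        error_sets: List[ErrorCallSet] = []
        for p in patients:
            if p.amplified_normal is not None:
                if p.normal is None:
                    raise PipelineError(
                        "blacklist",
                        f"patient {p.patient_id} has an amplified normal but "
                        "no unamplified normal",
                    )
                error_sets.append(
                    call_amplification_errors(p.amplified_normal, p.normal)
                )
        blacklist = build_blacklist(error_sets, min_recurrence=min_recurrence)
        vaf_summary = summarize_error_vafs(error_sets, blacklist)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("blacklist", str(exc)) from exc

    # -- stage: false-positive match rate -------------------------------------
    tumors = {p.patient_id: p.tumor for p in patients if p.tumor is not None}
    fp: Optional[FpMatchRate]
    try:
        fp = estimate_fp_match_rate(error_sets, blacklist, tumors, min_vaf=min_vaf)
    except UndefinedRateError:
        fp = None
    except Exception as exc:
        raise PipelineError("fp_match_rate", str(exc)) from exc

    # -- stage: filter cascade -------------------------------------------------
    try:
        patient_results: List[PatientFilterResult] = []
        matched_by_sample: Dict[str, SampleVariantSet] = {}
        retained_by_sample: Dict[str, SampleVariantSet] = {}
        private_by_patient: Dict[str, List[PrivateCall]] = {}
        afs_by_patient: Dict[str, List[float]] = {}
        for p in patients:
            result = PatientFilterResult(patient_id=p.patient_id)
            retained_samples: List[SampleVariantSet] = []
            for ctc in p.ctc_samples:
                if p.tumor is None:
                    raise PipelineError(
                        "filter", f"patient {p.patient_id} has CTC samples but no tumor"
                    )
                matched, trace = filter_ctc_sample(
                    ctc, blacklist, p.tumor, min_vaf=min_vaf
                )
                retained = filter_ctc_sample(ctc, blacklist, None, min_vaf=min_vaf)[0]
                retained_samples.append(retained)
                matched_by_sample[ctc.sample_id] = matched
                retained_by_sample[ctc.sample_id] = retained
                afs_by_patient.setdefault(p.patient_id, []).extend(
                    ov.vaf for ov in matched
                )
                result.sample_traces.append(trace)
            if len(retained_samples) >= 2:
                private = replicate_concordant_private(
                    retained_samples[0], retained_samples[1], p.tumor, blacklist
                )
                private_by_patient[p.patient_id] = private
                for trace in result.sample_traces:
                    trace.replicate_concordant_private = len(private)
            if result.sample_traces:
                patient_results.append(result)
        detection = cohort_detection_summary(patient_results)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    # -- stage: spectrum --------------------------------------------------------
    spectrum: Optional[SpectrumProfile]
    pooled = [ov for s in matched_by_sample.values() for ov in s]
    try:
        spectrum = compute_spectrum(pooled)
    except ZeroSnvError:
        spectrum = None

    # -- stage: associations -----------------------------------------------------
    associations: Dict[str, dict] = {}
    clin_map = {r.patient_id: r for r in clinical}
    for variable in ("CEA", "AGE", "DUKES", "MSI"):
        try:
            res = associate_af_with_clinical(afs_by_patient, clin_map, variable)
            associations[variable] = dataclasses.asdict(res)
        except AssociationError as exc:
            associations[variable] = {"error": str(exc)}

    # -- stage: gene table ---------------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gene_df = gene_alteration_table(matched_by_sample, panel)

    report = PipelineReport(
        version=__version__,
        seed=seed,
        config=config_echo,
        n_patients=len(patients),
        blacklist_size=len(blacklist),
        error_vaf_summary=dataclasses.asdict(vaf_summary),
        fp_match_rate=dataclasses.asdict(fp) if fp is not None else None,
        detection=dataclasses.asdict(detection),
        spectrum=dataclasses.asdict(spectrum) if spectrum is not None else None,
        associations=associations,
        gene_table=gene_df.to_dict(orient="records"),
        patient_traces={
            r.patient_id: [dataclasses.asdict(t) for t in r.sample_traces]
            for r in patient_results
        },
        private_calls={
            pid: [
                {
                    "chrom": c.variant.chrom,
                    "pos": c.variant.pos,
                    "ref": c.variant.ref,
                    "alt": c.variant.alt,
                    "vaf": c.vaf,
                }
                for c in calls
            ]
            for pid, calls in private_by_patient.items()
            if calls
        },
    )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_blacklist(blacklist, os.path.join(out_dir, "blacklist.tsv"))
        calls_dir = os.path.join(out_dir, "calls")
        os.makedirs(calls_dir, exist_ok=True)
        for sample_id, calls in sorted(matched_by_sample.items()):
            write_variant_table(
                calls, os.path.join(calls_dir, f"{sample_id}_matched.tsv")
            )
        report.to_json(os.path.join(out_dir, "report.json"))
    return report


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

def _patients_from_cohort(cohort: Cohort) -> List[PatientSamples]:
    return [
        PatientSamples(
            patient_id=p.patient_id,
            tumor=p.tumor,
            normal=p.normal,
            amplified_normal=p.amplified_normal,
            ctc_samples=list(p.ctc_samples),
        )
        for p in cohort.patients
    ]


def run_pipeline(
    config: CohortConfig | str | os.PathLike,
    out_dir: Optional[str] = None,
    *,
    min_recurrence: int = 2,
    min_vaf: float = 0.01,
    write_cohort_files: bool = False,
) -> PipelineReport:
    """Synthetic mode: generate a cohort from the config and analyze it."""
    if not isinstance(config, CohortConfig):
        config = CohortConfig.from_yaml(config)
    try:
        cohort = generate_cohort(config)
    except Exception as exc:
        raise PipelineError("generate", str(exc)) from exc
    if out_dir is not None and write_cohort_files:
        write_cohort(cohort, os.path.join(out_dir, "cohort"))
    return _analyze(
        _patients_from_cohort(cohort),
        [p.clinical for p in cohort.patients],
        cohort.panel,
        min_recurrence=min_recurrence,
        min_vaf=min_vaf,
        config_echo=config.to_dict(),
        seed=config.seed,
        out_dir=out_dir,
    )


def run_pipeline_from_files(
    manifest_path: str | os.PathLike,
    clinical_csv: str | os.PathLike,
    panel_bed: str | os.PathLike,
    primers_tsv: Optional[str | os.PathLike] = None,
    out_dir: Optional[str] = None,
    *,
    min_recurrence: int = 2,
    min_vaf: float = 0.01,
) -> PipelineReport:
    """File mode: analyze variant tables listed in a sample manifest.

    The manifest is a TSV with columns patient_id, sample_id, role,
    replicate_index ('.' when not applicable) and path (relative to the
    manifest's directory).
    """
    base = os.path.dirname(os.path.abspath(manifest_path))
    try:
        mdf = pd.read_csv(manifest_path, sep="\t", dtype=str)
        required = {"patient_id", "sample_id", "role", "replicate_index", "path"}
        if not required <= set(mdf.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        by_patient: Dict[str, PatientSamples] = {}
        for row in mdf.itertuples(index=False):
            rep = None if row.replicate_index in (".", "", None) else int(row.replicate_index)
            role = SampleRole(row.role)
            s = read_variant_table(
                os.path.join(base, row.path),
                sample_id=row.sample_id,
                patient_id=row.patient_id,
                role=role,
                replicate_index=rep if role is SampleRole.CTC_WGA else None,
            )
            p = by_patient.setdefault(row.patient_id, PatientSamples(row.patient_id))
            if role is SampleRole.TUMOR:
                p.tumor = s
            elif role is SampleRole.NORMAL:
                p.normal = s
            elif role is SampleRole.AMPLIFIED_NORMAL:
                p.amplified_normal = s
            else:
                p.ctc_samples.append(s)
        for p in by_patient.values():
            p.ctc_samples.sort(key=lambda s: (s.replicate_index or 0, s.sample_id))
        clinical = read_clinical_csv(clinical_csv)
        primers = read_primers_tsv(primers_tsv) if primers_tsv else None
        panel = read_panel_bed(panel_bed, primers=primers)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    return _analyze(
        list(by_patient.values()),
        clinical,
        panel,
        min_recurrence=min_recurrence,
        min_vaf=min_vaf,
        out_dir=out_dir,
    )
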
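"""Synthetic cohort generator.

Emulates the study design this pipeline targets: a colorectal-cancer cohort
of 48 patients with a 39-gene, ~110 kb amplicon panel; matched tumor and
normal tissue per patient; whole-genome-amplified (WGA) normal DNA for a
14-patient control subset; and WGA CTC samples (two independent replicates
for CTC-positive patients, one otherwise). WGA introduces two artifact
classes: *recurrent* errors drawn from a cohort-wide hotspot locus set
(median VAF 0.5%) and *random* non-recurrent errors at uniform panel loci
(median VAF 1%). VAFs are lognormal around the configured median, converted
to integer read counts under a negative-binomial coverage model, and the
reported VAF is re-derived from those counts — so the generated tables look
like what a low-frequency caller would emit.

Everything is driven by one :class:`CohortConfig` and a single seed;
generation is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel import ClinicalRecord, Panel, Region, reference_base
from .preprocess import AmpliconReadPair, MateRead, reverse_complement
from .variants import (
    GenomicVariant,
    ObservedVariant,
    SampleRole,
    SampleVariantSet,
)

__all__ = [
    "ConfigError",
    "NoOverlapError",
    "CohortConfig",
    "PanelSpec",
    "WgaErrorModel",
    "TumorModel",
    "CtcModel",
    "CoverageModel",
    "ClinicalModel",
    "SpectrumModel",
    "SimulatedPatient",
    "Cohort",
    "generate_panel",
    "generate_cohort",
    "simulate_wga_sample",
    "simulate_tumor_sample",
    "simulate_amplicon_read_pairs",
    "write_fastq_pairs",
    "write_cohort",
]


class ConfigError(ValueError):
    """An invalid configuration value; the message names the field."""


class NoOverlapError(ValueError):
    """Amplicon longer than twice the read length: mates would not overlap."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

# 39 genes frequently mutated or druggable in colorectal cancer, with the
# chromosome each sits on; coordinates in the synthetic panel are arbitrary.
GENE_CATALOG: Tuple[Tuple[str, str], ...] = (
    ("APC", "chr5"), ("TP53", "chr17"), ("KRAS", "chr12"), ("PIK3CA", "chr3"),
    ("FBXW7", "chr4"), ("SMAD4", "chr18"), ("TCF7L2", "chr10"), ("NRAS", "chr1"),
    ("BRAF", "chr7"), ("ERBB2", "chr17"), ("ERBB3", "chr12"), ("ATM", "chr11"),
    ("ARID1A", "chr1"), ("SOX9", "chr17"), ("AMER1", "chrX"), ("CTNNB1", "chr3"),
    ("PTEN", "chr10"), ("EGFR", "chr7"), ("MSH2", "chr2"), ("MSH6", "chr2"),
    ("MLH1", "chr3"), ("POLE", "chr12"), ("BRCA2", "chr13"), ("SMAD2", "chr18"),
    ("ACVR2A", "chr2"), ("TGFBR2", "chr3"), ("GNAS", "chr20"), ("MAP2K1", "chr15"),
    ("AKT1", "chr14"), ("PTPN11", "chr12"), ("RET", "chr10"), ("MET", "chr7"),
    ("NOTCH1", "chr9"), ("CDKN2A", "chr9"), ("DNMT3A", "chr2"), ("IDH1", "chr2"),
    ("KIT", "chr4"), ("ALK", "chr2"), ("CDC27", "chr17"),
)


@dataclass
class PanelSpec:
    n_genes: int = 39
    total_length: int = 110_000
    primer_length: int = 21


@dataclass
class WgaErrorModel:
    n_recurrent_hotspots: int = 400
    hotspot_occurrence_prob: float = 0.5
    recurrent_vaf_median: float = 0.005
    random_errors_per_amplified_normal: float = 275.0
    random_errors_per_ctc: float = 150.0
    random_vaf_median: float = 0.010
    vaf_dispersion: float = 0.8  # lognormal sigma


@dataclass
class TumorModel:
    mutations_per_tumor: float = 12.0  # Poisson mean, uniform over the panel
    clonal_fraction: float = 1.0  # heterozygous clonal -> true VAF 0.5


@dataclass
class CtcModel:
    ctc_positive_fraction: float = 0.60
    tumor_fraction_min: float = 0.05
    tumor_fraction_max: float = 0.40
    n_wga_replicates: int = 2
    # Optional CTC-private subclone shared across a patient's WGA replicates
    # but absent from the tumor; off by default.
    subclone_mutations: float = 0.0
    subclone_fraction: float = 0.5  # subclone cell fraction within the tumor DNA


@dataclass
class CoverageModel:
    mean_depth: float = 400.0
    dispersion: float = 0.2  # negative-binomial: var = m + dispersion * m^2


@dataclass
class ClinicalModel:
    cea_logit_intercept: float = -2.0
    cea_logit_slope: float = 12.0  # on the latent tumor fraction
    cea_missing_prob: float = 0.5
    msi_prob: float = 0.15
    age_mean: float = 60.0
    age_sd: float = 12.0
    age_min: int = 26
    age_max: int = 84
    dukes_probs: Tuple[float, float, float, float] = (
        7 / 48, 16 / 48, 21 / 48, 4 / 48,
    )


@dataclass
class SpectrumModel:
    c_to_t_fraction: float = 0.45  # remaining five classes share the rest equally


@dataclass
class CohortConfig:
    n_patients: int = 48
    n_amplified_normals: int = 14
    panel: PanelSpec = field(default_factory=PanelSpec)
    wga_error_model: WgaErrorModel = field(default_factory=WgaErrorModel)
    tumor_model: TumorModel = field(default_factory=TumorModel)
    ctc_model: CtcModel = field(default_factory=CtcModel)
    coverage_model: CoverageModel = field(default_factory=CoverageModel)
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    spectrum_model: SpectrumModel = field(default_factory=SpectrumModel)
    seed: int = 0

    def validate(self) -> None:
        def _require(cond: bool, fieldname: str, msg: str) -> None:
            if not cond:
                raise ConfigError(f"{fieldname}: {msg}")

        _require(self.n_patients >= 1, "n_patients", "must be >= 1")
        _require(
            0 <= self.n_amplified_normals <= self.n_patients,
            "n_amplified_normals",
            "must be between 0 and n_patients",
        )
        _require(self.panel.n_genes >= 1, "panel.n_genes", "must be >= 1")
        _require(
            self.panel.total_length >= self.panel.n_genes,
            "panel.total_length",
            "must cover at least one base per gene",
        )
        w = self.wga_error_model
        _require(w.n_recurrent_hotspots >= 0, "wga_error_model.n_recurrent_hotspots", "must be >= 0")
        _require(
            0 <= w.hotspot_occurrence_prob <= 1,
            "wga_error_model.hotspot_occurrence_prob",
            "must be a probability",
        )
        for name in ("recurrent_vaf_median", "random_vaf_median"):
            v = getattr(w, name)
            _require(0 < v < 1, f"wga_error_model.{name}", "must be in (0, 1)")
        _require(w.vaf_dispersion > 0, "wga_error_model.vaf_dispersion", "must be > 0")
        _require(
            w.random_errors_per_amplified_normal >= 0,
            "wga_error_model.random_errors_per_amplified_normal",
            "must be >= 0",
        )
        _require(w.random_errors_per_ctc >= 0, "wga_error_model.random_errors_per_ctc", "must be >= 0")
        _require(self.tumor_model.mutations_per_tumor >= 0, "tumor_model.mutations_per_tumor", "must be >= 0")
        _require(
            0 < self.tumor_model.clonal_fraction <= 1,
            "tumor_model.clonal_fraction",
            "must be in (0, 1]",
        )
        c = self.ctc_model
        _require(0 <= c.ctc_positive_fraction <= 1, "ctc_model.ctc_positive_fraction", "must be a probability")
        _require(
            0 <= c.tumor_fraction_min <= c.tumor_fraction_max <= 1,
            "ctc_model.tumor_fraction_min",
            "need 0 <= min <= max <= 1",
        )
        _require(c.n_wga_replicates >= 1, "ctc_model.n_wga_replicates", "must be >= 1")
        _require(c.subclone_mutations >= 0, "ctc_model.subclone_mutations", "must be >= 0")
        _require(0 < c.subclone_fraction <= 1, "ctc_model.subclone_fraction", "must be in (0, 1]")
        _require(self.coverage_model.mean_depth > 0, "coverage_model.mean_depth", "must be > 0")
        _require(self.coverage_model.dispersion >= 0, "coverage_model.dispersion", "must be >= 0")
        cl = self.clinical_model
        _require(0 <= cl.cea_missing_prob <= 1, "clinical_model.cea_missing_prob", "must be a probability")
        _require(0 <= cl.msi_prob <= 1, "clinical_model.msi_prob", "must be a probability")
        _require(
            abs(sum(cl.dukes_probs) - 1) < 1e-9 and all(p >= 0 for p in cl.dukes_probs),
            "clinical_model.dukes_probs",
            "must be a probability vector over A-D",
        )
        s = self.spectrum_model
        _require(0 <= s.c_to_t_fraction <= 1, "spectrum_model.c_to_t_fraction", "must be a probability")

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clinical_model"]["dukes_probs"] = list(d["clinical_model"]["dukes_probs"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        nested = {
            "panel": PanelSpec,
            "wga_error_model": WgaErrorModel,
            "tumor_model": TumorModel,
            "ctc_model": CtcModel,
            "coverage_model": CoverageModel,
            "clinical_model": ClinicalModel,
            "spectrum_model": SpectrumModel,
        }
        kwargs: dict = {}
        for k, v in d.items():
            if k in nested:
                sub = dict(v)
                if k == "clinical_model" and "dukes_probs" in sub:
                    sub["dukes_probs"] = tuple(sub["dukes_probs"])
                kwargs[k] = nested[k](**sub)
            else:
                kwargs[k] = v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Panel and cohort-wide structures
# ---------------------------------------------------------------------------

def generate_panel(spec: PanelSpec, rng: np.random.Generator) -> Panel:
    """Synthesize a panel: one region per gene, primers per chromosome."""
    genes: List[Tuple[str, str]] = []
    for i in range(spec.n_genes):
        if i < len(GENE_CATALOG):
            genes.append(GENE_CATALOG[i])
        else:
            genes.append((f"GENE{i + 1:02d}", f"chr{i % 22 + 1}"))
    base_len = spec.total_length // spec.n_genes
    remainder = spec.total_length % spec.n_genes
    regions: List[Region] = []
    next_start: Dict[str, int] = {}
    primers: Dict[str, List[str]] = {}
    for i, (gene, chrom) in enumerate(genes):
        length = base_len + (1 if i < remainder else 0)
        start = next_start.get(chrom, 1_000_000)
        regions.append(Region(chrom, start, start + length, gene))
        next_start[chrom] = start + length + 50_000
        for _ in range(2):  # forward + reverse primer per gene
            seq = "".join(rng.choice(list("ACGT"), size=spec.primer_length))
            primers.setdefault(chrom, []).append(seq)
    return Panel(regions, primers=primers)


def _draw_hotspots(
    panel: Panel, n: int, rng: np.random.Generator
) -> List[GenomicVariant]:
    n = min(n, panel.total_length)
    offsets = rng.choice(panel.total_length, size=n, replace=False)
    hotspots = []
    for off in sorted(int(o) for o in offsets):
        chrom, pos = panel.locus_at(off)
        ref = reference_base(chrom, pos)
        alt = _random_alt(ref, rng)
        hotspots.append(GenomicVariant(chrom, pos, ref, alt))
    return hotspots


def _random_alt(ref: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, 3))]


_PYR_CLASSES: Tuple[Tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _draw_tumor_truth(
    panel: Panel,
    n_mutations: int,
    spectrum: SpectrumModel,
    true_vaf: float,
    rng: np.random.Generator,
) -> Dict[GenomicVariant, float]:
    """Somatic truth variants with the configured substitution-class mass.

    A substitution class is drawn first (C>T carries ``c_to_t_fraction``,
    the other five classes share the remainder equally), then a panel locus
    whose synthetic reference base matches the class on either strand is
    rejection-sampled, keeping the class distribution exact.
    """
    ct = spectrum.c_to_t_fraction
    other = (1 - ct) / 5
    probs = np.array([other, other, ct, other, other, other])
    truth: Dict[GenomicVariant, float] = {}
    while len(truth) < n_mutations:
        ref_pyr, alt_pyr = _PYR_CLASSES[int(rng.choice(6, p=probs))]
        for _ in range(1000):
            off = int(rng.integers(0, panel.total_length))
            chrom, pos = panel.locus_at(off)
            ref = reference_base(chrom, pos)
            if ref == ref_pyr:
                v = GenomicVariant(chrom, pos, ref, alt_pyr)
                break
            if ref == _COMP[ref_pyr]:
                v = GenomicVariant(chrom, pos, ref, _COMP[alt_pyr])
                break
        else:  # pragma: no cover - panel lacking a base entirely
            raise ConfigError("panel.total_length: too small to place mutations")
        if v not in truth:
            truth[v] = true_vaf
    return truth


# ---------------------------------------------------------------------------
# Per-sample simulation
# ---------------------------------------------------------------------------

def _draw_depths(n: int, cov: CoverageModel, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=int)
    if cov.dispersion <= 0:
        depths = rng.poisson(cov.mean_depth, size=n)
    else:
        shape = 1.0 / cov.dispersion
        p = shape / (shape + cov.mean_depth)
        depths = rng.negative_binomial(shape, p, size=n)
    return np.maximum(depths, 1)


def _lognormal_vafs(
    n: int, median: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    return np.exp(np.log(median) + sigma * rng.standard_normal(n))


def _quantized(vaf: float, depth: int) -> Optional[int]:
    """Integer alt count for a target VAF; None when no read would support it."""
    alt = int(round(vaf * depth))
    if alt < 1:
        return None
    return min(alt, depth)


def simulate_wga_sample(
    truth_variants: Mapping[GenomicVariant, float],
    role: SampleRole,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    panel: Panel,
    hotspots: Sequence[GenomicVariant],
    tumor_fraction: float = 0.0,
    sample_id: str = "sample",
    patient_id: str = "patient",
    replicate_index: Optional[int] = None,
) -> SampleVariantSet:
    """Simulate one whole-genome-amplified sample's variant table.

    Emits, in order: tumor-derived variants (CTC samples only; binomial read
    sampling at ``tumor_fraction * true VAF``), cohort hotspot errors (each
    present with ``hotspot_occurrence_prob``, lognormal VAF around the
    recurrent median), and Poisson-many random errors at uniform panel loci
    (lognormal VAF around the random median). Reported VAFs are re-derived
    from integer read counts; a variant supported by zero reads is not called.
    """
    role = SampleRole(role)
    if role not in (SampleRole.AMPLIFIED_NORMAL, SampleRole.CTC_WGA):
        raise ValueError(f"simulate_wga_sample: unsupported role {role.value}")
    w = config.wga_error_model
    cov = config.coverage_model
    out = SampleVariantSet(
        sample_id, patient_id, role, replicate_index=replicate_index
    )
    taken = set()

    # tumor-derived signal (CTC only)
    if role is SampleRole.CTC_WGA and tumor_fraction > 0:
        items = sorted(truth_variants.items(), key=lambda kv: kv[0])
        depths = _draw_depths(len(items), cov, rng)
        for (v, true_vaf), depth in zip(items, depths):
            p = min(tumor_fraction * true_vaf, 1.0)
            alt = int(rng.binomial(int(depth), p))
            if alt >= 1 and v.key not in taken:
                out.add(ObservedVariant(v, int(depth), alt))
                taken.add(v.key)

    # recurrent hotspot errors
    if hotspots and w.hotspot_occurrence_prob > 0:
        present = rng.random(len(hotspots)) < w.hotspot_occurrence_prob
        idx = np.flatnonzero(present)
        vafs = _lognormal_vafs(len(idx), w.recurrent_vaf_median, w.vaf_dispersion, rng)
        depths = _draw_depths(len(idx), cov, rng)
        for j, vaf, depth in zip(idx, vafs, depths):
            v = hotspots[int(j)]
            alt = _quantized(float(vaf), int(depth))
            if alt is not None and v.key not in taken:
                out.add(ObservedVariant(v, int(depth), alt))
                taken.add(v.key)

    # random non-recurrent errors
    mean_errors = (
        w.random_errors_per_amplified_normal
        if role is SampleRole.AMPLIFIED_NORMAL
        else w.random_errors_per_ctc
    )
    if mean_errors > 0:
        k = int(rng.poisson(mean_errors))
        offsets = rng.integers(0, panel.total_length, size=k)
        vafs = _lognormal_vafs(k, w.random_vaf_median, w.vaf_dispersion, rng)
        depths = _draw_depths(k, cov, rng)
        for off, vaf, depth in zip(offsets, vafs, depths):
            chrom, pos = panel.locus_at(int(off))
            ref = reference_base(chrom, pos)
            v = GenomicVariant(chrom, pos, ref, _random_alt(ref, rng))
            if v.key in taken:
                continue
            alt = _quantized(float(vaf), int(depth))
            if alt is not None:
                out.add(ObservedVariant(v, int(depth), alt))
                taken.add(v.key)
    return out


def simulate_tumor_sample(
    truth_variants: Mapping[GenomicVariant, float],
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    sample_id: str,
    patient_id: str,
) -> SampleVariantSet:
    """Observed tumor-tissue calls: truth variants under binomial read sampling."""
    out = SampleVariantSet(sample_id, patient_id, SampleRole.TUMOR)
    items = sorted(truth_variants.items(), key=lambda kv: kv[0])
    depths = _draw_depths(len(items), config.coverage_model, rng)
    for (v, true_vaf), depth in zip(items, depths):
        alt = int(rng.binomial(int(depth), min(true_vaf, 1.0)))
        if alt >= 1:
            out.add(ObservedVariant(v, int(depth), alt))
    return out


def _draw_clinical(
    patient_id: str,
    tumor_fraction: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> ClinicalRecord:
    cm = config.clinical_model
    age = int(np.clip(round(rng.normal(cm.age_mean, cm.age_sd)), cm.age_min, cm.age_max))
    dukes = "ABCD"[int(rng.choice(4, p=np.asarray(cm.dukes_probs)))]
    msi = "MSI" if rng.random() < cm.msi_prob else "MSS"
    logit = cm.cea_logit_intercept + cm.cea_logit_slope * tumor_fraction
    abnormal = rng.random() < 1.0 / (1.0 + math.exp(-logit))
    if abnormal:
        cea = 5.0 * math.exp(rng.exponential(0.9))
    else:
        cea = float(rng.uniform(0.5, 4.99))
    if rng.random() < cm.cea_missing_prob:
        cea = None
    return ClinicalRecord(
        patient_id=patient_id,
        age=age,
        dukes=dukes,
        cea=None if cea is None else round(cea, 1),
        msi=msi,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPatient:
    """Ground-truth carrier for one synthetic patient."""

    patient_id: str
    tumor_truth: Dict[GenomicVariant, float]
    subclone_truth: Dict[GenomicVariant, float]
    tumor: SampleVariantSet
    normal: SampleVariantSet
    amplified_normal: Optional[SampleVariantSet]
    ctc_samples: List[SampleVariantSet]
    clinical: ClinicalRecord
    tumor_fraction: float
    ctc_positive: bool


@dataclass
class Cohort:
    config: CohortConfig
    panel: Panel
    hotspots: List[GenomicVariant]
    patients: List[SimulatedPatient]

    @property
    def amplified_normal_patients(self) -> List[SimulatedPatient]:
        return [p for p in self.patients if p.amplified_normal is not None]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort deterministically from the seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + config.n_patients)
    root = np.random.default_rng(children[0])

    panel = generate_panel(config.panel, root)
    hotspots = _draw_hotspots(panel, config.wga_error_model.n_recurrent_hotspots, root)

    n_positive = int(round(config.ctc_model.ctc_positive_fraction * config.n_patients))
    order = root.permutation(config.n_patients)
    positive_ids = set(int(i) for i in order[:n_positive])
    amp_order = root.permutation(config.n_patients)
    amplified_ids = set(int(i) for i in amp_order[: config.n_amplified_normals])

    true_vaf = 0.5 * config.tumor_model.clonal_fraction
    patients: List[SimulatedPatient] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i + 1])
        pid = f"P{i + 1:02d}"
        n_mut = int(rng.poisson(config.tumor_model.mutations_per_tumor))
        truth = _draw_tumor_truth(panel, n_mut, config.spectrum_model, true_vaf, rng)

        tumor = simulate_tumor_sample(
            truth, config, rng, sample_id=f"{pid}_T", patient_id=pid
        )
        normal = SampleVariantSet(f"{pid}_N", pid, SampleRole.NORMAL)

        amplified = None
        if i in amplified_ids:
            amplified = simulate_wga_sample(
                {}, SampleRole.AMPLIFIED_NORMAL, config, rng,
                panel=panel, hotspots=hotspots,
                sample_id=f"{pid}_AN", patient_id=pid,
            )

        positive = i in positive_ids
        if positive:
            tumor_fraction = float(
                rng.uniform(
                    config.ctc_model.tumor_fraction_min,
                    config.ctc_model.tumor_fraction_max,
                )
            )
            n_reps = config.ctc_model.n_wga_replicates
        else:
            tumor_fraction = 0.0
            n_reps = 1

        subclone: Dict[GenomicVariant, float] = {}
        if positive and config.ctc_model.subclone_mutations > 0:
            n_sub = int(rng.poisson(config.ctc_model.subclone_mutations))
            sub_vaf = true_vaf * config.ctc_model.subclone_fraction
            for v, _ in _draw_tumor_truth(
                panel, n_sub, config.spectrum_model, sub_vaf, rng
            ).items():
                if v not in truth:
                    subclone[v] = sub_vaf

        ctc_truth = {**truth, **subclone}
        ctc_samples = [
            simulate_wga_sample(
                ctc_truth, SampleRole.CTC_WGA, config, rng,
                panel=panel, hotspots=hotspots, tumor_fraction=tumor_fraction,
                sample_id=f"{pid}_CTC{r}", patient_id=pid, replicate_index=r,
            )
            for r in range(1, n_reps + 1)
        ]
        clinical = _draw_clinical(pid, tumor_fraction, config, rng)
        patients.append(
            SimulatedPatient(
                patient_id=pid,
                tumor_truth=truth,
                subclone_truth=subclone,
                tumor=tumor,
                normal=normal,
                amplified_normal=amplified,
                ctc_samples=ctc_samples,
                clinical=clinical,
                tumor_fraction=tumor_fraction,
                ctc_positive=positive,
            )
        )
    return Cohort(config=config, panel=panel, hotspots=hotspots, patients=patients)


# ---------------------------------------------------------------------------
# Read-pair fixtures
# ---------------------------------------------------------------------------

def simulate_amplicon_read_pairs(
    n_pairs: int,
    amplicon_length: int,
    read_length: int,
    primer: str,
    error_rate: float,
    rng: np.random.Generator,
    *,
    chrom: str = "chr1",
    start: int = 1000,
) -> List[AmpliconReadPair]:
    """Overlapping paired-end reads from one synthetic amplicon.

    The amplicon carries ``primer`` at its 5' end and the reverse complement
    of ``primer`` at its 3' end, so both mates begin with the primer in
    sequencing orientation. Mates overlap by ``2*read_length -
    amplicon_length`` reference bases. Sequencing errors are independent
    uniform substitutions at ``error_rate`` with reduced base quality.
    """
    if read_length > amplicon_length:
        raise ValueError("read_length must not exceed amplicon_length")
    if amplicon_length > 2 * read_length:
        raise NoOverlapError(
            f"amplicon of {amplicon_length} bp with {read_length} bp reads "
            "leaves no mate overlap"
        )
    L = len(primer)
    template = list(rng.choice(list("ACGT"), size=amplicon_length))
    template[:L] = list(primer)
    template[amplicon_length - L:] = list(reverse_complement(primer))
    template_s = "".join(template)

    pairs: List[AmpliconReadPair] = []
    for i in range(n_pairs):
        def _sequenced(ref_seq: str) -> Tuple[str, Tuple[int, ...]]:
            bases = list(ref_seq)
            quals = [int(q) for q in rng.integers(30, 41, size=len(bases))]
            if error_rate > 0:
                errs = np.flatnonzero(rng.random(len(bases)) < error_rate)
                for j in errs:
                    bases[j] = _random_alt(bases[j], rng)
                    quals[j] = int(rng.integers(8, 21))
            return "".join(bases), tuple(quals)

        seq1, q1 = _sequenced(template_s[:read_length])
        seq2, q2 = _sequenced(template_s[amplicon_length - read_length:])
        mate1 = MateRead(chrom, seq1, q1, start, is_reverse=False)
        mate2 = MateRead(
            chrom, seq2, q2, start + amplicon_length - read_length, is_reverse=True
        )
        pairs.append(AmpliconReadPair(f"pair{i + 1}", mate1, mate2))
    return pairs


def write_fastq_pairs(
    pairs: Sequence[AmpliconReadPair], path_r1: str, path_r2: str
) -> None:
    """Write mates in sequencing orientation (mate 2 reverse-complemented)."""
    r1, r2 = [], []
    for p in pairs:
        rec1 = SeqRecord(Seq(p.mate1.sequence), id=p.name, description="")
        rec1.letter_annotations["phred_quality"] = list(p.mate1.qualities)
        r1.append(rec1)
        rec2 = SeqRecord(
            Seq(reverse_complement(p.mate2.sequence)), id=p.name, description=""
        )
        rec2.letter_annotations["phred_quality"] = list(p.mate2.qualities)[::-1]
        r2.append(rec2)
    SeqIO.write(r1, path_r1, "fastq")
    SeqIO.write(r2, path_r2, "fastq")


# ---------------------------------------------------------------------------
# Cohort serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | os.PathLike) -> str:
    """Serialize a cohort: per-sample TSVs, panel, clinical CSV, manifest.

    Returns the manifest path. The manifest (patient_id, sample_id, role,
    replicate_index, path) plus clinical.csv, panel.bed and primers.tsv are
    everything the file-mode pipeline needs.
    """
    from .io import (
        write_clinical_csv,
        write_panel_bed,
        write_primers_tsv,
        write_variant_table,
    )

    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    samples_dir = os.path.join(outdir, "samples")
    os.makedirs(samples_dir, exist_ok=True)

    rows = []
    for p in cohort.patients:
        sets = [p.tumor, p.normal] + ([p.amplified_normal] if p.amplified_normal else [])
        sets += p.ctc_samples
        for s in sets:
            rel = os.path.join("samples", f"{s.sample_id}.tsv")
            write_variant_table(s, os.path.join(outdir, rel))
            rows.append(
                (
                    s.patient_id,
                    s.sample_id,
                    s.role.value,
                    s.replicate_index if s.replicate_index is not None else ".",
                    rel,
                )
            )
    manifest = os.path.join(outdir, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("patient_id\tsample_id\trole\treplicate_index\tpath\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    write_panel_bed(cohort.panel, os.path.join(outdir, "panel.bed"))
    write_primers_tsv(cohort.panel, os.path.join(outdir, "primers.tsv"))
    write_clinical_csv(
        [p.clinical for p in cohort.patients], os.path.join(outdir, "clinical.csv")
    )
    cohort.config.to_yaml(os.path.join(outdir, "config.yaml"))
    return manifest
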
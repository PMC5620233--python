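"""Synthetic cohort generator: determinism, calibration, truth conservation."""

import numpy as np
import pytest
from scipy import stats as sps

from ctcseq.panel import reference_base
from ctcseq.simulate import (
    Cohort,
    CohortConfig,
    ConfigError,
    CoverageModel,
    CtcModel,
    NoOverlapError,
    PanelSpec,
    TumorModel,
    WgaErrorModel,
    generate_cohort,
    generate_panel,
    simulate_amplicon_read_pairs,
    simulate_wga_sample,
    write_cohort,
)
from ctcseq.variants import SampleRole, SampleVariantSet


def _small_config(seed=0, **kw):
    base = dict(
        n_patients=6,
        n_amplified_normals=3,
        panel=PanelSpec(n_genes=5, total_length=8000),
        wga_error_model=WgaErrorModel(
            n_recurrent_hotspots=40,
            random_errors_per_amplified_normal=25,
            random_errors_per_ctc=15,
        ),
        tumor_model=TumorModel(mutations_per_tumor=6),
        coverage_model=CoverageModel(mean_depth=200),
        seed=seed,
    )
    base.update(kw)
    return CohortConfig(**base)


def _dir_bytes(d):
    import os

    out = {}
    for root, _, files in os.walk(d):
        for f in sorted(files):
            p = os.path.join(root, f)
            out[os.path.relpath(p, d)] = open(p, "rb").read()
    return out


def test_same_seed_gives_byte_identical_cohorts(tmp_path):
    cfg = _small_config(seed=11)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_cohort(generate_cohort(cfg), d1)
    write_cohort(generate_cohort(_small_config(seed=11)), d2)
    assert _dir_bytes(d1) == _dir_bytes(d2)


def test_different_seeds_differ(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_cohort(generate_cohort(_small_config(seed=1)), d1)
    write_cohort(generate_cohort(_small_config(seed=2)), d2)
    assert _dir_bytes(d1) != _dir_bytes(d2)


def test_default_config_echoes_study_design(default_cohort):
    assert len(default_cohort.patients) == 48
    assert len(default_cohort.amplified_normal_patients) == 14
    positives = [p for p in default_cohort.patients if p.ctc_positive]
    assert len(positives) == round(0.60 * 48)
    assert all(len(p.ctc_samples) == 2 for p in positives)
    assert all(
        len(p.ctc_samples) == 1 for p in default_cohort.patients if not p.ctc_positive
    )
    assert default_cohort.panel.total_length == 110_000
    assert len(default_cohort.panel.genes) == 39


def test_ctc_positive_fraction_zero_gives_no_tumor_signal():
    cfg = _small_config(ctc_model=CtcModel(ctc_positive_fraction=0.0))
    cohort = generate_cohort(cfg)
    for p in cohort.patients:
        assert not p.ctc_positive and p.tumor_fraction == 0.0
        truth_keys = {v.key for v in p.tumor_truth}
        for s in p.ctc_samples:
            assert not (s.keys() & truth_keys)


def test_all_error_sources_off_gives_empty_wga_sample(rng):
    cfg = _small_config(
        wga_error_model=WgaErrorModel(
            n_recurrent_hotspots=0,
            hotspot_occurrence_prob=0.0,
            random_errors_per_amplified_normal=0,
            random_errors_per_ctc=0,
        )
    )
    panel = generate_panel(cfg.panel, rng)
    s = simulate_wga_sample(
        {}, SampleRole.CTC_WGA, cfg, rng, panel=panel, hotspots=[], tumor_fraction=0.0
    )
    assert len(s) == 0


def test_invalid_config_names_field():
    with pytest.raises(ConfigError, match="hotspot_occurrence_prob"):
        _small_config(
            wga_error_model=WgaErrorModel(hotspot_occurrence_prob=1.5)
        ).validate()
    with pytest.raises(ConfigError, match="n_amplified_normals"):
        _small_config(n_amplified_normals=99).validate()


def test_config_yaml_round_trip(tmp_path):
    cfg = _small_config(seed=5)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    assert CohortConfig.from_yaml(path) == cfg


def test_normal_samples_never_contain_tumor_truth(default_cohort):
    for p in default_cohort.patients:
        assert len(p.normal) == 0
        truth_keys = {v.key for v in p.tumor_truth}
        assert not (p.normal.keys() & truth_keys)


def test_random_error_vaf_tail_matches_lognormal_closed_form(rng):
    """Fraction of random WGA errors retained at the >1% threshold.

    The generator draws error VAFs lognormal with median equal to the 1%
    threshold, so the continuous law puts exactly half its mass above the
    cutoff; count quantization at finite depth perturbs individual samples
    but averages out over the dispersed depth distribution.
    """
    cfg = CohortConfig()
    cfg.wga_error_model.n_recurrent_hotspots = 0
    panel = generate_panel(PanelSpec(), rng)
    n_above = 0
    n_total = 0
    for _ in range(200):
        s = simulate_wga_sample(
            {}, SampleRole.AMPLIFIED_NORMAL, cfg, rng, panel=panel, hotspots=[]
        )
        n_total += len(s)
        n_above += sum(1 for ov in s if ov.vaf > 0.01)
    expected = 0.5 * n_total
    assert n_above == pytest.approx(expected, rel=0.05)


def test_tumor_variant_observed_vaf_matches_binomial_mean(rng):
    """Heterozygous truth variant (true VAF 0.5) at tumor fraction 0.5 is
    observed at mean VAF 0.25 within 3 standard errors over 1000 draws."""
    cfg = CohortConfig()
    cfg.wga_error_model.n_recurrent_hotspots = 0
    cfg.wga_error_model.random_errors_per_ctc = 0
    panel = generate_panel(PanelSpec(), rng)
    chrom, pos = panel.locus_at(1234)
    ref = reference_base(chrom, pos)
    from ctcseq.variants import GenomicVariant

    truth = {GenomicVariant(chrom, pos, ref, "A" if ref != "A" else "C"): 0.5}
    vafs = []
    for _ in range(1000):
        s = simulate_wga_sample(
            truth, SampleRole.CTC_WGA, cfg, rng,
            panel=panel, hotspots=[], tumor_fraction=0.5,
        )
        vafs.extend(ov.vaf for ov in s)
    mean = np.mean(vafs)
    # per-draw variance: binomial at p=0.25 over ~NegBinom(400) depth
    se = np.std(vafs, ddof=1) / np.sqrt(len(vafs))
    assert abs(mean - 0.25) < 3 * se + 1e-4


class TestAmpliconReadPairs:
    PRIMER = "ACGTACGTACGTACGTACGTA"

    def test_overlap_length_158bp_amplicon(self, rng):
        pairs = simulate_amplicon_read_pairs(
            2, amplicon_length=158, read_length=150, primer=self.PRIMER,
            error_rate=0.0, rng=rng,
        )
        for p in pairs:
            lo, hi = p.overlap
            assert hi - lo == 2 * 150 - 158 == 142

    def test_equal_lengths_give_full_overlap(self, rng):
        (p,) = simulate_amplicon_read_pairs(
            1, amplicon_length=150, read_length=150, primer=self.PRIMER,
            error_rate=0.0, rng=rng,
        )
        lo, hi = p.overlap
        assert hi - lo == 150
        assert p.mate1.start == p.mate2.start

    def test_amplicon_longer_than_two_reads_is_error(self, rng):
        with pytest.raises(NoOverlapError):
            simulate_amplicon_read_pairs(
                1, amplicon_length=301, read_length=150, primer=self.PRIMER,
                error_rate=0.0, rng=rng,
            )

    def test_zero_error_rate_mates_agree_everywhere(self, rng):
        pairs = simulate_amplicon_read_pairs(
            5, amplicon_length=158, read_length=150, primer=self.PRIMER,
            error_rate=0.0, rng=rng,
        )
        for p in pairs:
            lo, hi = p.overlap
            for refpos in range(lo, hi):
                assert (
                    p.mate1.sequence[refpos - p.mate1.start]
                    == p.mate2.sequence[refpos - p.mate2.start]
                )

    def test_primer_prefixes_each_mate(self, rng):
        from ctcseq.preprocess import reverse_complement

        (p,) = simulate_amplicon_read_pairs(
            1, amplicon_length=158, read_length=150, primer=self.PRIMER,
            error_rate=0.0, rng=rng,
        )
        assert p.mate1.sequence.startswith(self.PRIMER)
        # mate2 is stored reference-forward; its sequencing 5' prefix is the
        # reverse complement of the stored 3' suffix
        assert reverse_complement(p.mate2.sequence)[:21] == self.PRIMER

    def test_fastq_round_trip(self, tmp_path, rng):
        from ctcseq.simulate import write_fastq_pairs

        pairs = simulate_amplicon_read_pairs(
            3, amplicon_length=158, read_length=150, primer=self.PRIMER,
            error_rate=0.01, rng=rng,
        )
        r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        write_fastq_pairs(pairs, str(r1), str(r2))
        from Bio import SeqIO

        recs1 = list(SeqIO.parse(str(r1), "fastq"))
        recs2 = list(SeqIO.parse(str(r2), "fastq"))
        assert len(recs1) == len(recs2) == 3
        assert str(recs1[0].seq) == pairs[0].mate1.sequence
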
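# Methods

## Variant model and matching semantics

Variants are stored in VCF-style 1-based coordinates; panel regions are
BED-style 0-based half-open intervals. Cross-sample operations (blacklist
membership, tumor–CTC intersection, replicate concordance) compare variants
by their *normalized* key: shared suffix bases are trimmed, then shared
prefix bases (advancing the position), always retaining one anchor base for
indels, and the result is idempotent. Matching is exact on the normalized
(chrom, pos, ref, alt) — no positional window — because an exact rule is the
only fully reproducible one. A caveat documented here deliberately: without
genome sequence context, pure allele-string trimming cannot left-align an
indel across a repeat run, so two spellings of a homopolymer deletion that
differ in flanking context can normalize to different keys. The synthetic
generator emits indel-free error calls and anchored truth variants, so this
does not affect the shipped analyses. Multi-allelic VCF records are split by
the reader; equal-length multi-base substitutions are carried as MNV (the
class enum extends SNV/INS/DEL) and are ignored by the spectrum.

## WGA error model and blacklist

"Recurrent" is defined as: the identical normalized key called in at least
`min_recurrence = 2` distinct amplified-normal error sets (one incidence per
sample, regardless of VAF). This is the weakest defensible definition and is
configurable. `summarize_error_vafs` partitions *every* error observation
into recurrent (key blacklisted) vs non-recurrent and reports each
partition's median VAF; an empty partition yields an undefined (None)
median, never zero.

The false-positive tumor-match rate counts, in its denominator, only errors
that survive the same filters applied to real samples — VAF strictly > 1%
(read literally from the ">1%" rule, so a variant at exactly 0.01 is
dropped) and not blacklisted. The denominator therefore excludes
blacklisted keys; the pre-exclusion observation counts are reported
alongside in the error summary. The rate is rounded to one decimal in
percent.

## Filter cascade

Stage order is blacklist removal → AF threshold → tumor matching. The first
two are pure per-variant predicates and commute (property-tested); matching
is placed last so the funnel counts are maximally interpretable. A patient
is "detected" when any of its CTC samples has ≥ 1 tumor-matched call. The
"mean variants per CTC sample" statistic is defined post-blacklist,
post-threshold, pre-matching. Replicate-concordant private calls report the
mean of the two replicate VAFs; since a mean of two ratios is not itself an
integer count ratio these are returned as dedicated `PrivateCall` records
rather than `ObservedVariant`s.

## Read preprocessing

Amplicon products (median ≈ 158 bp) sequenced 2 × 150 bp leave mates
overlapping by 2·150 − 158 = 142 reference bases. Where mates agree, the
bases corroborate each other and both qualities become min(q1 + q2, 60);
where they disagree, the higher-quality mate keeps max(q_high − q_low, 2)
and the other is floored at Q2, with quality ties resolved in favour of
mate 1 (deterministic and maximally conservative). These are the additive
conventions of overlap-consensus tools: monotone (agreement never lowers a
quality, disagreement never raises one) and auditable; the operation is not
idempotent — it saturates at the Q60 cap and Q2 floor. Primer trimming
hard-removes (rather than soft-masks) the longest primer from the same
chromosome whose Hamming distance to the read's 5′ prefix is ≤ 20% of the
primer length, at most once per read; hard removal guarantees primer bases
never enter pileups, and the alignment start advances for forward-strand
reads. Reads are modelled as ungapped alignments, which is adequate for
short amplicons; CIGAR-aware soft-clip handling is out of scope.

## Synthetic cohort generator

The generator emulates the targeted study design, not sequencing physics.
Defaults (all in `CohortConfig`):

| parameter | default | rationale |
|---|---|---|
| patients / amplified normals | 48 / 14 | study scale |
| panel | 39 genes, 110 kb, one region per gene | study panel scale |
| recurrent hotspots | 400 loci, present per sample w.p. 0.5 | yields ~200 recurrent errors/sample |
| recurrent / random VAF median | 0.5% / 1% | the two reported error medians |
| VAF dispersion | lognormal σ = 0.8 | keeps VAFs positive, right-skewed; ~half of random errors clear the 1% cut |
| random errors per amplified normal / CTC | 275 / 150 | post-threshold ≈ 137 retained per control (≈ 1,915/14) and ≈ 84 per CTC sample |
| coverage | NegBinom(mean 400, dispersion 0.2), var = m + 0.2 m² | ~400× median panel coverage with realistic spread |
| tumor | Poisson(12) clonal heterozygous mutations (true VAF 0.5), uniform over panel | typical panel-restricted CRC burden |
| CTC | 60% of patients positive (exactly round(0.6·n), mirroring 29/48), tumor fraction U(0.05, 0.40), 2 WGA replicates; negatives: 1 replicate, fraction 0 | dual WGA on the informative samples |
| spectrum | C>T mass 0.45, other five classes equal | CRC-like C>T dominance |
| clinical | P(CEA ≥ 5) = logistic(−2 + 12·tumor fraction); CEA missing w.p. 0.5; Dukes ~ (7,16,21,4)/48; P(MSI)=0.15 | recoverable positive CEA link; half the cohort lacks CEA, as in the study population |

Observed VAFs are quantized: alt = round(VAF·depth) for errors and
alt ~ Binomial(depth, tumor_fraction · true VAF) for tumor-derived variants,
with the reported VAF re-derived from counts and zero-support variants not
called. Quantization perturbs the >1% retention of individual draws, but
integrated over the dispersed depth distribution the retained fraction of
median-1% errors stays at ~0.50 (verified by closed form vs Monte Carlo in
the tests); the mean retained count per CTC sample is then
150·0.5 + ~9 tumor-derived ≈ 84.

There is no genome: the reference base at a locus is a deterministic hash of
(chrom, pos), so all generators agree on ref alleles and chance cross-sample
key collisions remain possible. Tumor truth variants draw their substitution
class first and then rejection-sample a locus whose pseudo-reference matches
the class on either strand, so the configured class mass is exact. An
optional CTC-private subclone (off by default) plants variants shared by a
patient's WGA replicates but absent from the tumor, to exercise the
replicate-concordance path.

What the generator does **not** model — and hence what green tests do not
establish about real data: alignment and calling artifacts other than WGA
errors, locus-specific error propensities (hotspots are uniform random
loci), allelic dropout and amplification bias across loci, CNVs, subclonal
tumor phylogenies, and indel errors. Parameter-recovery results demonstrate
the pipeline's internal consistency at the study's scale, not field accuracy.

## Clinical association

The Mann–Whitney U test is implemented in the package (it is the analysis'
central test): U from the rank sum of the first group with midrank ties; for
min(n, m) ≤ 8 without ties the two-sided p comes from exact enumeration of
the rank-arrangement distribution, P(|U − nm/2| ≥ |u − nm/2|), computed via
the standard counting recurrence and verified against brute-force
enumeration and scipy; otherwise the normal approximation with tie-corrected
variance and continuity correction is used. All-identical input yields
p = 1. Kruskal–Wallis (Dukes with > 2 levels) and Spearman (age) are scipy
calls behind the module surface.

Two observation mappings are exposed because the variant-to-observation
mapping behind a per-variant scatter is ambiguous: `pooled` (default; every
tumor-matched call is one observation, labelled by its patient's group) and
`patient_median` (one median AF per patient). Pooled mode matches the
plotting convention but treats within-patient-correlated AFs as independent,
which is anti-conservative — on a default synthetic cohort it can declare
spurious secondary associations. Patient-median mode makes the patient the
exchangeable unit; the null-calibration test (1,000 small zero-slope
cohorts) runs in this mode and holds the type-I error at 0.05 ± 0.02. The
four variables are reported raw, without multiple-testing correction, and
flagged as such.

## Numerical and degenerate-input choices

* AF threshold strictly exclusive (`vaf > min_vaf`); VAFs are exact count
  ratios so the 4/400 = 1% boundary case is handled without tolerance.
* Zero SNVs → the spectrum is an error, not an all-zero profile; dominant
  class ties break in the fixed class order C>A … T>G.
* Blacklist construction requires ≥ 2 error sets; an empty match-rate
  denominator raises rather than returning 0.
* Percentages: detection rounded to the nearest integer; match rate and gene
  table to one decimal.
* Determinism: one root seed; the cohort generator spawns independent
  per-patient seed sequences, so outputs are byte-identical across runs and
  platforms.

## Problem sizes used in shipped analyses

The analysis scripts and the acceptance script run the full default cohort
(48 patients, ~190 sample tables, ~80k simulated variant records, ~1 s to
generate). The null-calibration study uses 1,000 cohorts of 16 patients over
a 4 kb panel, chosen as the smallest design in which the CEA grouping is
almost always testable.
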
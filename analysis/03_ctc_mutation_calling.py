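#!/usr/bin/env python
"""Call somatic mutations in the CTC samples.

Applies the filter cascade to every CTC-WGA sample: blacklist removal,
>1% allele-frequency threshold, intersection with the matched primary tumor.
Reports the cohort detection rate, the mean number of retained variants per
CTC sample, replicate-concordant CTC-private candidates, and the per-gene
alteration table. Writes a tidy table of tumor-matched call AFs for the
downstream spectrum and clinical analyses.
"""

import argparse
import json
import os

import pandas as pd

from ctcseq.filtering import (
    PatientFilterResult,
    cohort_detection_summary,
    filter_ctc_sample,
    replicate_concordant_private,
)
from ctcseq.io import read_panel_bed
from ctcseq.report import gene_alteration_table
from ctcseq.variants import SampleRole
from ctcseq.wga_errors import read_blacklist

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "wga_step", os.path.join(os.path.dirname(__file__), "02_wga_error_model.py")
)
_wga = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_wga)
load_cohort_samples = _wga.load_cohort_samples


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="scratch/cohort")
    ap.add_argument("--blacklist", default="results/blacklist.tsv")
    ap.add_argument("--results", default="results")
    ap.add_argument("--min-vaf", type=float, default=0.01)
    args = ap.parse_args()

    samples = load_cohort_samples(args.cohort)
    blacklist = read_blacklist(args.blacklist)
    panel = read_panel_bed(os.path.join(args.cohort, "panel.bed"))

    results, af_rows, private_rows = [], [], []
    matched_by_sample = {}
    for pid, by_role in sorted(samples.items()):
        tumor = by_role[SampleRole.TUMOR.value][0]
        ctcs = sorted(
            by_role.get(SampleRole.CTC_WGA.value, []),
            key=lambda s: s.replicate_index or 0,
        )
        res = PatientFilterResult(pid)
        retained_sets = []
        for ctc in ctcs:
            matched, trace = filter_ctc_sample(ctc, blacklist, tumor, args.min_vaf)
            retained_sets.append(
                filter_ctc_sample(ctc, blacklist, None, args.min_vaf)[0]
            )
            res.sample_traces.append(trace)
            matched_by_sample[ctc.sample_id] = matched
            for ov in matched:
                af_rows.append(
                    {
                        "patient_id": pid,
                        "sample_id": ctc.sample_id,
                        "chrom": ov.variant.chrom,
                        "pos": ov.variant.pos,
                        "ref": ov.variant.ref,
                        "alt": ov.variant.alt,
                        "vaf": ov.vaf,
                    }
                )
        if len(retained_sets) >= 2:
            for call in replicate_concordant_private(
                retained_sets[0], retained_sets[1], tumor, blacklist
            ):
                private_rows.append(
                    {
                        "patient_id": pid,
                        "chrom": call.variant.chrom,
                        "pos": call.variant.pos,
                        "ref": call.variant.ref,
                        "alt": call.variant.alt,
                        "mean_vaf": call.vaf,
                    }
                )
        results.append(res)

    summary = cohort_detection_summary(results)
    gene_df = gene_alteration_table(matched_by_sample, panel)

    os.makedirs(args.results, exist_ok=True)
    pd.DataFrame(
        af_rows,
        columns=["patient_id", "sample_id", "chrom", "pos", "ref", "alt", "vaf"],
    ).to_csv(os.path.join(args.results, "tumor_matched_afs.tsv"), sep="\t", index=False)
    pd.DataFrame(
        private_rows,
        columns=["patient_id", "chrom", "pos", "ref", "alt", "mean_vaf"],
    ).to_csv(os.path.join(args.results, "ctc_private_calls.tsv"), sep="\t", index=False)
    gene_df.to_csv(
        os.path.join(args.results, "gene_alteration_table.tsv"), sep="\t", index=False
    )
    with open(os.path.join(args.results, "detection_summary.json"), "w") as fh:
        json.dump(
            {
                "n_detected": summary.n_detected,
                "n_total": summary.n_total,
                "percent": summary.percent,
                "mean_variants_per_ctc_sample": summary.mean_variants_per_ctc_sample,
                "n_ctc_private_calls": len(private_rows),
            },
            fh,
            indent=2,
        )
        fh.write("\n")

    print(
        f"Tumor-matching mutations detected in {summary.n_detected}/"
        f"{summary.n_total} patients ({summary.percent}%)."
    )
    print(
        f"Mean retained variants per CTC sample (post-blacklist, >1% VAF): "
        f"{summary.mean_variants_per_ctc_sample:.1f}"
    )
    print(f"Replicate-concordant CTC-private candidates: {len(private_rows)}")
    top = gene_df.head(3)
    print(
        "Most altered genes: "
        + ", ".join(f"{r.gene} ({r.percent}%)" for r in top.itertuples(index=False))
    )


if __name__ == "__main__":
    main()
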
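#!/usr/bin/env python
"""Characterize WGA amplification errors from the amplified-normal controls.

Calls amplification errors (amplified normal minus matched unamplified
normal), builds the recurrent-error blacklist (keys seen in >= 2 controls),
summarizes the VAF medians of the recurrent vs random error partitions, and
estimates the false-positive tumor-match rate of errors that survive the
blacklist and the >1% allele-frequency threshold.
"""

import argparse
import json
import os

import pandas as pd

from ctcseq.io import read_variant_table
from ctcseq.variants import SampleRole
from ctcseq.wga_errors import (
    UndefinedRateError,
    build_blacklist,
    call_amplification_errors,
    estimate_fp_match_rate,
    summarize_error_vafs,
    write_blacklist,
)


def load_cohort_samples(cohort_dir):
    mdf = pd.read_csv(os.path.join(cohort_dir, "manifest.tsv"), sep="\t", dtype=str)
    samples = {}
    for row in mdf.itertuples(index=False):
        s = read_variant_table(os.path.join(cohort_dir, row.path))
        samples.setdefault(row.patient_id, {}).setdefault(row.role, []).append(s)
    return samples


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="scratch/cohort")
    ap.add_argument("--results", default="results")
    ap.add_argument("--min-recurrence", type=int, default=2)
    args = ap.parse_args()

    samples = load_cohort_samples(args.cohort)
    error_sets = []
    tumors = {}
    for pid, by_role in sorted(samples.items()):
        if SampleRole.TUMOR.value in by_role:
            tumors[pid] = by_role[SampleRole.TUMOR.value][0]
        if SampleRole.AMPLIFIED_NORMAL.value in by_role:
            error_sets.append(
                call_amplification_errors(
                    by_role[SampleRole.AMPLIFIED_NORMAL.value][0],
                    by_role[SampleRole.NORMAL.value][0],
                )
            )

    blacklist = build_blacklist(error_sets, min_recurrence=args.min_recurrence)
    summary = summarize_error_vafs(error_sets, blacklist)
    try:
        fp = estimate_fp_match_rate(error_sets, blacklist, tumors)
        fp_dict = {"n_match": fp.n_match, "n_total": fp.n_total,
                   "rate_percent": fp.rate_percent}
    except UndefinedRateError:
        fp_dict = None

    os.makedirs(args.results, exist_ok=True)
    write_blacklist(blacklist, os.path.join(args.results, "blacklist.tsv"))
    payload = {
        "n_amplified_normals": len(error_sets),
        "n_error_observations": sum(len(e) for e in error_sets),
        "blacklist_size": len(blacklist),
        "recurrent_vaf_median_percent": (
            100 * summary.recurrent_vaf_median
            if summary.recurrent_vaf_median is not None else None
        ),
        "nonrecurrent_vaf_median_percent": (
            100 * summary.nonrecurrent_vaf_median
            if summary.nonrecurrent_vaf_median is not None else None
        ),
        "n_recurrent": summary.n_recurrent,
        "n_nonrecurrent": summary.n_nonrecurrent,
        "fp_match_rate": fp_dict,
    }
    out = os.path.join(args.results, "wga_error_summary.json")
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")

    print(
        f"{payload['n_error_observations']} WGA errors from "
        f"{payload['n_amplified_normals']} amplified normals; "
        f"{payload['blacklist_size']} recurrent loci blacklisted."
    )
    print(
        f"Median VAF: recurrent {payload['recurrent_vaf_median_percent']:.2f}%, "
        f"random {payload['nonrecurrent_vaf_median_percent']:.2f}%."
    )
    if fp_dict:
        print(
            f"False-positive tumor-match rate: {fp_dict['n_match']}/"
            f"{fp_dict['n_total']} = {fp_dict['rate_percent']}% of retained errors."
        )
    print(f"Wrote {out} and {args.results}/blacklist.tsv")


if __name__ == "__main__":
    main()
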
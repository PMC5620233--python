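#!/usr/bin/env python
"""Associate CTC mutation allele frequencies with clinical variables.

Runs rank-based tests of the tumor-matched CTC allele frequencies against
CEA (dichotomized at 5 ng/ml, Mann-Whitney), age (Spearman), Dukes' stage
(Kruskal-Wallis) and MSI status (Mann-Whitney), in both the pooled
per-variant mode and the per-patient-median mode. P-values are reported raw
(no multiple-testing correction across the four variables).
"""

import argparse
import dataclasses
import json
import os

import pandas as pd

from ctcseq.clinical import AssociationError, associate_af_with_clinical
from ctcseq.io import read_clinical_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--calls", default="results/tumor_matched_afs.tsv")
    ap.add_argument("--clinical", default="scratch/cohort/clinical.csv")
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    df = pd.read_csv(args.calls, sep="\t", dtype={"patient_id": str})
    afs = {pid: grp["vaf"].tolist() for pid, grp in df.groupby("patient_id")}
    clinical = read_clinical_csv(args.clinical)

    payload = {}
    for mode in ("pooled", "patient_median"):
        payload[mode] = {}
        for variable in ("CEA", "AGE", "DUKES", "MSI"):
            try:
                res = associate_af_with_clinical(afs, clinical, variable, mode=mode)
                payload[mode][variable] = dataclasses.asdict(res)
            except AssociationError as exc:
                payload[mode][variable] = {"error": str(exc)}

    os.makedirs(args.results, exist_ok=True)
    out = os.path.join(args.results, "clinical_associations.json")
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")

    for variable, res in payload["pooled"].items():
        if "error" in res:
            print(f"{variable}: not testable ({res['error']})")
        else:
            extra = f", higher in {res['direction']}" if res.get("direction") else ""
            print(
                f"{variable}: {res['test_name']} p={res['p_value']:.3g} "
                f"(pooled, n={sum(res['group_sizes'].values())}{extra})"
            )
    print(f"Full results (both modes): {out}")


if __name__ == "__main__":
    main()
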
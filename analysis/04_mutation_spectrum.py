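#!/usr/bin/env python
"""Mutation spectrum of the tumor-matched CTC calls.

Computes the strand-collapsed six-class substitution spectrum of the pooled
tumor-matched CTC variants and reports the dominant class (expected: C>T,
the colorectal-cancer signature). Optionally renders a bar chart.
"""

import argparse
import dataclasses
import json
import os

import pandas as pd

from ctcseq.spectrum import compute_spectrum, dominant_class
from ctcseq.variants import GenomicVariant


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--calls", default="results/tumor_matched_afs.tsv")
    ap.add_argument("--results", default="results")
    ap.add_argument("--plot", default=None,
                    help="Optional path for a bar-chart PNG (e.g. scratch/spectrum.png)")
    args = ap.parse_args()

    df = pd.read_csv(args.calls, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    variants = [
        GenomicVariant(r.chrom, int(r.pos), r.ref, r.alt)
        for r in df.itertuples(index=False)
    ]
    profile = compute_spectrum(variants)
    dom = dominant_class(profile)

    os.makedirs(args.results, exist_ok=True)
    out = os.path.join(args.results, "mutation_spectrum.json")
    payload = dataclasses.asdict(profile)
    payload["dominant_class"] = dom
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")

    print(f"Spectrum over {profile.n_snvs} SNVs ({profile.n_non_snv} non-SNVs ignored):")
    for cls, freq in profile.frequencies.items():
        print(f"  {cls}: {freq:.3f}")
    print(f"Dominant class: {dom}")

    if args.plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        os.makedirs(os.path.dirname(args.plot) or ".", exist_ok=True)
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(list(profile.frequencies), list(profile.frequencies.values()),
               color="#4c72b0")
        ax.set_ylabel("frequency")
        ax.set_title("CTC somatic mutation spectrum")
        fig.tight_layout()
        fig.savefig(args.plot, dpi=150)
        print(f"Plot: {args.plot}")


if __name__ == "__main__":
    main()
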
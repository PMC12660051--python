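#!/usr/bin/env python
"""Summarize HU accuracy and spatial-structural agreement of sCT vs pCT.

Reads the per-case agreement table from stage 01 and reports, per tissue
class (body, soft tissue, bone, air), the cohort median and interquartile
range of MAE, Dice, ASSD and Hausdorff distance — the evaluation that
typically shows bone as the most dissimilar class.

    python analysis/02_image_agreement.py
"""

import argparse
from pathlib import Path

import pandas as pd


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/image_agreement_summary.csv"))
    args = ap.parse_args()

    ag = pd.read_csv(args.cohort_dir / "agreement.csv")
    rows = []
    for (structure,), sub in ag.groupby(["structure"]):
        for col in ("mae_hu", "dice", "assd_mm", "hd_mm"):
            v = sub[col].dropna()
            rows.append({
                "structure": structure, "metric": col,
                "median": v.median(),
                "q1": v.quantile(0.25), "q3": v.quantile(0.75),
                "min": v.min(), "max": v.max(), "n": len(v),
            })
    out = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out, index=False, float_format="%.6g")

    piv = out[out.metric == "mae_hu"].set_index("structure")
    print("median (IQR) MAE by tissue class [HU]:")
    for s in ("body", "soft_tissue", "bone", "air"):
        r = piv.loc[s]
        print(f"  {s:12s} {r['median']:6.1f} ({r.q1:.1f}-{r.q3:.1f})")
    d = out[(out.metric == "dice") & (out.structure == "bone")].iloc[0]
    print(f"bone Dice median {d['median']:.2f} — the least congruent class")
    print(f"summary written to {args.out}")


if __name__ == "__main__":
    main()
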
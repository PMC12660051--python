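#!/usr/bin/env python
"""Gamma pass-rate summaries (2%/2 mm, local and global, two thresholds).

Reads the 16-cell per-case gamma table from stage 01 and reports cohort
median/IQR per modality, normalization mode, dose threshold and ROI — the
comparison in which proton recalculations on sCT typically fare worse than
photon ones.

    python analysis/04_gamma_pass_rates.py
"""

import argparse
from pathlib import Path

import pandas as pd


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/gamma_pass_rate_summary.csv"))
    args = ap.parse_args()

    g = pd.read_csv(args.cohort_dir / "gamma.csv")
    rows = []
    for (modality, mode, thr, roi), sub in g.groupby(
        ["modality", "mode", "threshold_percent", "roi"]
    ):
        v = sub["pass_rate_percent"]
        rows.append({
            "modality": modality, "mode": mode, "threshold_percent": thr,
            "roi": roi, "median": v.median(), "q1": v.quantile(0.25),
            "q3": v.quantile(0.75), "min": v.min(), "n": len(v),
        })
    out = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out, index=False, float_format="%.6g")

    sel = out[(out["mode"] == "local") & (out.threshold_percent == 10.0)
              & (out.roi == "body")].set_index("modality")
    print("local gamma pass rate, whole body, 10% dose threshold:")
    for m in ("photon", "proton"):
        r = sel.loc[m]
        print(f"  {m:7s} median {r['median']:.1f}% (IQR {r.q1:.1f}-{r.q3:.1f}%, "
              f"worst case {r['min']:.1f}%)")
    print(f"summary written to {args.out}")


if __name__ == "__main__":
    main()
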
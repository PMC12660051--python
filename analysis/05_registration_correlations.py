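#!/usr/bin/env python
"""Does residual pCT/sCT misregistration explain the gamma failures?

Reads stage 01's gamma and misregistration tables and correlates the local
gamma pass rate (whole body, 10% threshold) with the body-contour ASSD and
the beam-visible misregistration volumes V_photon / V_proton — the analysis
that attributes the poorer proton agreement to patient-positioning changes
between the CT and MR sessions.

    python analysis/05_registration_correlations.py
"""

import argparse
from pathlib import Path

import pandas as pd

from sctdoseval.stats import PairedSample, StatsError, pearson


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path,
                    default=Path("results/registration_correlations.csv"))
    args = ap.parse_args()

    g = pd.read_csv(args.cohort_dir / "gamma.csv")
    mis = pd.read_csv(args.cohort_dir / "misregistration.csv").set_index("case_id")
    sel = g[(g["mode"] == "local") & (g.roi == "body")
            & (g.threshold_percent == 10.0)]

    rows = []
    for modality in ("photon", "proton"):
        gpr = sel[sel.modality == modality].set_index("case_id")[
            "pass_rate_percent"
        ]
        m = mis.loc[gpr.index]
        for label, col in (("assd_body_mm", "assd_body_mm"),
                           (f"v_{modality}_cm3", f"v_{modality}_cm3")):
            try:
                r, p = pearson(PairedSample(gpr.values, m[col].values))
            except StatsError as e:
                r, p = float("nan"), float("nan")
                print(f"  {modality} vs {label}: undefined ({e})")
                continue
            rows.append({"modality": modality, "against": label,
                         "pearson_r": r, "p_value": p, "n": len(gpr)})
            print(f"  local GPR ({modality}) vs {label}: "
                  f"r = {r:+.2f} (p = {p:.3g})")
    out = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out, index=False, float_format="%.6g")
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
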
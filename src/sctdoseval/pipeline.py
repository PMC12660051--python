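"""End-to-end per-case and cohort analysis.

``run_case`` executes the evaluation chain on one case — HU overrides,
segmentation on each CT, image agreement (MAE / Dice / surface distances),
misregistration volumes, DVH-metric differences and the 16-cell gamma
pass-rate table.  ``run_cohort`` streams generated cases through it and adds
the cohort statistics: paired Wilcoxon tests of pCT- vs sCT-calculated DVH
metrics (and photon vs proton differences), Pearson correlations of the local
gamma pass rate against the body-contour ASSD and the beam-visible
misregistration volumes, and median/IQR summaries.  All tables are written as
CSV with 6-significant-digit floats so identical configuration and seed give
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import dvh as dvhmod
from . import segmentation as seg
from .case import CaseRecord
from .gamma import GammaCriteria, pass_rate_table
from .grid import Mask, Volume, override_hu
from .phantom import PhantomSpec, SCTErrorModel, iter_cohort
from .stats import PairedSample, StatsError, pearson, summarize, wilcoxon_signed_rank

logger = logging.getLogger("sctdoseval")

__all__ = ["CohortReport", "default_config", "load_config", "run_case", "run_cohort"]

FLOAT_FORMAT = "%.6g"


def default_config() -> dict:
    """Pipeline defaults; every analysis parameter is configurable here."""
    return {
        "phantom": {
            "grid_shape": [128, 128, 80],
            "spacing_mm": [2.0, 2.0, 2.0],
            "base_of_tongue_fraction": 0.35,
            "bilateral_fraction": 0.9,
        },
        "error_model": {
            "mae_targets_hu": {"soft_tissue": 43.0, "bone": 298.0, "air": 118.0},
            "bone_edge_amplitude": 0.35,
            "offset_translation_sd_mm": 3.5,
            "offset_rotation_sd_deg": 1.5,
            "residual_fraction": 0.3,
            "shoulder_deformation": True,
        },
        "plans": {
            "prescription_gy": 68.0,
            "elective_gy": 50.0,
            "fractions": 34,
            "photon_beams": 72,
        },
        "segmentation": {
            "body_threshold_hu": -250.0,
            "t_low_hu": -250.0,
            "t_high_hu": 250.0,
        },
        "overrides": {"contrast_hu": 0.0, "table_hu": -1000.0},
        "dvh": {"bin_width_gy": 0.01},
        "gamma": {
            "dose_criterion_percent": 2.0,
            "dta_mm": 2.0,
            "thresholds_percent": [10.0, 90.0],
            "gamma_cap": 1.1,
            "intersect_ctv_with_body_overlap": True,
        },
        "misregistration": {"beam_visibility_fraction": 0.05},
        "stats": {
            "alpha": 0.05,
            "gpr_mode": "local",
            "gpr_roi": "body",
            "gpr_threshold_percent": 10.0,
        },
        "cohort": {"n_cases": 20, "seed": 0},
        "output": {"float_format": FLOAT_FORMAT},
    }


def _deep_update(base: dict, other: dict) -> dict:
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config root must be a mapping, got {type(user).__name__}")
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


# -- per-case ----------------------------------------------------------------


def run_case(case: CaseRecord, config: Optional[dict] = None) -> Dict[str, pd.DataFrame]:
    """Run the full evaluation chain on one case.

    Returns a bundle of long-format tables: ``agreement`` (per tissue class),
    ``misregistration``, ``dvh`` (per structure/metric/modality, pCT minus
    sCT) and ``gamma`` (16 pass-rate cells).
    """
    cfg = config if config is not None else default_config()
    scfg = cfg["segmentation"]
    logger.info("case %s: overrides", case.case_id)

    pct = case.pct
    if case.contrast_mask is not None and case.contrast_mask.n_true:
        pct = override_hu(pct, case.contrast_mask, cfg["overrides"]["contrast_hu"])
    if case.table_mask is not None and case.table_mask.n_true:
        pct = override_hu(pct, case.table_mask, cfg["overrides"]["table_hu"])

    logger.info("case %s: segmentation", case.case_id)
    body_p = seg.segment_body(pct, scfg["body_threshold_hu"])
    body_s = seg.segment_body(case.sct, scfg["body_threshold_hu"])
    classes_p = seg.segment_tissue_classes(pct, body_p, scfg["t_low_hu"], scfg["t_high_hu"])
    classes_s = seg.segment_tissue_classes(case.sct, body_s, scfg["t_low_hu"], scfg["t_high_hu"])

    logger.info("case %s: image agreement", case.case_id)
    rows = []
    for name in ("body", "soft_tissue", "bone", "air"):
        mp = getattr(classes_p, name)
        ms = getattr(classes_s, name)
        region = seg.intersection(mp, ms)
        row = {"case_id": case.case_id, "structure": name}
        row["mae_hu"] = (
            agr.mae(pct, case.sct, region) if region.n_true else np.nan
        )
        row["dice"] = agr.dice(mp, ms)
        if mp.n_true and ms.n_true:
            row["assd_mm"], row["hd_mm"] = agr.surface_distances(mp, ms)
        else:
            row["assd_mm"] = row["hd_mm"] = np.nan
        rows.append(row)
    agreement = pd.DataFrame(rows)

    logger.info("case %s: misregistration", case.case_id)
    misreg = agr.misregistration_mask(body_p, body_s)
    vis = cfg["misregistration"]["beam_visibility_fraction"]
    assd_body = float(agreement.loc[agreement.structure == "body", "assd_mm"].iloc[0])
    mis_row = {
        "case_id": case.case_id,
        "xor_volume_cm3": misreg.volume_cm3,
        "v_photon_cm3": agr.beam_visible_volume(
            misreg, case.dose_photon_sct, case.prescription_gy, vis
        ),
        "v_proton_cm3": agr.beam_visible_volume(
            misreg, case.dose_proton_sct, case.prescription_gy, vis
        ),
        "assd_body_mm": assd_body,
    }
    for s in ("ctvn68", "ctve"):
        if s in case.structures and case.structures[s].n_true:
            mis_row[f"frac_{s}_outside_sct_body"] = seg.fraction_outside(
                case.structures[s], body_s
            )
    misregistration = pd.DataFrame([mis_row])

    logger.info("case %s: DVH metrics", case.case_id)
    plan = dvhmod.default_metric_plan("ctvp68")
    dvh_tables = []
    for modality in ("photon", "proton"):
        t = dvhmod.dvh_metric_difference(
            getattr(case, f"dose_{modality}_pct"),
            getattr(case, f"dose_{modality}_sct"),
            case.structures,
            plan,
            modality=modality,
        )
        dvh_tables.append(t)
    dvh = pd.concat(dvh_tables, ignore_index=True)
    dvh.insert(0, "case_id", case.case_id)

    logger.info("case %s: gamma analysis", case.case_id)
    gcfg = cfg["gamma"]
    case.body_overlap = seg.intersection(body_p, body_s)
    ctv = case.structures["ctvp68"]
    for s in ("ctvn68", "ctve"):
        ctv = seg.union(ctv, case.structures[s])
    if gcfg.get("intersect_ctv_with_body_overlap", True):
        ctv = seg.intersection(ctv, case.body_overlap)
    case.ctv_union = ctv
    crit = GammaCriteria(
        dose_criterion_percent=gcfg["dose_criterion_percent"],
        dta_mm=gcfg["dta_mm"],
        prescription_gy=case.prescription_gy,
    )
    gamma = pass_rate_table(case, crit, gamma_cap=gcfg.get("gamma_cap", 1.1))
    gamma.insert(0, "case_id", case.case_id)

    return {
        "agreement": agreement,
        "misregistration": misregistration,
        "dvh": dvh,
        "gamma": gamma,
    }


# -- cohort ------------------------------------------------------------------


@dataclass
class CohortReport:
    """All cohort-level tables produced by :func:`run_cohort`."""

    agreement: pd.DataFrame
    misregistration: pd.DataFrame
    dvh: pd.DataFrame
    gamma: pd.DataFrame
    statistics: pd.DataFrame
    summaries: pd.DataFrame
    n_cases: int
    config: dict = field(repr=False, default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ff = self.config.get("output", {}).get("float_format", FLOAT_FORMAT)
        for name in ("agreement", "misregistration", "dvh", "gamma", "statistics", "summaries"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False, float_format=ff)
        manifest = {
            "n_cases": self.n_cases,
            "config_sha256": hashlib.sha256(
                json.dumps(self.config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "config": self.config,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _safe_wilcoxon(x, y) -> tuple:
    try:
        w, p = wilcoxon_signed_rank(PairedSample(np.asarray(x), np.asarray(y)))
        return w, p, ""
    except StatsError as e:
        return np.nan, np.nan, str(e)


def _safe_pearson(x, y) -> tuple:
    try:
        r, p = pearson(PairedSample(np.asarray(x), np.asarray(y)))
        return r, p, ""
    except StatsError as e:
        return np.nan, np.nan, str(e)


def cohort_statistics(
    dvh: pd.DataFrame,
    gamma: pd.DataFrame,
    misregistration: pd.DataFrame,
    cfg: Optional[dict] = None,
) -> pd.DataFrame:
    """Cohort statistics: Wilcoxon pCT vs sCT per metric and modality,
    Wilcoxon photon-vs-proton differences, and Pearson correlations of the
    local gamma pass rate with registration-quality measures."""
    cfg = cfg if cfg is not None else default_config()
    stats_cfg = cfg["stats"]
    rows = []
    for (modality, structure, metric), sub in dvh.groupby(
        ["modality", "structure", "metric"], sort=True
    ):
        w, p, note = _safe_wilcoxon(sub["pct_gy"], sub["sct_gy"])
        rows.append(
            {
                "test": "wilcoxon_pct_vs_sct",
                "modality": modality,
                "structure": structure,
                "metric": metric,
                "statistic": w,
                "p_value": p,
                "note": note,
            }
        )
    wide = dvh.pivot_table(
        index=["case_id", "structure", "metric"], columns="modality",
        values="delta_gy", aggfunc="first",
    ).reset_index()
    if {"photon", "proton"} <= set(wide.columns):
        for (structure, metric), sub in wide.groupby(["structure", "metric"], sort=True):
            w, p, note = _safe_wilcoxon(sub["photon"], sub["proton"])
            rows.append(
                {
                    "test": "wilcoxon_photon_vs_proton_delta",
                    "modality": "both",
                    "structure": structure,
                    "metric": metric,
                    "statistic": w,
                    "p_value": p,
                    "note": note,
                }
            )
    gpr_sel = gamma[
        (gamma["mode"] == stats_cfg["gpr_mode"])
        & (gamma["roi"] == stats_cfg["gpr_roi"])
        & (gamma["threshold_percent"] == stats_cfg["gpr_threshold_percent"])
    ]
    for modality in ("photon", "proton"):
        g = gpr_sel[gpr_sel["modality"] == modality].set_index("case_id")[
            "pass_rate_percent"
        ]
        m = misregistration.set_index("case_id").loc[g.index]
        for against, col in (
            ("assd_body_mm", "assd_body_mm"),
            (f"v_{modality}_cm3", f"v_{modality}_cm3"),
        ):
            r, p, note = _safe_pearson(g.values, m[col].values)
            rows.append(
                {
                    "test": "pearson_local_gpr",
                    "modality": modality,
                    "structure": stats_cfg["gpr_roi"],
                    "metric": f"gpr_vs_{against}",
                    "statistic": r,
                    "p_value": p,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)


def cohort_summaries(agreement: pd.DataFrame, gamma: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR, range) summaries of the per-case agreement metrics and
    gamma pass rates."""
    rows = []
    for (structure,), sub in agreement.groupby(["structure"], sort=True):
        for col in ("mae_hu", "dice", "assd_mm", "hd_mm"):
            vals = sub[col].dropna().values
            if len(vals) == 0:
                continue
            med, q1, q3, lo, hi = summarize(vals)
            rows.append(
                {
                    "quantity": col,
                    "group": structure,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "min": lo,
                    "max": hi,
                    "n": len(vals),
                }
            )
    for (modality, mode, thr, roi), sub in gamma.groupby(
        ["modality", "mode", "threshold_percent", "roi"], sort=True
    ):
        med, q1, q3, lo, hi = summarize(sub["pass_rate_percent"].values)
        rows.append(
            {
                "quantity": "gamma_pass_rate_percent",
                "group": f"{modality}/{mode}/{thr:g}%/{roi}",
                "median": med,
                "q1": q1,
                "q3": q3,
                "min": lo,
                "max": hi,
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)


def run_cohort(
    config: Optional[dict] = None,
    seed: Optional[int] = None,
    n_cases: Optional[int] = None,
    out_dir=None,
    keep_going: bool = False,
    cases: Optional[Iterable[CaseRecord]] = None,
) -> CohortReport:
    """Generate (or accept) a cohort, run every case, and assemble the
    cohort report.  Degenerate statistics (identical pairs, constant
    correlates) are flagged in the tables' ``note`` column rather than
    raising."""
    cfg = config if config is not None else default_config()
    seed = seed if seed is not None else cfg["cohort"].get("seed", 0)
    n = n_cases if n_cases is not None else cfg["cohort"]["n_cases"]
    if cases is None:
        if n < 2:
            raise ValueError("a cohort needs at least 2 cases")
        pcfg = cfg["phantom"]
        ecfg = cfg["error_model"]
        spec = PhantomSpec(
            grid_shape=tuple(pcfg["grid_shape"]),
            spacing_mm=tuple(pcfg["spacing_mm"]),
        )
        err = SCTErrorModel(
            mae_targets_hu=dict(ecfg["mae_targets_hu"]),
            bone_edge_amplitude=ecfg["bone_edge_amplitude"],
            offset_translation_sd_mm=ecfg["offset_translation_sd_mm"],
            offset_rotation_sd_deg=ecfg["offset_rotation_sd_deg"],
            residual_fraction=ecfg["residual_fraction"],
            shoulder_deformation=ecfg["shoulder_deformation"],
        )
        cases = iter_cohort(
            n, spec, err, seed=seed, n_photon_beams=cfg["plans"]["photon_beams"]
        )
    bundles: Dict[str, List[pd.DataFrame]] = {
        "agreement": [], "misregistration": [], "dvh": [], "gamma": []
    }
    n_done = 0
    for case in cases:
        try:
            bundle = run_case(case, cfg)
        except Exception:
            logger.exception("case %s failed", case.case_id)
            if not keep_going:
                raise
            continue
        for k in bundles:
            bundles[k].append(bundle[k])
        n_done += 1
    if n_done == 0:
        raise RuntimeError("no case completed successfully")
    tables = {k: pd.concat(v, ignore_index=True) for k, v in bundles.items()}
    statistics = cohort_statistics(
        tables["dvh"], tables["gamma"], tables["misregistration"], cfg
    )
    summaries = cohort_summaries(tables["agreement"], tables["gamma"])
    report = CohortReport(
        agreement=tables["agreement"],
        misregistration=tables["misregistration"],
        dvh=tables["dvh"],
        gamma=tables["gamma"],
        statistics=statistics,
        summaries=summaries,
        n_cases=n_done,
        config=cfg,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
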
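"""Cumulative dose-volume histograms and DVH point metrics.

``D_v`` (the minimum dose received by the hottest v% of a structure) is
computed from the structure's voxel doses by order statistics with linear
interpolation: with doses sorted ascending, ``D_v`` sits at fractional rank
``k = n (1 - v/100) + 1`` (1-based), clamped to [1, n].  This convention
agrees exactly with a brute-force threshold scan at every attainable volume
fraction, gives ``D_100 = min`` and approaches ``max`` as v -> 0.  All voxels
are weighted equally (no sub-voxel volume model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .grid import Mask, Volume, require_same_grid

__all__ = [
    "DVHCurve",
    "DVHError",
    "dose_at_volume",
    "mean_dose",
    "compute_dvh",
    "dvh_metrics",
    "dvh_metric_difference",
    "TARGET_METRICS",
    "OAR_DMEAN_STRUCTURES",
    "OAR_D2_STRUCTURES",
]

#: metrics evaluated for the high-risk target
TARGET_METRICS = ("d2_gy", "d99_5_gy", "dmean_gy")
#: organs at risk reported with mean dose
OAR_DMEAN_STRUCTURES = (
    "spinal_cord",
    "brainstem",
    "parotid_l",
    "parotid_r",
    "oesophagus",
    "oral_cavity",
    "larynx",
)
#: serial organs additionally reported with near-maximum dose
OAR_D2_STRUCTURES = ("spinal_cord", "brainstem")


class DVHError(ValueError):
    pass


def _structure_doses(dose: Volume, structure: Mask) -> np.ndarray:
    require_same_grid(dose, structure)
    if structure.n_true == 0:
        raise DVHError("empty structure mask")
    return dose.values[structure.values]


def dose_at_volume(dose: Volume, structure: Mask, volume_percent: float) -> float:
    """Largest dose d such that at least ``volume_percent`` of the structure
    receives >= d, linearly interpolated between order statistics."""
    if not (0 < volume_percent <= 100):
        raise DVHError("volume_percent must be in (0, 100]")
    d = np.sort(_structure_doses(dose, structure))
    n = d.size
    k = n * (1.0 - volume_percent / 100.0) + 1.0  # 1-based fractional rank
    k = min(max(k, 1.0), float(n))
    return float(np.interp(k, np.arange(1, n + 1), d))


def mean_dose(dose: Volume, structure: Mask) -> float:
    return float(_structure_doses(dose, structure).mean())


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the structure receiving at least each dose."""

    dose_edges: np.ndarray
    volume_fraction: np.ndarray
    structure_name: str = ""
    total_volume_cm3: float = 0.0

    def metric(self, volume_percent: float) -> float:
        """Read D_v off the curve (reporting convenience; point metrics are
        computed voxelwise, see :func:`dose_at_volume`)."""
        vf = self.volume_fraction
        target = volume_percent / 100.0
        # curve is non-increasing in dose; find the largest dose with vf >= target
        ok = vf >= target
        if not ok.any():
            return float(self.dose_edges[0])
        return float(self.dose_edges[np.nonzero(ok)[0][-1]])


def compute_dvh(
    dose: Volume,
    structure: Mask,
    bin_width_gy: float = 0.01,
    structure_name: str = "",
) -> DVHCurve:
    d = _structure_doses(dose, structure)
    top = max(float(d.max()), 0.0) + bin_width_gy
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    # fraction receiving >= edge
    counts = np.searchsorted(np.sort(d), edges, side="left")
    vf = 1.0 - counts / d.size
    vf[0] = 1.0
    return DVHCurve(edges, vf, structure_name, structure.volume_cm3)


_METRIC_FNS = {
    "d2_gy": lambda dv, m: dose_at_volume(dv, m, 2.0),
    "d99_5_gy": lambda dv, m: dose_at_volume(dv, m, 99.5),
    "dmean_gy": mean_dose,
}


def dvh_metrics(
    dose: Volume,
    structures: Dict[str, Mask],
    metrics_by_structure: Dict[str, Sequence[str]],
) -> pd.DataFrame:
    """Long-format table of DVH metrics for one dose grid."""
    rows = []
    for name, metric_names in metrics_by_structure.items():
        if name not in structures:
            raise DVHError(f"missing structure {name!r}")
        for metric in metric_names:
            fn = _METRIC_FNS[metric]
            rows.append(
                {"structure": name, "metric": metric, "value_gy": fn(dose, structures[name])}
            )
    return pd.DataFrame(rows)


def default_metric_plan(target: str = "ctvp68") -> Dict[str, Sequence[str]]:
    """The reported metric set: D2/D99.5/Dmean for the high-risk target, Dmean
    for the OARs plus D2 for spinal cord and brainstem."""
    plan: Dict[str, Sequence[str]] = {target: list(TARGET_METRICS)}
    for s in OAR_DMEAN_STRUCTURES:
        metrics = ["dmean_gy"]
        if s in OAR_D2_STRUCTURES:
            metrics.append("d2_gy")
        plan[s] = metrics
    return plan


def dvh_metric_difference(
    dose_pct: Volume,
    dose_sct: Volume,
    structures: Dict[str, Mask],
    metrics_by_structure: Dict[str, Sequence[str]],
    modality: str = "",
) -> pd.DataFrame:
    """Per structure/metric difference, computed as pCT minus sCT."""
    a = dvh_metrics(dose_pct, structures, metrics_by_structure)
    b = dvh_metrics(dose_sct, structures, metrics_by_structure)
    out = a.rename(columns={"value_gy": "pct_gy"})
    out["sct_gy"] = b["value_gy"]
    out["delta_gy"] = out["pct_gy"] - out["sct_gy"]
    if modality:
        out.insert(0, "modality", modality)
    return out
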
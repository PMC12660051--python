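"""Analytic photon-arc and proton multi-field dose surrogates.

These models are intentionally simple: they are not treatment-planning
engines, but they carry the physical structure that the evaluation pipeline
is sensitive to.  Protons deposit a parametric spread-out Bragg peak (SOBP)
in water-equivalent-thickness (WET) coordinates, so upstream HU errors shift
the steep distal dose edge; photons accumulate exponential attenuation of the
same WET, so the same HU errors change their dose only gently.  Both models
are deterministic and normalized so the median dose over the high-risk target
equals the prescription.

HU is mapped to relative proton stopping power (RSP) by a piecewise-linear
CT-calibration surrogate: RSP = max(0, 1 + HU/1000) up to 100 HU (air = 0,
water = 1), then a flattened bone ramp of 0.0005 / HU.

Beams are coplanar in the axial (x, y) plane.  Gantry angle 0 deg enters
anteriorly and travels toward +y; the in-beam direction of angle a is
(-sin a, cos a).  Per beam, the volume is resampled into the beam frame by an
in-plane rotation, depth integrals become cumulative sums, and the dose is
rotated back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import Grid, Mask, Volume

__all__ = [
    "PlanSpec",
    "DoseError",
    "hu_to_rsp",
    "wet_along_ray",
    "photon_dose",
    "proton_dose",
    "photon_arc_plan",
    "proton_field_plan",
]

#: effective linear attenuation per mm of water-equivalent depth (6 MV scale)
MU_WATER_PER_MM = 0.005
#: Gaussian sigma (mm, WET) of the distal SOBP falloff
SOBP_DISTAL_SIGMA_MM = 3.0
#: entrance plateau level relative to the SOBP flat top
SOBP_ENTRANCE_LEVEL = 0.7
#: slight rise of the entrance region with water-equivalent depth
SOBP_ENTRANCE_SLOPE_PER_MM = 0.0015
#: proximal ramp length (mm, WET) from entrance plateau up to the flat top
SOBP_PROXIMAL_RAMP_MM = 3.0
#: WET margin (mm) the SOBP extends beyond the target interval
SOBP_WET_MARGIN_MM = 2.0
#: lateral beam's-eye-view margin (mm) around the projected target
BEV_MARGIN_MM = 4.0

PROTON_ANGLES_BILATERAL = (0.0, 50.0, 160.0, 200.0, 310.0)
PROTON_ANGLES_UNILATERAL = (0.0, 50.0, 160.0, 180.0)


class DoseError(ValueError):
    pass


@dataclass(frozen=True)
class PlanSpec:
    """Treatment-plan surrogate: modality, prescriptions and beam geometry.

    68 Gy in 34 fractions to the high-risk targets and 50 Gy to the elective
    nodal volume; a full arc of equally weighted coplanar beams for photons,
    five bilateral (or four unilateral) fields for protons.
    """

    modality: str = "photon_arc"
    prescription_gy: float = 68.0
    fractions: int = 34
    elective_gy: float = 50.0
    beam_angles_deg: Tuple[float, ...] = ()

    def __post_init__(self):
        if self.modality not in ("photon_arc", "proton_fields"):
            raise DoseError(f"unknown modality {self.modality!r}")
        if self.prescription_gy <= 0:
            raise DoseError("prescription must be positive")
        if any(not (0 <= a < 360) for a in self.beam_angles_deg):
            raise DoseError("beam angles must lie in [0, 360)")


def photon_arc_plan(n_beams: int = 72, prescription_gy: float = 68.0,
                    elective_gy: float = 50.0) -> PlanSpec:
    angles = tuple(np.arange(n_beams) * 360.0 / n_beams)
    return PlanSpec("photon_arc", prescription_gy, 34, elective_gy, angles)


def proton_field_plan(bilateral: bool = True, prescription_gy: float = 68.0,
                      elective_gy: float = 50.0) -> PlanSpec:
    angles = PROTON_ANGLES_BILATERAL if bilateral else PROTON_ANGLES_UNILATERAL
    return PlanSpec("proton_fields", prescription_gy, 34, elective_gy, angles)


# -- HU -> stopping power ----------------------------------------------------


def hu_to_rsp(hu):
    """Relative proton stopping power from HU (monotone piecewise-linear)."""
    hu = np.asarray(hu, dtype=float)
    low = np.maximum(0.0, 1.0 + hu / 1000.0)
    high = 1.1 + (hu - 100.0) * 5e-4
    out = np.where(hu <= 100.0, low, high)
    return out if out.shape else float(out)


# -- WET line integral -------------------------------------------------------


def wet_along_ray(ct: Volume, origin, direction, depth_mm: float,
                  step_mm: Optional[float] = None) -> float:
    """Water-equivalent thickness along a ray: the integral of RSP over the
    first ``depth_mm`` mm of the ray.

    The RSP profile is sampled (trilinear) on a world-anchored lattice of step
    ``step_mm`` (default: half the smallest voxel spacing) along the ray and
    integrated as a piecewise-linear function, which makes the integral
    exactly additive in depth.  Rays missing the grid contribute 0.
    """
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise DoseError("direction must be non-zero")
    d = d / nrm
    origin = np.asarray(origin, dtype=float)
    if depth_mm <= 0:
        return 0.0
    h = step_mm if step_mm is not None else min(ct.grid.spacing) / 2.0
    s0 = float(origin @ d)
    s1 = s0 + depth_mm
    k_lo = int(np.floor(s0 / h)) - 1
    k_hi = int(np.ceil(s1 / h)) + 1
    ks = np.arange(k_lo, k_hi + 1)
    s_lattice = ks * h
    pts = origin[None, :] + (s_lattice - s0)[:, None] * d[None, :]
    idx = ct.grid.world_to_index(pts).T
    hu = ndimage.map_coordinates(
        ct.values.astype(float, copy=False), idx, order=1,
        mode="constant", cval=-1000.0,
    )
    g = hu_to_rsp(hu)

    # integral of the piecewise-linear interpolant of g over [s0, s1]
    def _ghat(s: float) -> float:
        j = int(np.floor(s / h)) - k_lo
        t = (s - s_lattice[j]) / h
        return float((1 - t) * g[j] + t * g[j + 1])

    ja = int(np.floor(s0 / h)) - k_lo
    jb = int(np.floor(s1 / h)) - k_lo
    if ja == jb:
        return 0.5 * (_ghat(s0) + _ghat(s1)) * (s1 - s0)
    total = 0.5 * (_ghat(s0) + g[ja + 1]) * (s_lattice[ja + 1] - s0)
    total += 0.5 * (g[jb] + _ghat(s1)) * (s1 - s_lattice[jb])
    if jb > ja + 1:
        seg = g[ja + 1 : jb + 1]
        total += h * (0.5 * seg[0] + seg[1:-1].sum() + 0.5 * seg[-1]) if seg.size > 1 else 0.0
    return float(total)


# -- in-plane rotation machinery --------------------------------------------


class _InplaneRotation:
    """Bilinear resampler rotating content by ``angle_deg`` about the z-axis
    through the grid center; corner indices and weights are precomputed once
    and reused for every volume rotated at this angle."""

    def __init__(self, grid: Grid, angle_deg: float):
        nx, ny = grid.shape[0], grid.shape[1]
        xs = grid.axis_coordinates(0)
        ys = grid.axis_coordinates(1)
        cx, cy = grid.center_world[:2]
        a = np.deg2rad(angle_deg)
        ca, sa = np.cos(a), np.sin(a)
        X, Y = np.meshgrid(xs - cx, ys - cy, indexing="ij")
        # content rotated by +a  =>  sample source at R(-a) * out
        sx = ca * X + sa * Y + cx
        sy = -sa * X + ca * Y + cy
        ix = (sx - grid.origin[0]) / grid.spacing[0]
        iy = (sy - grid.origin[1]) / grid.spacing[1]
        i0 = np.floor(ix).astype(np.intp)
        j0 = np.floor(iy).astype(np.intp)
        fx = ix - i0
        fy = iy - j0
        self._parts = []
        for ci in (0, 1):
            wi = np.where(ci == 0, 1 - fx, fx)
            ii = i0 + ci
            for cj in (0, 1):
                wj = np.where(cj == 0, 1 - fy, fy)
                jj = j0 + cj
                w = wi * wj
                valid = (ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny)
                w = np.where(valid, w, 0.0).astype(np.float32)
                self._parts.append(
                    (np.clip(ii, 0, nx - 1), np.clip(jj, 0, ny - 1), w)
                )

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Rotate a 3-D array (content outside the grid reads as 0)."""
        out = None
        for ii, jj, w in self._parts:
            term = values[ii, jj, :] * w[:, :, None]
            out = term if out is None else out + term
        return out


# -- shared beam-frame helpers ----------------------------------------------


def _target_weight_map(targets: Dict[str, Mask], plan: PlanSpec) -> np.ndarray:
    """Per-voxel relative prescription: 1 inside the high-risk CTVs, the
    elective ratio inside CTVe, 0 elsewhere."""
    rel_elective = plan.elective_gy / plan.prescription_gy
    w = None
    for name, mask in targets.items():
        level = rel_elective if name.lower() in ("ctve", "elective") else 1.0
        m = mask.values.astype(np.float32) * level
        w = m if w is None else np.maximum(w, m)
    if w is None:
        raise DoseError("no target masks supplied")
    return w


def _bev_fluence(w_rot: np.ndarray, grid: Grid, smooth: bool = True) -> np.ndarray:
    """Beam's-eye-view fluence for rays along +y: max of the rotated target
    weight along depth, dilated by the lateral margin and smoothed into a
    penumbra."""
    bev = w_rot.max(axis=1)  # (nx, nz)
    margin_vox = (
        max(1, int(round(BEV_MARGIN_MM / grid.spacing[0]))),
        max(1, int(round(BEV_MARGIN_MM / grid.spacing[2]))),
    )
    bev = ndimage.grey_dilation(bev, size=(2 * margin_vox[0] + 1, 2 * margin_vox[1] + 1))
    if smooth:
        bev = ndimage.gaussian_filter(bev, sigma=1.0)
    return bev


def _check_targets_on_grid(ct: Volume, targets: Dict[str, Mask]):
    for name, m in targets.items():
        if not ct.grid.matches(m.grid):
            raise DoseError(f"target {name!r} not on the CT grid")


def _primary_target(targets: Dict[str, Mask]) -> Mask:
    """Normalization structure: the high-risk primary CTV if present, else the
    first mask supplied."""
    for key in ("ctvp68", "ctvp"):
        if key in targets:
            return targets[key]
    return next(iter(targets.values()))


def _normalize(dose: np.ndarray, target: Mask, plan: PlanSpec,
               scale: Optional[float]) -> Tuple[np.ndarray, float]:
    if scale is None:
        med = float(np.median(dose[target.values]))
        if med <= 0:
            raise DoseError("target receives no dose; beams miss the target")
        scale = plan.prescription_gy / med
    return dose * scale, scale


# -- photon arc --------------------------------------------------------------


def photon_dose(
    ct: Volume,
    plan: PlanSpec,
    targets: Dict[str, Mask],
    scale: Optional[float] = None,
    plan_data: Optional[dict] = None,
    return_scale: bool = False,
    return_plan_data: bool = False,
):
    """Photon arc dose: per beam angle, ray-traced exponential attenuation
    exp(-mu_w * WET(depth)) weighted by the beam's-eye target coverage, summed
    over the arc and scaled so the median dose over the normalization target
    equals the prescription.

    When recalculating a plan optimized on another CT, pass the ``scale`` and
    ``plan_data`` returned by the planning call so that the fluence pattern
    and monitor units are frozen and only the medium changes.
    """
    if plan.modality != "photon_arc":
        raise DoseError("photon_dose requires a photon_arc plan")
    if not plan.beam_angles_deg:
        raise DoseError("plan has no beam angles")
    _check_targets_on_grid(ct, targets)
    grid = ct.grid
    rsp = hu_to_rsp(ct.values).astype(np.float32)
    planning = plan_data is None
    if planning:
        wmap = _target_weight_map(targets, plan)
        plan_data = {}
    sy = grid.spacing[1]
    dose = np.zeros(grid.shape, dtype=np.float32)
    for ang in plan.beam_angles_deg:
        fwd = _InplaneRotation(grid, -ang)
        inv = _InplaneRotation(grid, ang)
        rsp_r = fwd.apply(rsp)
        # WET to the voxel center along +y
        cum = np.cumsum(rsp_r, axis=1, dtype=np.float32) * sy
        cum -= 0.5 * sy * rsp_r
        if planning:
            fl = _bev_fluence(fwd.apply(wmap), grid)
            plan_data[ang] = fl
        else:
            fl = plan_data[ang]
        beam = fl[:, None, :] * np.exp(-MU_WATER_PER_MM * cum)
        dose += inv.apply(beam)
    dose, scale = _normalize(dose, _primary_target(targets), plan, scale)
    vol = Volume(grid, dose, unit="Gy")
    out = [vol]
    if return_scale:
        out.append(scale)
    if return_plan_data:
        out.append(plan_data)
    return out[0] if len(out) == 1 else tuple(out)


# -- proton fields ------------------------------------------------------------


def _sobp_profile(w, w_prox, w_dist):
    """SOBP depth dose as a function of cumulative WET ``w`` given per-ray
    proximal/distal WET edges (broadcastable): a gently rising entrance region
    reaching ~70% of the flat top at the proximal ramp, a short ramp, flat top
    across the target interval, and a Gaussian distal falloff."""
    ramp_lo = w_prox - SOBP_PROXIMAL_RAMP_MM
    up = np.clip((w - ramp_lo) / SOBP_PROXIMAL_RAMP_MM, 0.0, 1.0)
    entrance = np.maximum(
        0.35,
        SOBP_ENTRANCE_LEVEL + SOBP_ENTRANCE_SLOPE_PER_MM * np.minimum(w - ramp_lo, 0.0),
    )
    level = entrance + (1.0 - SOBP_ENTRANCE_LEVEL) * up
    distal = np.exp(-0.5 * ((w - w_dist) / SOBP_DISTAL_SIGMA_MM) ** 2)
    return np.where(w <= w_dist, level, distal).astype(np.float32)


def proton_dose(
    ct: Volume,
    plan: PlanSpec,
    targets: Dict[str, Mask],
    scale: Optional[float] = None,
    plan_data: Optional[dict] = None,
    return_scale: bool = False,
    return_plan_data: bool = False,
):
    """Multi-field proton dose: each field covers the beam's-eye view of the
    targets with pencil rays; every ray deposits an SOBP in WET coordinates
    spanning the target's WET extent along that ray (plus a small margin),
    with a Gaussian distal falloff.  Fields are summed and scaled so the
    median dose over the normalization target equals the prescription.

    The per-ray SOBP WET intervals are determined on the CT the plan is
    optimized on.  To recalculate that plan on another CT (the synthetic CT),
    pass the ``scale`` and ``plan_data`` of the planning call: the energy
    selection is then frozen and HU differences shift the Bragg edges in
    geometric depth — the range-sensitivity mechanism protons are known for.
    """
    if plan.modality != "proton_fields":
        raise DoseError("proton_dose requires a proton_fields plan")
    if not plan.beam_angles_deg:
        raise DoseError("plan has no beam angles")
    _check_targets_on_grid(ct, targets)
    grid = ct.grid
    rsp = hu_to_rsp(ct.values).astype(np.float32)
    planning = plan_data is None
    if planning:
        wmap = _target_weight_map(targets, plan)
        any_target = wmap > 0
        plan_data = {}
    sy = grid.spacing[1]
    dose = np.zeros(grid.shape, dtype=np.float32)
    covered = False
    for ang in plan.beam_angles_deg:
        fwd = _InplaneRotation(grid, -ang)
        inv = _InplaneRotation(grid, ang)
        rsp_r = fwd.apply(rsp)
        cum = np.cumsum(rsp_r, axis=1, dtype=np.float32) * sy
        cum -= 0.5 * sy * rsp_r
        if planning:
            t_r = fwd.apply(any_target.astype(np.float32)) > 0.5
            has = t_r.any(axis=1)  # (nx, nz) rays intersecting the target
            if not has.any():
                plan_data[ang] = None
                continue
            jf = np.argmax(t_r, axis=1)
            jl = t_r.shape[1] - 1 - np.argmax(t_r[:, ::-1, :], axis=1)
            ii, kk = np.indices(has.shape)
            w_prox = np.where(has, cum[ii, jf, kk], 0.0) - SOBP_WET_MARGIN_MM
            w_dist = np.where(has, cum[ii, jl, kk], 0.0) + SOBP_WET_MARGIN_MM
            # extend ray edges into the lateral margin
            margin = max(1, int(round(BEV_MARGIN_MM / grid.spacing[0])))
            dist, (inear, knear) = ndimage.distance_transform_edt(
                ~has, return_indices=True
            )
            lateral_ok = dist <= margin + 0.5
            w_prox = w_prox[inear, knear]
            w_dist = w_dist[inear, knear]
            fl = _bev_fluence(fwd.apply(wmap), grid)
            plan_data[ang] = {
                "w_prox": w_prox,
                "w_dist": w_dist,
                "lateral_ok": lateral_ok,
                "fluence": fl,
            }
        field_data = plan_data[ang]
        if field_data is None:
            continue
        covered = True
        beam = _sobp_profile(
            cum,
            field_data["w_prox"][:, None, :],
            field_data["w_dist"][:, None, :],
        )
        beam *= (
            field_data["lateral_ok"][:, None, :] * field_data["fluence"][:, None, :]
        ).astype(np.float32)
        beam = ndimage.gaussian_filter1d(beam, sigma=0.8, axis=0)
        beam = ndimage.gaussian_filter1d(beam, sigma=0.8, axis=2)
        dose += inv.apply(beam)
    if not covered:
        raise DoseError("target outside all beams")
    dose, scale = _normalize(dose, _primary_target(targets), plan, scale)
    vol = Volume(grid, dose, unit="Gy")
    out = [vol]
    if return_scale:
        out.append(scale)
    if return_plan_data:
        out.append(plan_data)
    return out[0] if len(out) == 1 else tuple(out)
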
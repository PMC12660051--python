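"""Synthetic paired-CT head-and-neck phantom generator.

Generates complete evaluation cases with known ground truth: a neck-like
planning CT (elliptic body with shoulders, vertebral column with cord canal,
mandible, trachea and pharyngeal air, parotids, oral cavity, brainstem,
optional contrast vessels and couch), a set of target and organ-at-risk
structures placed anatomically (lateral "tonsil" or midline "base-of-tongue"
primary), a synthetic CT derived from it with tissue-class-dependent HU
errors and a residual rigid misregistration, and photon/proton dose grids
computed on both CTs with identical plans.

The sCT error model applies, per tissue class, a spatially smooth error field
whose scale is calibrated so the realized mean absolute HU error over the
class intersection matches the requested target (soft tissue tens of HU,
bone hundreds of HU), plus a stochastic erosion/dilation of the bone edge
that degrades bone overlap.  Patient repositioning between the CT and MR
sessions is modelled as a rigid offset per case of which a fixed fraction
survives the (imperfect) rigid registration; an optional extra shoulder-region
displacement mimics the posture changes that rigid registration cannot
resolve.

All randomness derives from one integer seed per case through numpy's
``SeedSequence(seed, spawn_key=...)`` splitting, so cohorts are bit
reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .case import CaseRecord
from .dose import PlanSpec, photon_arc_plan, photon_dose, proton_dose, proton_field_plan
from .grid import (
    Grid,
    Mask,
    RigidTransform,
    Volume,
    apply_rigid,
    clamp_hu,
)

__all__ = [
    "PhantomSpec",
    "SCTErrorModel",
    "build_phantom",
    "make_sct",
    "make_case",
    "make_cohort",
    "iter_cohort",
]

HU_AIR = -1000.0
HU_SOFT = 40.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic patient (lengths in mm, HU for intensities)."""

    grid_shape: Tuple[int, int, int] = (128, 128, 80)
    spacing_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    body_semiaxes: Tuple[float, float] = (68.0, 82.0)
    shoulder_extra: Tuple[float, float] = (42.0, 10.0)
    shoulder_z: float = -35.0
    tumor_site: str = "tonsil"  # or "base_of_tongue"
    side: int = 1  # +1 patient left, -1 patient right
    bilateral: bool = True
    texture_std_hu: float = 12.0
    texture_corr_mm: float = 8.0
    include_contrast: bool = True
    include_table: bool = True
    anatomy_scale: float = 1.0
    texture_seed: int = 0

    def grid(self) -> Grid:
        return Grid.centered(self.grid_shape, self.spacing_mm)


@dataclass(frozen=True)
class SCTErrorModel:
    """Per-class HU error scales and positioning-offset statistics.

    ``mae_targets_hu`` are the calibration targets for the realized mean
    absolute HU error over each tissue-class intersection.  The rigid offset
    drawn per case models repositioning between CT and MR; only
    ``residual_fraction`` of it survives registration.
    """

    mae_targets_hu: Dict[str, float] = field(
        default_factory=lambda: {"soft_tissue": 43.0, "bone": 298.0, "air": 118.0}
    )
    bone_edge_amplitude: float = 0.35
    error_corr_mm: float = 8.0
    class_bias_fraction: Dict[str, float] = field(
        default_factory=lambda: {"soft_tissue": 0.0, "bone": -0.6, "air": 0.5}
    )
    offset_translation_sd_mm: float = 3.5
    offset_rotation_sd_deg: float = 1.5
    residual_fraction: float = 0.3
    shoulder_deformation: bool = True
    shoulder_shift_sd_mm: float = 6.0
    calibration_iterations: int = 3

    @property
    def is_zero(self) -> bool:
        return (
            all(v == 0 for v in self.mae_targets_hu.values())
            and self.bone_edge_amplitude == 0
        )


def _smooth_field(shape, rng: np.random.Generator, sigma_vox: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length sigma."""
    f = ndimage.gaussian_filter(
        rng.standard_normal(shape).astype(np.float32), sigma=sigma_vox
    )
    sd = float(f.std())
    return f / sd if sd > 0 else f


def _ellipsoid(X, Y, Z, center, semi) -> np.ndarray:
    return (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _tube(X, Y, Z, center_xy, radius, z_lo=-np.inf, z_hi=np.inf) -> np.ndarray:
    return (
        ((X - center_xy[0]) ** 2 + (Y - center_xy[1]) ** 2) <= radius**2
    ) & (Z >= z_lo) & (Z <= z_hi)


def build_phantom(spec: PhantomSpec):
    """Construct the planning CT and all masks for one synthetic patient.

    Returns ``(ct, structures, aux)`` where ``ct`` is the anatomy CT (without
    contrast or couch — those live in ``aux`` and are composed into the pCT by
    :func:`make_case`), ``structures`` the delineated targets/OARs, and
    ``aux`` extra masks (``contrast``, ``table``, ``body``).
    """
    grid = spec.grid()
    s = spec.anatomy_scale
    x = grid.axis_coordinates(0)
    y = grid.axis_coordinates(1)
    z = grid.axis_coordinates(2)
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    shoulder_w = 1.0 / (1.0 + np.exp(-((spec.shoulder_z - Z) / 12.0)))
    ax = (spec.body_semiaxes[0] + spec.shoulder_extra[0] * shoulder_w) * s
    ay = (spec.body_semiaxes[1] + spec.shoulder_extra[1] * shoulder_w) * s
    body = ((X / ax) ** 2 + (Y / ay) ** 2) <= 1.0

    rng_tex = np.random.default_rng(
        np.random.SeedSequence(spec.texture_seed, spawn_key=(0xA11,))
    )
    texture = _smooth_field(
        grid.shape, rng_tex, spec.texture_corr_mm / np.mean(spec.spacing_mm)
    )
    texture = np.clip(texture * spec.texture_std_hu, -30.0, 30.0)

    hu = np.full(grid.shape, HU_AIR, dtype=np.float32)
    hu[body] = HU_SOFT + texture[body]

    def put(mask, value):
        hu[mask & body] = value

    # skeleton
    spine = _tube(X, Y, Z, (0, 45 * s), 14 * s)
    spine_hu = 950.0 + 150.0 * np.sin(2 * np.pi * Z / 28.0)
    hu[spine & body] = np.broadcast_to(spine_hu, grid.shape)[spine & body]
    canal = _tube(X, Y, Z, (0, 45 * s), 5 * s)
    put(canal, 40.0)
    mandible = (
        _ellipsoid(X, Y, Z, (34 * s, -40 * s, 50), (8, 12, 15))
        | _ellipsoid(X, Y, Z, (-34 * s, -40 * s, 50), (8, 12, 15))
        | _ellipsoid(X, Y, Z, (0, -62 * s, 45), (16, 9, 8))
    )
    put(mandible, 1200.0)
    shoulders = _ellipsoid(X, Y, Z, (78 * s, 5, -62), (20, 13, 11)) | _ellipsoid(
        X, Y, Z, (-78 * s, 5, -62), (20, 13, 11)
    )
    put(shoulders, 850.0)

    # airways
    # closed inferiorly so the airway is a true internal cavity of the body
    trachea = _tube(X, Y, Z, (0, -38 * s), 9 * s, z_lo=-60, z_hi=25)
    put(trachea, -900.0)
    lumen = _tube(X, Y, Z, (0, -38 * s), 5 * s, z_lo=25, z_hi=55)
    put(lumen, -900.0)
    oral = _ellipsoid(X, Y, Z, (0, -52 * s, 52), (26, 20, 16))
    put(oral, 30.0)
    oral_air = _ellipsoid(X, Y, Z, (0, -52 * s, 52), (13, 9, 6))
    put(oral_air, -750.0)

    # structures
    side = spec.side
    if spec.tumor_site == "tonsil":
        ctvp = _ellipsoid(X, Y, Z, (side * 34 * s, -18 * s, 36), (15, 13, 17))
    elif spec.tumor_site == "base_of_tongue":
        ctvp = _ellipsoid(X, Y, Z, (0, -34 * s, 40), (17, 14, 14))
    else:
        raise ValueError(f"unknown tumor site {spec.tumor_site!r}")
    ctvn = _ellipsoid(X, Y, Z, (side * 44 * s, 8 * s, 2), (11, 13, 24))
    ctve = ndimage.binary_dilation(ctvn, iterations=int(round(8 / spec.spacing_mm[0])))
    # elective nodal chain continues into the low neck / supraclavicular
    # region, so the beams traverse the shoulder slices as in clinical plans
    ctve |= _ellipsoid(X, Y, Z, (side * 42 * s, 5 * s, -38), (12, 13, 30))
    if spec.bilateral:
        ctve |= _ellipsoid(X, Y, Z, (-side * 44 * s, 8 * s, 2), (9, 11, 20))
        ctve |= _ellipsoid(X, Y, Z, (-side * 42 * s, 5 * s, -38), (10, 12, 26))
    ctve |= ctvn

    structures = {
        "ctvp68": ctvp,
        "ctvn68": ctvn,
        "ctve": ctve,
        "spinal_cord": _tube(X, Y, Z, (0, 45 * s), 3 * s),
        "brainstem": _tube(X, Y, Z, (0, 28 * s), 8 * s, z_lo=58),
        "parotid_l": _ellipsoid(X, Y, Z, (48 * s, 0, 48), (11, 15, 13)),
        "parotid_r": _ellipsoid(X, Y, Z, (-48 * s, 0, 48), (11, 15, 13)),
        "oesophagus": _tube(X, Y, Z, (0, 16 * s), 5.5, z_hi=30),
        "oral_cavity": oral,
        "larynx": _tube(X, Y, Z, (0, -38 * s), 16 * s, z_lo=18, z_hi=48),
    }
    structures = {
        name: Mask(grid, m & body) for name, m in structures.items()
    }

    aux: Dict[str, Mask] = {"body": Mask(grid, body)}
    contrast = (
        _tube(X, Y, Z, (30 * s, 28 * s), 3.5) | _tube(X, Y, Z, (-30 * s, 28 * s), 3.5)
    ) & body
    aux["contrast"] = Mask(grid, contrast if spec.include_contrast else np.zeros(grid.shape, bool))
    table = (np.abs(X) <= 110) & (Y >= 92) & (Y <= 104) & ~body
    aux["table"] = Mask(grid, table if spec.include_table else np.zeros(grid.shape, bool))

    ct = Volume(grid, clamp_hu(hu).astype(np.float32), unit="HU")
    return ct, structures, aux


def _threshold_classes(values: np.ndarray, body: np.ndarray):
    soft = body & (values >= -250) & (values <= 250)
    bone = body & (values > 250)
    air = body & (values < -250)
    return {"soft_tissue": soft, "bone": bone, "air": air}


def make_sct(
    ct: Volume,
    body: Mask,
    err: SCTErrorModel,
    residual: RigidTransform,
    rng: np.random.Generator,
    extra_shoulder_mm: float = 0.0,
    shoulder_z: float = -35.0,
) -> Volume:
    """Synthesize the registered sCT from the anatomy CT.

    Tissue-class error fields are self-calibrated: after applying the residual
    transform, the per-class intersection MAE is measured and the field scales
    are adjusted (a couple of fixed-point iterations) toward the requested
    targets, because class-membership changes and resampling otherwise bias
    the realized error away from the nominal scale.
    """
    grid = ct.grid
    base = ct.values.astype(np.float32).copy()
    sigma_vox = err.error_corr_mm / float(np.mean(grid.spacing))
    classes0 = _threshold_classes(base, body.values)

    if err.bone_edge_amplitude > 0:
        ind = ndimage.gaussian_filter(
            classes0["bone"].astype(np.float32), sigma=1.2
        )
        wobble = _smooth_field(grid.shape, rng, 10.0 / np.mean(grid.spacing))
        # band-limit the wobble to the bone boundary so the perturbation is a
        # local erosion/dilation of the edge, not free-floating bone islands
        band = 4.0 * ind * (1.0 - ind)
        region = (ind + err.bone_edge_amplitude * wobble * band) > 0.5
        added = region & ~classes0["bone"] & body.values
        removed = classes0["bone"] & ~region
        base[added] = 420.0
        base[removed] = 50.0
        classes0 = _threshold_classes(base, body.values)

    fields = {}
    scales = {}
    for name, target in err.mae_targets_hu.items():
        if target <= 0:
            continue
        g = _smooth_field(grid.shape, rng, sigma_vox)
        bias = err.class_bias_fraction.get(name, 0.0)
        raw = bias + g
        sel = classes0[name]
        denom = float(np.mean(np.abs(raw[sel]))) if sel.any() else 1.0
        fields[name] = raw
        scales[name] = target / max(denom, 1e-6)

    def _compose(scales_now):
        out = base.copy()
        for name, f in fields.items():
            sel = classes0[name]
            out[sel] += scales_now[name] * f[sel]
        return out

    def _transform(values):
        v = Volume(grid, values, unit="HU")
        moved = apply_rigid(v, residual, order=3)
        if extra_shoulder_mm != 0.0:
            extra = RigidTransform(
                residual.rotation_deg,
                (
                    residual.translation_mm[0] + extra_shoulder_mm,
                    residual.translation_mm[1],
                    residual.translation_mm[2],
                ),
            )
            moved_sh = apply_rigid(v, extra, order=3)
            zc = grid.axis_coordinates(2)
            w = 1.0 / (1.0 + np.exp(-((shoulder_z - zc) / 10.0)))
            moved.values = (
                moved.values * (1.0 - w)[None, None, :]
                + moved_sh.values * w[None, None, :]
            )
        return moved

    if not fields:
        sct = _transform(base)
        sct.values = clamp_hu(sct.values).astype(np.float32)
        return sct

    body_s = apply_rigid(Volume(grid, body.values.astype(np.float32), "1"), residual, order=0)
    body_s_mask = body_s.values > 0.5

    sct = None
    for _ in range(max(1, err.calibration_iterations)):
        sct = _transform(_compose(scales))
        cls_s = _threshold_classes(sct.values, body_s_mask)
        for name in fields:
            inter = classes0[name] & cls_s[name]
            if inter.sum() < 100:
                continue
            measured = float(np.mean(np.abs(ct.values[inter] - sct.values[inter])))
            if measured > 0:
                ratio = err.mae_targets_hu[name] / measured
                scales[name] *= float(np.clip(ratio, 0.5, 2.0))
    sct = _transform(_compose(scales))
    sct.values = clamp_hu(sct.values).astype(np.float32)
    return sct


def _draw_offset(err: SCTErrorModel, rng: np.random.Generator) -> RigidTransform:
    t = rng.normal(0.0, err.offset_translation_sd_mm, size=3)
    r = rng.normal(0.0, err.offset_rotation_sd_deg, size=3) * np.array([1.0, 0.5, 0.5])
    if err.offset_translation_sd_mm == 0 and err.offset_rotation_sd_deg == 0:
        return RigidTransform()
    return RigidTransform(tuple(r), tuple(t))


def make_case(
    spec: PhantomSpec,
    err: SCTErrorModel,
    seed: int = 0,
    case_id: str = "case000",
    n_photon_beams: int = 72,
    compute_doses: bool = True,
) -> CaseRecord:
    """Generate one complete case: pCT, registered sCT with known residual
    misalignment, structures, and photon/proton doses computed on both CTs
    with the plan scaled on the pCT (recalculation, no re-optimization)."""
    ss = np.random.SeedSequence(seed, spawn_key=(1,))
    rng = np.random.default_rng(ss)
    spec = replace(spec, texture_seed=seed)
    ct0, structures, aux = build_phantom(spec)
    grid = ct0.grid

    offset = _draw_offset(err, rng)
    residual = offset.scaled(err.residual_fraction)
    extra = (
        float(rng.normal(0.0, err.shoulder_shift_sd_mm))
        if err.shoulder_deformation
        else 0.0
    )
    sct = make_sct(ct0, aux["body"], err, residual, rng,
                   extra_shoulder_mm=extra, shoulder_z=spec.shoulder_z)

    pct = ct0.copy()
    if aux["contrast"].n_true:
        pct.values[aux["contrast"].values] += 200.0
    if aux["table"].n_true:
        pct.values[aux["table"].values] = 120.0
    pct.values = clamp_hu(pct.values).astype(np.float32)

    plans = {
        "photon": photon_arc_plan(n_photon_beams),
        "proton": proton_field_plan(bilateral=spec.bilateral),
    }
    targets = {k: structures[k] for k in ("ctvp68", "ctvn68", "ctve")}
    if compute_doses:
        # plans are optimized on the pCT; the sCT dose is a recalculation with
        # frozen fluence/energy selection and monitor units
        d_ph_p, s_ph, pd_ph = photon_dose(
            ct0, plans["photon"], targets, return_scale=True, return_plan_data=True
        )
        d_ph_s = photon_dose(sct, plans["photon"], targets, scale=s_ph, plan_data=pd_ph)
        d_pr_p, s_pr, pd_pr = proton_dose(
            ct0, plans["proton"], targets, return_scale=True, return_plan_data=True
        )
        d_pr_s = proton_dose(sct, plans["proton"], targets, scale=s_pr, plan_data=pd_pr)
    else:
        zero = Volume(grid, np.zeros(grid.shape, np.float32), "Gy")
        d_ph_p = d_ph_s = d_pr_p = d_pr_s = zero

    return CaseRecord(
        case_id=case_id,
        pct=pct,
        sct=sct,
        structures=structures,
        applied_offset=offset,
        residual_offset=residual,
        plans=plans,
        dose_photon_pct=d_ph_p,
        dose_photon_sct=d_ph_s,
        dose_proton_pct=d_pr_p,
        dose_proton_sct=d_pr_s,
        prescription_gy=plans["photon"].prescription_gy,
        contrast_mask=aux["contrast"],
        table_mask=aux["table"],
        ground_truth={
            "offset": offset,
            "residual": residual,
            "extra_shoulder_mm": extra,
            "mae_targets_hu": dict(err.mae_targets_hu),
            "tumor_site": spec.tumor_site,
            "bilateral": spec.bilateral,
        },
    )


def _cohort_specs(
    n_cases: int,
    base_spec: PhantomSpec,
    seed: int,
    base_of_tongue_fraction: float = 0.35,
    bilateral_fraction: float = 0.9,
) -> List[Tuple[PhantomSpec, int, str]]:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    out = []
    for i in range(n_cases):
        site = (
            "base_of_tongue"
            if rng.random() < base_of_tongue_fraction
            else "tonsil"
        )
        spec_i = replace(
            base_spec,
            tumor_site=site,
            side=int(rng.choice([-1, 1])),
            bilateral=bool(rng.random() < bilateral_fraction),
            anatomy_scale=float(np.clip(rng.normal(1.0, 0.04), 0.88, 1.12)),
        )
        case_seed = int(rng.integers(0, 2**31 - 1))
        out.append((spec_i, case_seed, f"case{i:03d}"))
    return out


def iter_cohort(
    n_cases: int,
    base_spec: PhantomSpec,
    err: SCTErrorModel,
    seed: int = 0,
    n_photon_beams: int = 72,
    compute_doses: bool = True,
) -> Iterator[CaseRecord]:
    """Generate cohort cases one at a time (memory-friendly)."""
    for spec_i, case_seed, cid in _cohort_specs(n_cases, base_spec, seed):
        yield make_case(
            spec_i, err, seed=case_seed, case_id=cid,
            n_photon_beams=n_photon_beams, compute_doses=compute_doses,
        )


def make_cohort(
    n_cases: int,
    base_spec: Optional[PhantomSpec] = None,
    err: Optional[SCTErrorModel] = None,
    seed: int = 0,
    **kwargs,
) -> List[CaseRecord]:
    """Materialize a cohort of independent seeded cases (see
    :func:`iter_cohort` for the streaming variant used by the pipeline)."""
    if n_cases < 2:
        raise ValueError("a cohort needs at least 2 cases")
    base_spec = base_spec if base_spec is not None else PhantomSpec()
    err = err if err is not None else SCTErrorModel()
    return list(iter_cohort(n_cases, base_spec, err, seed=seed, **kwargs))
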
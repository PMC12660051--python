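"""HU-to-stopping-power mapping, WET ray tracing and dose surrogates."""

import numpy as np
import pytest

from sctdoseval.dose import (
    DoseError,
    PlanSpec,
    hu_to_rsp,
    photon_arc_plan,
    photon_dose,
    proton_dose,
    proton_field_plan,
    wet_along_ray,
)
from sctdoseval.grid import Grid, Mask, Volume


def water_phantom(shape=(60, 60, 20), spacing=1.0, hu=0.0):
    g = Grid.centered(shape, (spacing,) * 3)
    return Volume(g, np.full(shape, float(hu), dtype=np.float32), "HU")


def distal_50_depth(dose_profile, xs, plateau):
    """Depth where the profile last crosses 50% of the plateau, linearly
    interpolated between samples."""
    half = 0.5 * plateau
    above = dose_profile >= half
    i = np.nonzero(above)[0][-1]
    if i == len(xs) - 1:
        return xs[-1]
    f = (dose_profile[i] - half) / (dose_profile[i] - dose_profile[i + 1])
    return xs[i] + f * (xs[i + 1] - xs[i])


class TestHuToRsp:
    def test_fixed_points(self):
        assert hu_to_rsp(0.0) == pytest.approx(1.0)
        assert hu_to_rsp(-1000.0) == pytest.approx(0.0)
        assert hu_to_rsp(700.0) == pytest.approx(1.4)

    def test_monotone_nondecreasing(self):
        hu = np.linspace(-1100, 3000, 2001)
        rsp = hu_to_rsp(hu)
        assert np.all(np.diff(rsp) >= 0)
        assert np.all(rsp >= 0)


class TestWetAlongRay:
    def test_uniform_water_gives_geometric_depth(self):
        ct = water_phantom()
        wet = wet_along_ray(ct, (-25.0, 0.0, 0.0), (1, 0, 0), 50.0)
        assert wet == pytest.approx(50.0, abs=1e-9)

    def test_bone_slab_adds_excess_wet(self):
        ct = water_phantom()
        x = ct.grid.axis_coordinates(0)
        slab = (x >= -5.0) & (x < 5.0)  # 10 mm slab
        ct.values[slab, :, :] = 700.0  # RSP 1.4
        wet = wet_along_ray(ct, (-25.0, 0.0, 0.0), (1, 0, 0), 50.0)
        assert wet == pytest.approx(54.0, abs=0.05)

    def test_additive_in_depth(self):
        ct = water_phantom()
        ct.values += np.linspace(0, 80, 20)[None, None, :]  # mild gradient
        o = np.array([-25.0, -3.0, -2.0])
        d = np.array([3.0, 1.0, 0.5])
        d /= np.linalg.norm(d)
        a, b = 17.3, 41.9
        w_total = wet_along_ray(ct, o, d, b)
        w_split = wet_along_ray(ct, o, d, a) + wet_along_ray(ct, o + a * d, d, b - a)
        assert w_split == pytest.approx(w_total, abs=1e-9)

    def test_plus_100_hu_slab_adds_one_mm(self):
        ct = water_phantom()
        x = ct.grid.axis_coordinates(0)
        slab = (x >= -5.0) & (x < 5.0)
        ct_pert = Volume(ct.grid, ct.values.copy(), "HU")
        ct_pert.values[slab, :, :] += 100.0  # stays in the linear ramp
        w0 = wet_along_ray(ct, (-25.0, 0.0, 0.0), (1, 0, 0), 50.0)
        w1 = wet_along_ray(ct_pert, (-25.0, 0.0, 0.0), (1, 0, 0), 50.0)
        assert w1 - w0 == pytest.approx(1.0, abs=1e-6)

    def test_ray_missing_grid_is_zero(self):
        ct = water_phantom()
        assert wet_along_ray(ct, (1000.0, 1000.0, 0.0), (0, 1, 0), 30.0) == 0.0


def _single_field_setup(spacing=1.0, extra_hu=None):
    """Water cylinder with a mid-depth target and one anterior field."""
    g = Grid.centered((80, 80, 24), (spacing,) * 3)
    vals = np.full(g.shape, 0.0, dtype=np.float32)
    if extra_hu is not None:
        extra_hu(g, vals)
    ct = Volume(g, vals, "HU")
    y = g.axis_coordinates(1)
    x = g.axis_coordinates(0)
    z = g.axis_coordinates(2)
    target = (
        (np.abs(x)[:, None, None] <= 8)
        & (np.abs(y - 8)[None, :, None] <= 8)
        & (np.abs(z)[None, None, :] <= 6)
    )
    targets = {"ctvp68": Mask(g, np.broadcast_to(target, g.shape).copy())}
    plan = PlanSpec("proton_fields", 68.0, 34, 50.0, (0.0,))
    return ct, targets, plan


class TestProtonDose:
    def test_normalization_contract(self):
        ct, targets, plan = _single_field_setup()
        dose = proton_dose(ct, plan, targets)
        med = np.median(dose.values[targets["ctvp68"].values])
        assert med == pytest.approx(68.0, abs=0.01)

    def test_peak_inside_target_and_distal_falloff(self):
        ct, targets, plan = _single_field_setup()
        dose = proton_dose(ct, plan, targets)
        g = ct.grid
        iy = np.arange(g.shape[1])
        profile = dose.values[40, :, 12]
        y = g.axis_coordinates(1)
        peak_y = y[profile.argmax()]
        assert -2 <= peak_y <= 18  # inside the target depth interval
        # dose falls below 10% of the plateau within 3 sigma past the edge
        plateau = np.median(profile[(y > 2) & (y < 14)])
        beyond = profile[y > 16 + 3 * 3.0 + 2.0]
        assert beyond.max() < 0.1 * plateau

    def test_upstream_bone_slab_shifts_distal_edge_by_its_wet(self):
        def add_slab(g, vals):
            y = g.axis_coordinates(1)
            slab = (y >= -30) & (y < -20)
            vals[:, slab, :] += 300.0

        ct0, targets, plan = _single_field_setup()
        ct1, _, _ = _single_field_setup(extra_hu=add_slab)
        d0, s0, pd0 = proton_dose(ct0, plan, targets, return_scale=True,
                                  return_plan_data=True)
        # recalculate the same plan on the perturbed CT
        d1 = proton_dose(ct1, plan, targets, scale=s0, plan_data=pd0)
        y = ct0.grid.axis_coordinates(1)
        p0 = d0.values[40, :, 12]
        p1 = d1.values[40, :, 12]
        plateau = np.median(p0[(y > 2) & (y < 14)])
        shift = distal_50_depth(p0, y, plateau) - distal_50_depth(p1, y, plateau)
        # slab: 10 mm x 300 HU above water in the hu<=100... piecewise ramp
        from sctdoseval.dose import hu_to_rsp
        expected = 10.0 * (hu_to_rsp(300.0) - 1.0)
        assert shift == pytest.approx(expected, abs=0.5)

    def test_target_outside_beam_raises(self):
        ct, targets, plan = _single_field_setup()
        g = ct.grid
        far = np.zeros(g.shape, bool)
        far[0:2, 0:2, 0:2] = True
        # a target that no ray of the (empty-angle) plan can reach
        empty_plan = PlanSpec("proton_fields", 68.0, 34, 50.0, ())
        with pytest.raises(DoseError):
            proton_dose(ct, empty_plan, {"ctvp68": Mask(g, far)})


class TestPhotonDose:
    def test_arc_maximum_near_rotation_center(self):
        g = Grid.centered((41, 41, 17), (2.0, 2.0, 2.0))  # odd: voxel at center
        ct = Volume(g, np.zeros(g.shape, dtype=np.float32), "HU")
        x = g.axis_coordinates(0)
        target = (
            (np.abs(x)[:, None, None] <= 6)
            & (np.abs(x)[None, :, None] <= 6)
            & (np.abs(g.axis_coordinates(2))[None, None, :] <= 4)
        )
        targets = {"ctvp68": Mask(g, np.broadcast_to(target, g.shape).copy())}
        dose = photon_dose(ct, photon_arc_plan(36), targets)
        # the symmetric attenuation sum peaks at the rotation center (flat to
        # ripple level inside the target, so compare values, not argmax)
        assert dose.values[20, 20, 8] >= 0.999 * dose.values.max()

    def test_normalization_contract(self):
        g = Grid.centered((40, 40, 16), (2.0, 2.0, 2.0))
        ct = Volume(g, np.zeros(g.shape, dtype=np.float32), "HU")
        m = np.zeros(g.shape, bool)
        m[15:25, 15:25, 6:10] = True
        targets = {"ctvp68": Mask(g, m)}
        dose = photon_dose(ct, photon_arc_plan(24), targets)
        assert np.median(dose.values[m]) == pytest.approx(68.0, abs=0.01)

    def test_photons_less_hu_sensitive_than_protons_at_distal_edge(self):
        # +50 HU everywhere: photon dose shifts by a few tenths of a percent,
        # the proton distal edge region changes by many percent
        ct, targets, plan_pr = _single_field_setup(spacing=1.0)
        ct_hi = Volume(ct.grid, ct.values + 50.0, "HU")
        d_pr, s_pr, pd_pr = proton_dose(ct, plan_pr, targets, return_scale=True,
                                        return_plan_data=True)
        d_pr_hi = proton_dose(ct_hi, plan_pr, targets, scale=s_pr, plan_data=pd_pr)
        plan_ph = PlanSpec("photon_arc", 68.0, 34, 50.0, (0.0,))
        d_ph, s_ph, pd_ph = photon_dose(ct, plan_ph, targets, return_scale=True,
                                        return_plan_data=True)
        d_ph_hi = photon_dose(ct_hi, plan_ph, targets, scale=s_ph, plan_data=pd_ph)
        y = ct.grid.axis_coordinates(1)
        distal = (y > 14) & (y < 22)
        ph_change = np.abs(d_ph.values[40, distal, 12] - d_ph_hi.values[40, distal, 12]).max()
        pr_change = np.abs(d_pr.values[40, distal, 12] - d_pr_hi.values[40, distal, 12]).max()
        assert ph_change < pr_change

    def test_wrong_modality_rejected(self):
        g = Grid.centered((8, 8, 8), (2, 2, 2))
        ct = Volume(g, np.zeros(g.shape), "HU")
        with pytest.raises(DoseError):
            photon_dose(ct, proton_field_plan(), {"t": Mask(g, np.ones(g.shape, bool))})

    def test_beam_angle_validation(self):
        with pytest.raises(DoseError):
            PlanSpec("photon_arc", 68.0, 34, 50.0, (0.0, 400.0))
        with pytest.raises(DoseError):
            PlanSpec("photon_arc", -1.0, 34, 50.0, (0.0,))
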
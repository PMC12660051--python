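"""Synthetic phantom generator: geometry invariants, determinism, error
model calibration mechanics and misalignment construction."""

import numpy as np
import pytest

from sctdoseval.agreement import surface_distances
from sctdoseval.grid import RigidTransform
from sctdoseval.phantom import (
    PhantomSpec,
    SCTErrorModel,
    build_phantom,
    iter_cohort,
    make_case,
    make_cohort,
    make_sct,
)
from sctdoseval.segmentation import segment_body

SMALL = PhantomSpec(grid_shape=(64, 64, 40), spacing_mm=(4.0, 4.0, 4.0))

ZERO_ERROR = SCTErrorModel(
    mae_targets_hu={"soft_tissue": 0.0, "bone": 0.0, "air": 0.0},
    bone_edge_amplitude=0.0,
    offset_translation_sd_mm=0.0,
    offset_rotation_sd_deg=0.0,
    shoulder_deformation=False,
)


class TestGeometry:
    def test_structures_inside_body_and_nesting(self):
        ct, structures, aux = build_phantom(SMALL)
        body = aux["body"].values
        for name, m in structures.items():
            assert m.n_true > 0, name
            assert not (m.values & ~body).any(), f"{name} leaks outside the body"
        # elective volume contains the nodal target; cord inside canal column
        assert not (
            structures["ctvn68"].values & ~structures["ctve"].values
        ).any()

    def test_tumor_sites_differ(self):
        ct_t, s_t, _ = build_phantom(SMALL)
        ct_b, s_b, _ = build_phantom(
            PhantomSpec(grid_shape=(64, 64, 40), spacing_mm=(4, 4, 4),
                        tumor_site="base_of_tongue")
        )
        assert not np.array_equal(s_t["ctvp68"].values, s_b["ctvp68"].values)

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError):
            build_phantom(
                PhantomSpec(grid_shape=(32, 32, 16), spacing_mm=(4, 4, 4),
                            tumor_site="nasopharynx")
            )

    def test_hu_range_clamped(self):
        ct, _, _ = build_phantom(SMALL)
        assert ct.values.min() >= -1024.0
        assert ct.values.max() <= 3071.0


class TestZeroError:
    def test_zero_error_model_reproduces_planning_ct_bit_exactly(self):
        spec = PhantomSpec(
            grid_shape=(64, 64, 40), spacing_mm=(4, 4, 4),
            include_contrast=False, include_table=False,
        )
        case = make_case(spec, ZERO_ERROR, seed=3, compute_doses=False)
        assert np.array_equal(case.sct.values, case.pct.values)
        assert case.residual_offset.is_identity


class TestDeterminism:
    def test_same_seed_same_case(self):
        a = make_case(SMALL, SCTErrorModel(), seed=9, compute_doses=False)
        b = make_case(SMALL, SCTErrorModel(), seed=9, compute_doses=False)
        assert np.array_equal(a.pct.values, b.pct.values)
        assert np.array_equal(a.sct.values, b.sct.values)
        assert a.applied_offset == b.applied_offset

    def test_different_seeds_differ(self):
        a = make_case(SMALL, SCTErrorModel(), seed=9, compute_doses=False)
        b = make_case(SMALL, SCTErrorModel(), seed=10, compute_doses=False)
        assert not np.array_equal(a.sct.values, b.sct.values)

    def test_cohort_reproducible_and_varied(self):
        k1 = make_cohort(3, SMALL, SCTErrorModel(), seed=4, compute_doses=False)
        k2 = make_cohort(3, SMALL, SCTErrorModel(), seed=4, compute_doses=False)
        for a, b in zip(k1, k2):
            assert np.array_equal(a.sct.values, b.sct.values)
        sites = {c.ground_truth["tumor_site"] for c in k1}
        assert len(k1) == 3
        with pytest.raises(ValueError):
            make_cohort(1)


class TestMisalignment:
    def test_residual_fraction_controls_body_assd(self):
        # half of a 6 mm offset survives registration; the body ASSD tracks
        # the 3 mm residual shift (attenuated by surface orientation: flat
        # superior/inferior faces move tangentially) and doubles with it
        spec = PhantomSpec(grid_shape=(96, 96, 40), spacing_mm=(2, 2, 2),
                           include_contrast=False, include_table=False)
        ct, structures, aux = build_phantom(spec)
        err = SCTErrorModel(
            mae_targets_hu={"soft_tissue": 0.0, "bone": 0.0, "air": 0.0},
            bone_edge_amplitude=0.0, residual_fraction=0.5,
            shoulder_deformation=False,
        )
        offset = RigidTransform((0, 0, 0), (6.0, 0.0, 0.0))
        body_p = segment_body(ct)

        def assd_for(residual):
            rng = np.random.default_rng(0)
            sct = make_sct(ct, aux["body"], err, residual, rng)
            return surface_distances(body_p, segment_body(sct))[0]

        assd_3mm = assd_for(offset.scaled(err.residual_fraction))
        assert 0.5 < assd_3mm <= 3.0 + 2.0
        assd_6mm = assd_for(offset)
        assert assd_6mm == pytest.approx(2 * assd_3mm, rel=0.3)

    def test_zero_offset_cohort_perfectly_registered(self):
        err = SCTErrorModel(
            mae_targets_hu={"soft_tissue": 0.0, "bone": 0.0, "air": 0.0},
            bone_edge_amplitude=0.0,
            offset_translation_sd_mm=0.0, offset_rotation_sd_deg=0.0,
            shoulder_deformation=False,
        )
        bare = PhantomSpec(grid_shape=(64, 64, 40), spacing_mm=(4, 4, 4),
                           include_contrast=False, include_table=False)
        for case in iter_cohort(2, bare, err, seed=5, compute_doses=False):
            assert case.residual_offset.is_identity
            assert np.array_equal(
                segment_body(case.sct).values, segment_body(case.pct).values
            )

    def test_median_body_xor_increases_with_offset_sd(self):
        medians = []
        for sd in (0.5, 2.0, 6.0):
            err = SCTErrorModel(
                mae_targets_hu={"soft_tissue": 0.0, "bone": 0.0, "air": 0.0},
                bone_edge_amplitude=0.0,
                offset_translation_sd_mm=sd, offset_rotation_sd_deg=0.0,
                residual_fraction=1.0, shoulder_deformation=False,
            )
            xors = []
            for case in iter_cohort(6, SMALL, err, seed=11, compute_doses=False):
                bp = segment_body(case.pct)
                bs = segment_body(case.sct)
                xors.append(float((bp.values ^ bs.values).sum()))
            medians.append(np.median(xors))
        assert medians[0] < medians[1] < medians[2]


class TestErrorModel:
    def test_calibrated_classwise_mae_near_targets_on_one_case(self):
        # full-resolution calibration check for a single case (the cohort
        # median check lives in the acceptance suite)
        from sctdoseval import segmentation as seg
        from sctdoseval.agreement import mae

        case = make_case(PhantomSpec(), SCTErrorModel(), seed=2,
                         compute_doses=False)
        bp = seg.segment_body(case.pct)
        bs = seg.segment_body(case.sct)
        cp = seg.segment_tissue_classes(case.pct, bp)
        cs = seg.segment_tissue_classes(case.sct, bs)
        targets = {"soft_tissue": 43.0, "bone": 298.0, "air": 118.0}
        for name, target in targets.items():
            region = seg.intersection(getattr(cp, name), getattr(cs, name))
            got = mae(case.pct, case.sct, region)
            assert abs(got - target) / target < 0.2, (name, got)

    def test_ground_truth_recorded(self):
        case = make_case(SMALL, SCTErrorModel(), seed=6, compute_doses=False)
        gt = case.ground_truth
        assert gt["offset"] == case.applied_offset
        assert gt["residual"] == case.residual_offset
        assert gt["mae_targets_hu"]["bone"] == 298.0
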
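"""HU agreement, overlap and surface-distance metrics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from sctdoseval.agreement import (
    AgreementError,
    beam_visible_volume,
    dice,
    difference_map,
    mae,
    misregistration_mask,
    surface_distances,
    surface_points,
)
from sctdoseval.grid import Grid, Mask, Volume

from conftest import cube_mask, hu_volume


def brute_force_surface_distances(a: Mask, b: Mask):
    """All-pairs oracle for ASSD/HD on small masks."""
    sa = surface_points(a)
    sb = surface_points(b)
    d = cdist(sa, sb)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    assd = (d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb))
    hd = max(d_ab.max(), d_ba.max())
    return assd, hd


class TestMAE:
    def test_identical_volumes(self, small_grid, rng):
        v = hu_volume(small_grid, rng.normal(0, 200, small_grid.shape))
        region = cube_mask(small_grid, (0, 0, 0), (8, 8, 8))
        assert mae(v, v, region) == 0.0

    def test_uniform_offset(self, small_grid, rng):
        a = hu_volume(small_grid, rng.normal(0, 200, small_grid.shape))
        b = hu_volume(small_grid, a.values + 50.0)
        region = Mask(small_grid, np.ones(small_grid.shape, bool))
        assert mae(a, b, region) == pytest.approx(50.0)

    def test_three_voxel_arithmetic(self, small_grid):
        a_vals = np.zeros(small_grid.shape)
        b_vals = np.zeros(small_grid.shape)
        a_vals[0, 0, 0], a_vals[1, 0, 0], a_vals[2, 0, 0] = 0, 100, -100
        b_vals[0, 0, 0], b_vals[1, 0, 0], b_vals[2, 0, 0] = 10, 90, -60
        region = np.zeros(small_grid.shape, bool)
        region[0:3, 0, 0] = True
        got = mae(hu_volume(small_grid, a_vals), hu_volume(small_grid, b_vals),
                  Mask(small_grid, region))
        assert got == pytest.approx((10 + 10 + 40) / 3)

    def test_empty_region_raises(self, small_grid):
        v = hu_volume(small_grid, np.zeros(small_grid.shape))
        with pytest.raises(AgreementError):
            mae(v, v, Mask(small_grid, np.zeros(small_grid.shape, bool)))


class TestDifferenceMap:
    def test_antisymmetry_and_mae_consistency(self, small_grid, rng):
        a = hu_volume(small_grid, rng.normal(0, 100, small_grid.shape))
        b = hu_volume(small_grid, rng.normal(0, 100, small_grid.shape))
        d_ab = difference_map(a, b)
        d_ba = difference_map(b, a)
        assert np.array_equal(d_ab.values, -d_ba.values)
        region = cube_mask(small_grid, (2, 2, 2), (12, 12, 6))
        assert np.mean(np.abs(d_ab.values[region.values])) == pytest.approx(
            mae(a, b, region)
        )

    def test_unit_mismatch_rejected(self, small_grid):
        a = Volume(small_grid, np.zeros(small_grid.shape), "HU")
        b = Volume(small_grid, np.zeros(small_grid.shape), "Gy")
        with pytest.raises(AgreementError):
            difference_map(a, b)


class TestDice:
    def test_identical_and_disjoint(self, small_grid):
        a = cube_mask(small_grid, (0, 0, 0), (6, 6, 6))
        b = cube_mask(small_grid, (8, 8, 0), (14, 14, 6))
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_half_overlapping_equal_cubes(self):
        g = Grid((24, 12, 12), (2, 2, 2))
        a = cube_mask(g, (0, 0, 0), (8, 8, 8))
        b = cube_mask(g, (4, 0, 0), (12, 8, 8))
        assert dice(a, b) == pytest.approx(0.5)

    def test_symmetry(self, small_grid, rng):
        a = Mask(small_grid, rng.random(small_grid.shape) < 0.3)
        b = Mask(small_grid, rng.random(small_grid.shape) < 0.3)
        assert dice(a, b) == dice(b, a)

    def test_both_empty_raises(self, small_grid):
        empty = Mask(small_grid, np.zeros(small_grid.shape, bool))
        with pytest.raises(AgreementError):
            dice(empty, empty)


class TestSurfaceDistances:
    def test_identical_masks(self, small_grid):
        m = cube_mask(small_grid, (3, 3, 2), (9, 9, 6))
        assert surface_distances(m, m) == (0.0, 0.0)

    def test_translated_cube_hausdorff(self):
        g = Grid((24, 16, 16), (2, 2, 2))
        a = cube_mask(g, (2, 2, 2), (10, 10, 10))
        b = cube_mask(g, (4, 2, 2), (12, 10, 10))  # 4 mm along x
        assd, hd = surface_distances(a, b)
        assert hd == pytest.approx(4.0)
        oracle_assd, oracle_hd = brute_force_surface_distances(a, b)
        assert assd == pytest.approx(oracle_assd, abs=1e-9)
        assert hd == pytest.approx(oracle_hd, abs=1e-9)

    def test_matches_all_pairs_oracle_on_random_masks(self, rng):
        g = Grid((10, 10, 10), (2.0, 1.5, 3.0))
        for _ in range(5):
            a = np.zeros(g.shape, bool)
            b = np.zeros(g.shape, bool)
            a[tuple(rng.integers(1, 9, (3, 30)))] = True
            b[tuple(rng.integers(1, 9, (3, 30)))] = True
            ma, mb = Mask(g, a), Mask(g, b)
            got = surface_distances(ma, mb)
            expected = brute_force_surface_distances(ma, mb)
            assert got[0] == pytest.approx(expected[0], abs=1e-9)
            assert got[1] == pytest.approx(expected[1], abs=1e-9)

    def test_symmetric_in_arguments(self, rng):
        g = Grid((12, 12, 12), (2, 2, 2))
        a = cube_mask(g, (1, 1, 1), (6, 7, 5))
        b = cube_mask(g, (4, 3, 2), (10, 10, 9))
        assert surface_distances(a, b) == surface_distances(b, a)

    def test_empty_mask_raises(self, small_grid):
        m = cube_mask(small_grid, (0, 0, 0), (4, 4, 4))
        with pytest.raises(AgreementError):
            surface_distances(m, Mask(small_grid, np.zeros(small_grid.shape, bool)))


class TestMisregistration:
    def test_identical_bodies_give_empty_xor(self, small_grid):
        body = cube_mask(small_grid, (2, 2, 2), (12, 12, 6))
        assert misregistration_mask(body, body).n_true == 0

    def test_one_voxel_offset_xor_counts(self):
        g = Grid((60, 60, 10), (2, 2, 2))
        a = cube_mask(g, (2, 2, 2), (52, 52, 8))
        b = cube_mask(g, (3, 2, 2), (53, 52, 8))
        xor = misregistration_mask(a, b)
        # two 50 x 6-voxel faces appear/disappear
        assert xor.n_true == 2 * 50 * 6
        assert xor.n_true == a.n_true + b.n_true - 2 * (a.values & b.values).sum()


class TestBeamVisibleVolume:
    def test_zero_dose(self, small_grid):
        misreg = cube_mask(small_grid, (0, 0, 0), (10, 10, 4))
        dose = Volume(small_grid, np.zeros(small_grid.shape), "Gy")
        assert beam_visible_volume(misreg, dose, 68.0) == 0.0

    def test_fully_covered_equals_xor_volume(self, small_grid):
        misreg = cube_mask(small_grid, (0, 0, 0), (10, 10, 4))
        dose = Volume(small_grid, np.full(small_grid.shape, 30.0), "Gy")
        assert beam_visible_volume(misreg, dose, 68.0) == pytest.approx(
            misreg.volume_cm3
        )

    def test_partial_coverage_arithmetic(self):
        g = Grid((10, 10, 10), (2, 2, 2))
        misreg = cube_mask(g, (0, 0, 0), (10, 10, 10))  # 1000 voxels
        dose_vals = np.zeros(g.shape)
        dose_vals[0:4, :, :] = 10.0  # 400 voxels above 5% of 68 Gy
        dose = Volume(g, dose_vals, "Gy")
        got = beam_visible_volume(misreg, dose, 68.0, visibility_fraction=0.05)
        assert got == pytest.approx(400 * 0.008)

    def test_nonpositive_prescription_rejected(self, small_grid):
        misreg = cube_mask(small_grid, (0, 0, 0), (4, 4, 4))
        dose = Volume(small_grid, np.zeros(small_grid.shape), "Gy")
        with pytest.raises(AgreementError):
            beam_visible_volume(misreg, dose, 0.0)
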
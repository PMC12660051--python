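import numpy as np
import pytest

from sctdoseval.grid import Grid, Mask, Volume


@pytest.fixture
def small_grid():
    """16x16x8 lattice at 2 mm, world origin at the lattice center."""
    return Grid.centered((16, 16, 8), (2.0, 2.0, 2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def cube_mask(grid: Grid, lo, hi) -> Mask:
    """Axis-aligned index-range cube [lo, hi) on a grid."""
    v = np.zeros(grid.shape, dtype=bool)
    v[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return Mask(grid, v)


def hu_volume(grid: Grid, values) -> Volume:
    return Volume(grid, np.asarray(values, dtype=float), unit="HU")
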
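"""HU accuracy and spatial-structural agreement between paired CT volumes.

Implements the image-level comparison of a synthetic CT against the planning
CT: mean absolute HU error and difference maps over structure regions, Dice
overlap, surface distances (maximum Hausdorff distance and average symmetric
surface distance), the body-contour misregistration (XOR) volume and its
beam-visible restriction.

Surfaces are defined as the centers of boundary voxels (voxels in the mask
with at least one face-neighbour outside it); distances are Euclidean in mm
between these point sets.  This voxel-center surface is bit-reproducible but
can differ from marching-cubes-based tools at the sub-voxel level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import Mask, Volume, require_same_grid

__all__ = [
    "mae",
    "difference_map",
    "dice",
    "surface_distances",
    "surface_points",
    "misregistration_mask",
    "beam_visible_volume",
    "AgreementError",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class AgreementError(ValueError):
    pass


def mae(a: Volume, b: Volume, region: Mask) -> float:
    """Mean absolute difference between two volumes over a region (HU)."""
    require_same_grid(a, b, region)
    if region.n_true == 0:
        raise AgreementError("MAE region is empty")
    sel = region.values
    return float(np.mean(np.abs(a.values[sel] - b.values[sel])))


def difference_map(a: Volume, b: Volume) -> Volume:
    """Voxelwise difference a - b (unit preserved)."""
    require_same_grid(a, b)
    if a.unit != b.unit:
        raise AgreementError(f"unit mismatch: {a.unit} vs {b.unit}")
    return Volume(a.grid, a.values - b.values, a.unit)


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap coefficient 2|a n b| / (|a| + |b|)."""
    require_same_grid(a, b)
    na, nb = a.n_true, b.n_true
    if na + nb == 0:
        raise AgreementError("Dice undefined: both masks empty")
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


def surface_points(m: Mask) -> np.ndarray:
    """World coordinates (mm) of boundary voxel centers.

    A voxel is on the boundary if it belongs to the mask and has at least one
    face-neighbour outside it (voxels at the array edge count as boundary).
    """
    v = m.values
    interior = ndimage.binary_erosion(v, structure=_FACE_STRUCT, border_value=0)
    boundary = v & ~interior
    idx = np.argwhere(boundary)
    return m.grid.index_to_world(idx)


def surface_distances(a: Mask, b: Mask) -> Tuple[float, float]:
    """(ASSD, HD) in mm between the surfaces of two masks.

    ASSD averages the directed nearest-neighbour distances pooled over both
    surfaces; HD is the exact maximum (100th percentile) of the two directed
    maxima.
    """
    require_same_grid(a, b)
    if a.n_true == 0 or b.n_true == 0:
        raise AgreementError("surface distances undefined for an empty mask")
    sa = surface_points(a)
    sb = surface_points(b)
    d_ab = cKDTree(sb).query(sa, workers=-1)[0]
    d_ba = cKDTree(sa).query(sb, workers=-1)[0]
    assd = float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))
    hd = float(max(d_ab.max(), d_ba.max()))
    return assd, hd


def misregistration_mask(body_pct: Mask, body_sct: Mask) -> Mask:
    """Voxels covered by exactly one of the two body contours (XOR)."""
    require_same_grid(body_pct, body_sct)
    return Mask(body_pct.grid, body_pct.values ^ body_sct.values)


def beam_visible_volume(
    misreg: Mask,
    dose: Volume,
    prescription_gy: float,
    visibility_fraction: float = 0.05,
) -> float:
    """Volume (cm^3) of the misregistration region lying inside the beam
    footprint of a plan.

    "Where the beams passed through" is approximated by the dose footprint:
    voxels receiving at least ``visibility_fraction`` of the prescription.
    Computed separately with the photon and the proton dose this yields
    V_photon and V_proton.
    """
    require_same_grid(misreg, dose)
    if prescription_gy <= 0:
        raise AgreementError("prescription must be positive")
    visible = misreg.values & (dose.values >= visibility_fraction * prescription_gy)
    return float(visible.sum() * misreg.grid.voxel_volume_mm3 / 1000.0)
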
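"""Body and tissue-class segmentation from HU, and mask set algebra.

The body is extracted by thresholding (default -250 HU), keeping the largest
26-connected component and filling fully enclosed cavities so that internal
air (trachea, sinuses) stays part of the body.  Inside the body, voxels are
partitioned exhaustively into soft tissue (HU in the closed interval
[-250, 250]), bone (> 250 HU) and air (< -250 HU).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .grid import GridError, Mask, Volume, require_same_grid

__all__ = [
    "TissueClassSet",
    "SegmentationError",
    "segment_body",
    "segment_tissue_classes",
    "mask_algebra",
    "intersection",
    "union",
    "xor",
    "minus",
    "fraction_outside",
    "T_LOW",
    "T_HIGH",
    "BODY_THRESHOLD_HU",
]

#: soft-tissue / bone and soft-tissue / air HU boundaries
T_LOW = -250.0
T_HIGH = 250.0
BODY_THRESHOLD_HU = -250.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(ValueError):
    pass


@dataclass
class TissueClassSet:
    """Body mask partitioned into soft tissue, bone and air.

    Invariant: the three classes are pairwise disjoint and their union is the
    body exactly.
    """

    body: Mask
    soft_tissue: Mask
    bone: Mask
    air: Mask
    thresholds: Tuple[float, float] = (T_LOW, T_HIGH)

    def as_dict(self) -> dict:
        return {
            "body": self.body,
            "soft_tissue": self.soft_tissue,
            "bone": self.bone,
            "air": self.air,
        }

    def check_partition(self) -> None:
        s, b, a = self.soft_tissue.values, self.bone.values, self.air.values
        if np.any((s & b) | (s & a) | (b & a)):
            raise SegmentationError("tissue classes are not pairwise disjoint")
        if not np.array_equal(s | b | a, self.body.values):
            raise SegmentationError("tissue classes do not partition the body")


def segment_body(
    ct: Volume,
    body_threshold_hu: float = BODY_THRESHOLD_HU,
    min_component_voxels: int = 1,
    fill_holes: bool = True,
) -> Mask:
    """Automatic body contour: threshold, largest component, hole fill.

    26-connectivity is used for the foreground components and the default
    6-connected complement for hole filling (the standard digital-topology
    pairing), so enclosed air cavities are absorbed into the body when
    ``fill_holes`` is set.
    """
    if ct.unit != "HU":
        raise ValueError("segment_body expects an HU volume")
    fg = ct.values >= body_threshold_hu
    if not fg.any():
        raise SegmentationError("all-air volume: no voxels above the body threshold")
    labels, n = ndimage.label(fg, structure=_STRUCT_26)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = int(counts.argmax())
    if counts[largest] < min_component_voxels:
        raise SegmentationError(
            f"largest component has {counts[largest]} voxels "
            f"(< min_component_voxels={min_component_voxels})"
        )
    body = labels == largest
    if fill_holes:
        body = ndimage.binary_fill_holes(body)
    return Mask(ct.grid, body)


def segment_tissue_classes(
    ct: Volume,
    body: Mask,
    t_low: float = T_LOW,
    t_high: float = T_HIGH,
) -> TissueClassSet:
    """Partition the body into soft tissue [t_low, t_high], bone (> t_high)
    and air (< t_low); the soft-tissue interval is closed at both ends so the
    partition is exhaustive."""
    require_same_grid(ct, body)
    v = ct.values
    b = body.values
    soft = b & (v >= t_low) & (v <= t_high)
    bone = b & (v > t_high)
    air = b & (v < t_low)
    out = TissueClassSet(
        body=body.copy(),
        soft_tissue=Mask(ct.grid, soft),
        bone=Mask(ct.grid, bone),
        air=Mask(ct.grid, air),
        thresholds=(t_low, t_high),
    )
    return out


def intersection(a: Mask, b: Mask) -> Mask:
    require_same_grid(a, b)
    return Mask(a.grid, a.values & b.values)


def union(a: Mask, b: Mask) -> Mask:
    require_same_grid(a, b)
    return Mask(a.grid, a.values | b.values)


def xor(a: Mask, b: Mask) -> Mask:
    require_same_grid(a, b)
    return Mask(a.grid, a.values ^ b.values)


def minus(a: Mask, b: Mask) -> Mask:
    require_same_grid(a, b)
    return Mask(a.grid, a.values & ~b.values)


_OPS = {"intersection": intersection, "union": union, "xor": xor, "minus": minus}


def mask_algebra(a: Mask, b: Mask, op: str) -> Mask:
    """Voxelwise set operation: intersection, union, xor or minus."""
    try:
        fn = _OPS[op]
    except KeyError:
        raise ValueError(f"unknown mask operation {op!r}; choose from {sorted(_OPS)}")
    return fn(a, b)


def fraction_outside(structure: Mask, body: Mask) -> float:
    """Fraction of a structure's voxels lying outside the body contour."""
    require_same_grid(structure, body)
    n = structure.n_true
    if n == 0:
        raise SegmentationError("empty structure mask")
    outside = int((structure.values & ~body.values).sum())
    return outside / n
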
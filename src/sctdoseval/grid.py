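"""Grid-aware volumes, masks and rigid transforms.

All images in this package live on axis-aligned 3-D lattices: a :class:`Grid`
records voxel counts, spacing (mm) and the world coordinate of the *center* of
voxel ``(0, 0, 0)``.  Indices are 0-based, axes are world-aligned (identity
direction matrix); oblique or sheared grids are deliberately unsupported so
that distance-to-agreement geometry stays unambiguous.

:class:`Volume` carries a scalar field (HU, Gy or dimensionless) and
:class:`Mask` a boolean field on such a lattice.  Resampling between grids
uses spline interpolation (cubic by default for volumes, nearest-neighbour
always for masks), and :class:`RigidTransform` applies a known rigid motion by
resampling through its inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Tuple, Union

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "Grid",
    "Volume",
    "Mask",
    "RigidTransform",
    "GridError",
    "resample_to",
    "apply_rigid",
    "override_hu",
    "HU_MIN",
    "HU_MAX",
]

#: 12-bit CT convention; HU volumes are clamped to this range on write.
HU_MIN = -1024.0
HU_MAX = 3071.0

_FILL_BY_UNIT = {"HU": -1000.0, "Gy": 0.0, "1": 0.0}


class GridError(ValueError):
    """Invalid grid geometry or mismatched lattices."""


def _as_triple(x, dtype=float) -> tuple:
    t = tuple(dtype(v) for v in x)
    if len(t) != 3:
        raise GridError(f"expected a length-3 sequence, got {x!r}")
    return t


@dataclass(frozen=True)
class Grid:
    """Axis-aligned 3-D sampling lattice.

    Parameters
    ----------
    shape : (nx, ny, nz) voxels per axis, each >= 1.
    spacing : (sx, sy, sz) voxel spacing in mm, strictly positive.
    origin : world coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", _as_triple(self.shape, int))
        object.__setattr__(self, "spacing", _as_triple(self.spacing, float))
        object.__setattr__(self, "origin", _as_triple(self.origin, float))
        if any(n < 1 for n in self.shape):
            raise GridError(f"shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be strictly positive, got {self.spacing}")

    # -- geometry ----------------------------------------------------------

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def index_to_world(self, idx) -> np.ndarray:
        """World coordinates (mm) of (possibly fractional) voxel indices."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, xyz) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    @property
    def center_world(self) -> np.ndarray:
        """World coordinate of the geometric center of the voxel-center hull."""
        return self.index_to_world((np.asarray(self.shape) - 1) / 2.0)

    def matches(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    @classmethod
    def centered(cls, shape, spacing) -> "Grid":
        """Grid whose world origin sits at the center of the lattice."""
        shape = _as_triple(shape, int)
        spacing = _as_triple(spacing, float)
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        return cls(shape, spacing, origin)


@dataclass
class Volume:
    """Scalar field on a :class:`Grid` with a physical unit (HU, Gy or '1')."""

    grid: Grid
    values: np.ndarray
    unit: str = "HU"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.unit not in _FILL_BY_UNIT:
            raise ValueError(f"unit must be one of {sorted(_FILL_BY_UNIT)}, got {self.unit!r}")

    @property
    def fill_value(self) -> float:
        return _FILL_BY_UNIT[self.unit]

    def copy(self) -> "Volume":
        return Volume(self.grid, self.values.copy(), self.unit)


@dataclass
class Mask:
    """Boolean field on a :class:`Grid`."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool, copy=False)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"mask shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_true(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_true * self.grid.voxel_volume_mm3 / 1000.0

    def copy(self) -> "Mask":
        return Mask(self.grid, self.values.copy())


def require_same_grid(*objs: Union[Volume, Mask]) -> Grid:
    g0 = objs[0].grid
    for o in objs[1:]:
        if not g0.matches(o.grid):
            raise GridError("operands live on different grids")
    return g0


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion: intrinsic Z-Y-X Euler rotation about the volume center,
    then a world-frame translation.

    ``rotation_deg`` is ordered (z, y, x) in degrees; ``translation_mm`` is
    (x, y, z) in mm.  The motion maps a world point ``p`` to
    ``R (p - c) + c + t`` where ``c`` is the center of the grid it is applied
    to.
    """

    rotation_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "rotation_deg", _as_triple(self.rotation_deg))
        object.__setattr__(self, "translation_mm", _as_triple(self.translation_mm))

    @property
    def is_identity(self) -> bool:
        return all(a == 0 for a in self.rotation_deg) and all(
            t == 0 for t in self.translation_mm
        )

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYX", self.rotation_deg, degrees=True).as_matrix()

    def apply_points(self, pts: np.ndarray, center) -> np.ndarray:
        """Transform world points (N, 3) about the given center."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(center, dtype=float)
        R = self.rotation_matrix()
        return (pts - c) @ R.T + c + np.asarray(self.translation_mm)

    def inverse(self) -> "RigidTransform":
        R = Rotation.from_euler("ZYX", self.rotation_deg, degrees=True)
        Rinv = R.inv()
        t_inv = -Rinv.apply(np.asarray(self.translation_mm))
        ang = Rinv.as_euler("ZYX", degrees=True)
        return RigidTransform(tuple(ang), tuple(t_inv))

    def scaled(self, f: float) -> "RigidTransform":
        """Scale angles and translation by ``f`` (small-motion approximation
        of a partial transform; used to model residual registration error)."""
        return RigidTransform(
            tuple(a * f for a in self.rotation_deg),
            tuple(t * f for t in self.translation_mm),
        )


# -- operations -------------------------------------------------------------


def _resample_values(
    values: np.ndarray,
    source: Grid,
    target: Grid,
    order: int,
    cval: float,
) -> np.ndarray:
    # Separable coordinates: world-aligned axes mean each target axis maps to
    # one source axis.
    coords_1d = [
        (target.axis_coordinates(a) - source.origin[a]) / source.spacing[a]
        for a in range(3)
    ]
    mesh = np.meshgrid(*coords_1d, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh])
    out = ndimage.map_coordinates(
        values.astype(float, copy=False), coords, order=order, mode="constant", cval=cval
    )
    return out.reshape(target.shape)


def resample_to(
    source: Union[Volume, Mask],
    target: Grid,
    order: Optional[int] = None,
) -> Union[Volume, Mask]:
    """Resample a volume or mask onto ``target``.

    Volumes default to cubic spline interpolation (order 3); masks are always
    resampled with nearest-neighbour regardless of ``order`` so boolean-ness is
    preserved.  Samples falling outside the source extent take the unit's fill
    value (-1000 HU, 0 Gy, False).  Resampling onto a matching grid returns the
    data unchanged for any order.
    """
    if isinstance(source, Mask):
        if source.grid.matches(target):
            return source.copy()
        out = _resample_values(source.values.astype(np.float32), source.grid, target, 0, 0.0)
        return Mask(target, out > 0.5)
    if order is None:
        order = 3
    if source.grid.matches(target):
        return source.copy()
    out = _resample_values(source.values, source.grid, target, order, source.fill_value)
    return Volume(target, out, source.unit)


def apply_rigid(v: Volume, t: RigidTransform, order: int = 3) -> Volume:
    """Move the content of ``v`` by rigid transform ``t`` (output on ``v``'s
    grid, resample-through-inverse contract).

    The identity transform returns the input unchanged bit-exactly.
    """
    if t.is_identity:
        return v.copy()
    grid = v.grid
    c = grid.center_world
    # output(x) = v(T^-1 x);  T^-1(x) = R^T (x - c - t) + c
    R = t.rotation_matrix()
    tr = np.asarray(t.translation_mm)
    mesh = np.meshgrid(*[grid.axis_coordinates(a) for a in range(3)], indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    src_world = (pts - c - tr) @ R + c  # (p - c - t) @ (R^T)^T == ... @ R
    src_idx = grid.world_to_index(src_world).T
    out = ndimage.map_coordinates(
        v.values.astype(float, copy=False),
        src_idx,
        order=order,
        mode="constant",
        cval=v.fill_value,
    )
    return Volume(grid, out.reshape(grid.shape), v.unit)


def apply_rigid_mask(m: Mask, t: RigidTransform) -> Mask:
    """Rigid motion of a mask (nearest-neighbour)."""
    if t.is_identity:
        return m.copy()
    v = Volume(m.grid, m.values.astype(float), unit="1")
    out = apply_rigid(v, t, order=0)
    return Mask(m.grid, out.values > 0.5)


def override_hu(ct: Volume, mask: Mask, hu_value: float) -> Volume:
    """Return a copy of ``ct`` with voxels inside ``mask`` set to ``hu_value``.

    This is the surrogate for density overrides in a planning system: a
    contrast-uptake region is forced to water (0 HU), couch/fixation hardware
    to air (-1000 HU).  The input is not mutated.
    """
    require_same_grid(ct, mask)
    out = ct.copy()
    out.values[mask.values] = hu_value
    return out


def clamp_hu(values: np.ndarray) -> np.ndarray:
    return np.clip(values, HU_MIN, HU_MAX)
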
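"""NIfTI and JSON I/O.

Volumes and masks are stored as NIfTI-1 (`.nii` / `.nii.gz`) with a
world-aligned diagonal affine; the physical unit and role travel in a JSON
sidecar (`<stem>.json` with fields ``unit`` and ``role``) because NIfTI has no
dose/HU unit field.  Rigid transforms are stored as JSON
``{"rotation_deg": [z, y, x], "translation_mm": [x, y, z],
"convention": "intrinsic-ZYX-center"}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np

from .grid import Grid, GridError, Mask, RigidTransform, Volume, clamp_hu

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_transform",
    "load_transform",
]

_CONVENTION = "intrinsic-ZYX-center"


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_img(img) -> Grid:
    aff = img.affine
    lin = aff[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-4):
        raise GridError(
            "only world-aligned (diagonal-affine) NIfTI volumes are supported"
        )
    spacing = np.diag(lin).astype(float)
    origin = aff[:3, 3].astype(float)
    # Normalise negative spacings (flipped axes) to a positive-spacing grid.
    if np.any(spacing <= 0):
        raise GridError("negative or zero voxel spacing in NIfTI affine")
    return Grid(tuple(int(n) for n in img.shape[:3]), tuple(spacing), tuple(origin))


def save_volume(vol: Volume, path: Union[str, Path], role: str = "") -> Path:
    """Write a volume to NIfTI plus a unit/role sidecar.

    HU volumes are clamped to [-1024, 3071] (12-bit CT convention) on write.
    """
    path = Path(path)
    values = vol.values
    if vol.unit == "HU":
        values = clamp_hu(values)
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(vol.grid))
    nib.save(img, path)
    sidecar = {"unit": vol.unit, "role": role}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_volume(path: Union[str, Path], unit: Optional[str] = None) -> Volume:
    """Read a NIfTI volume; unit comes from the sidecar unless given."""
    path = Path(path)
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    if unit is None:
        sc = _sidecar_path(path)
        unit = json.loads(sc.read_text())["unit"] if sc.exists() else "HU"
    return Volume(grid, np.asarray(img.dataobj, dtype=float), unit)


def save_mask(mask: Mask, path: Union[str, Path], role: str = "") -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.grid))
    nib.save(img, path)
    _sidecar_path(path).write_text(json.dumps({"unit": "binary", "role": role}, indent=2))
    return path


def load_mask(path: Union[str, Path]) -> Mask:
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    return Mask(grid, np.asarray(img.dataobj) > 0)


def save_transform(t: RigidTransform, path: Union[str, Path]) -> Path:
    path = Path(path)
    payload = {
        "rotation_deg": list(t.rotation_deg),
        "translation_mm": list(t.translation_mm),
        "convention": _CONVENTION,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_transform(path: Union[str, Path]) -> RigidTransform:
    payload = json.loads(Path(path).read_text())
    conv = payload.get("convention", _CONVENTION)
    if conv != _CONVENTION:
        raise ValueError(f"unsupported transform convention {conv!r}")
    return RigidTransform(
        tuple(payload["rotation_deg"]), tuple(payload["translation_mm"])
    )
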
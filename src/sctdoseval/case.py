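"""The per-case data bundle: paired CTs, structures, transforms and doses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from .dose import PlanSpec
from .grid import Grid, Mask, RigidTransform, Volume

__all__ = ["CaseRecord"]


@dataclass
class CaseRecord:
    """One evaluation case: planning CT, registered synthetic CT, structure
    masks, the rigid misalignment actually present after registration, and the
    photon/proton dose grids computed on each CT with the same plans.

    Everything lives on the planning-CT grid.  ``ground_truth`` carries the
    generator parameters (offsets, error-field scales) for recovery tests;
    ``body_overlap`` and ``ctv_union`` are derived by the pipeline.
    """

    case_id: str
    pct: Volume
    sct: Volume
    structures: Dict[str, Mask]
    applied_offset: RigidTransform
    residual_offset: RigidTransform
    plans: Dict[str, PlanSpec]
    dose_photon_pct: Volume
    dose_photon_sct: Volume
    dose_proton_pct: Volume
    dose_proton_sct: Volume
    prescription_gy: float = 68.0
    contrast_mask: Optional[Mask] = None
    table_mask: Optional[Mask] = None
    ground_truth: Dict = field(default_factory=dict)
    # derived during analysis
    body_overlap: Optional[Mask] = None
    ctv_union: Optional[Mask] = None

    @property
    def grid(self) -> Grid:
        return self.pct.grid
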
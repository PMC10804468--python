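"""Synthetic-CT construction in the CBCT frame, and contour propagation.

The sCT transfers HU values (including dental-artifact overrides) from the
planning CT into the CBCT frame of reference through the DIR displacement
field.  Voxels outside the CBCT field of view are filled with the
corresponding, unwarped planning-CT data — a hard switch at the FOV seam,
with the provenance recorded so evaluation can flag it.  The deformed
repeat CT (``rCT_def``), built by registering the noise-free deformed CT
to the same CBCT, serves as the HU gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .grids import Grid, StructureSet, VectorField, VoxelImage, dice  # noqa: F401
from .registration import (
    RegistrationConfig,
    deformable_register,
    warp_image,
    warp_mask,
)


@dataclass
class SctInputs:
    """Everything needed to build one synthetic CT.

    ``artifact_mask`` (planning-CT grid) is overridden to ``override_hu``
    before warping, so the overridden value — not the streak HU — is
    transferred.  ``dvf`` is the DIR field on the CBCT grid (pull-back);
    ``fov`` is the in-FOV mask on the same grid.
    """

    pct: VoxelImage
    dvf: VectorField
    fov: np.ndarray
    artifact_mask: Optional[np.ndarray] = None
    override_hu: float = 40.0

    def __post_init__(self) -> None:
        if not (-200.0 <= self.override_hu <= 200.0):
            raise ValueError("override HU must be within the soft-tissue range [-200, 200]")
        if self.fov.shape != self.dvf.grid.dims:
            raise ValueError("FOV mask must conform to the DVF grid")
        if self.artifact_mask is not None and (
            self.artifact_mask.shape != self.pct.grid.dims
        ):
            raise ValueError("artifact mask must conform to the pCT grid")


def apply_artifact_override(
    pct: VoxelImage, artifact_mask: Optional[np.ndarray], override_hu: float
) -> VoxelImage:
    """Replace dental-artifact voxels by a soft-tissue-like HU value."""
    if artifact_mask is None or not artifact_mask.any():
        return pct.copy()
    vals = pct.values.copy()
    vals[artifact_mask] = override_hu
    return VoxelImage(pct.grid, vals, kind="HU")


def build_sct(inputs: SctInputs) -> Tuple[VoxelImage, np.ndarray]:
    """Build the synthetic CT and its FOV provenance map.

    Inside the FOV: the override-applied pCT warped through the DVF
    (trilinear).  Outside: the override-applied pCT copied unwarped.
    Returns ``(sCT, provenance)`` where provenance is True where the voxel
    came from the warped (in-FOV) branch.
    """
    if not inputs.dvf.grid.same_geometry(inputs.pct.grid):
        # warping handles differing grids, but FOV fill requires a shared one
        raise ValueError("sCT construction requires pCT and CBCT on the same grid")
    pct_ov = apply_artifact_override(inputs.pct, inputs.artifact_mask,
                                     inputs.override_hu)
    warped = warp_image(pct_ov, inputs.dvf, interpolation="trilinear",
                        fill_value=-1000.0)
    vals = np.where(inputs.fov, warped.values, pct_ov.values)
    return VoxelImage(inputs.dvf.grid, vals, kind="HU"), inputs.fov.copy()


def build_rct_def(
    rct: VoxelImage,
    cbct: VoxelImage,
    cfg: Optional[RegistrationConfig] = None,
    fov: Optional[np.ndarray] = None,
    gt_contours: Optional[StructureSet] = None,
) -> Tuple[VoxelImage, Optional[StructureSet]]:
    """Deform the repeat CT into the CBCT frame: the dose gold standard.

    The rCT (here: the phantom's noise-free deformed CT) is deformably
    registered to the CBCT and resampled; ground-truth contours, when
    given, are attached unchanged (they already live in the CBCT frame).
    """
    dvf = deformable_register(cbct, rct, cfg, fov)
    rct_def = warp_image(rct, dvf, interpolation="trilinear", fill_value=-1000.0)
    if fov is not None:
        vals = np.where(fov, rct_def.values, rct.values)
        rct_def = VoxelImage(dvf.grid, vals, kind="HU")
    return rct_def, gt_contours


def propagate_contours(structures: StructureSet, dvf: VectorField) -> StructureSet:
    """Warp every mask of a structure set through the DVF ("uncorrected").

    Masks are warped with trilinear interpolation of the indicator and a
    0.5 threshold.  Structures that come out empty are kept (flagged by
    their zero volume) rather than dropped.
    """
    masks = {name: warp_mask(structures[name], dvf) for name in structures.names()}
    return StructureSet(dvf.grid, masks, dict(structures.prescriptions))
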
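"""Voxel grids, vector fields and structure sets.

These are the common currency of the whole pipeline: CT-like images (HU),
dose grids (Gy), displacement vector fields (mm) and named binary masks all
live on regular, axis-aligned 3D grids.  World coordinates are in mm with
``world = origin + index * spacing`` on each axis; arrays are indexed
``(x, y, z)`` with ``z`` the superior-inferior (axial) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional, Tuple

import nibabel as nib
import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular 3D voxel grid (origin/spacing in mm)."""

    origin: Tuple[float, float, float]
    spacing: Tuple[float, float, float]
    dims: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must be length-3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be >= 1, got {self.dims}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.dims

    @property
    def extent_mm(self) -> Tuple[float, float, float]:
        return tuple(d * s for d, s in zip(self.dims, self.spacing))

    def axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a])
            for a in range(3)
        )

    def coords(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (sparse meshgrid)."""
        ax = self.axes()
        return np.meshgrid(*ax, indexing="ij", sparse=True)

    def world_to_index(self, pts_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world points (..., 3)."""
        o = np.asarray(self.origin)
        s = np.asarray(self.spacing)
        return (np.asarray(pts_mm, dtype=float) - o) / s

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


def _check_grid_values(grid: Grid, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.dims:
        raise ValueError(f"values shape {values.shape} != grid dims {grid.dims}")
    return values


@dataclass
class VoxelImage:
    """A scalar volume (HU for CT-like images, Gy for dose) on a grid."""

    grid: Grid
    values: np.ndarray
    kind: str = "HU"  # "HU" or "Gy"

    def __post_init__(self) -> None:
        self.values = _check_grid_values(self.grid, self.values).astype(
            np.float32, copy=False
        )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if self.kind == "HU":
            if self.values.min() < HU_MIN or self.values.max() > HU_MAX:
                raise ValueError(
                    f"HU values outside [{HU_MIN}, {HU_MAX}]: "
                    f"range ({self.values.min()}, {self.values.max()})"
                )
        elif self.kind == "Gy":
            if self.values.min() < 0:
                raise ValueError("dose values must be >= 0")

    def copy(self) -> "VoxelImage":
        return VoxelImage(self.grid, self.values.copy(), self.kind)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.grid.spacing) + [1.0])
        aff[:3, 3] = self.grid.origin
        return aff

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.values, dtype=np.float32),
                                 self.affine()), path)

    @classmethod
    def from_nifti(cls, path: str, kind: str = "HU") -> "VoxelImage":
        img = nib.load(path)
        aff = img.affine
        if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
            raise ValueError("only axis-aligned NIfTI volumes are supported")
        spacing = tuple(float(v) for v in np.diag(aff[:3, :3]))
        origin = tuple(float(v) for v in aff[:3, 3])
        data = np.asanyarray(img.dataobj).astype(np.float32)
        return cls(Grid(origin, spacing, data.shape), data, kind)


@dataclass
class VectorField:
    """Per-voxel 3-vector displacement in mm (a DVF).

    Pull-back convention: the field lives on the *fixed* grid and maps a
    point x in the fixed frame to its corresponding point ``x + u(x)`` in
    the moving frame, so ``warped(x) = moving(x + u(x))``.  The convention
    is immutable metadata.
    """

    grid: Grid
    displacement: np.ndarray  # (nx, ny, nz, 3) mm
    convention: str = field(default="pull-back")

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=np.float32)
        if disp.shape != self.grid.dims + (3,):
            raise ValueError(
                f"displacement shape {disp.shape} != {self.grid.dims + (3,)}"
            )
        if not np.all(np.isfinite(disp)):
            raise ValueError("displacement must be finite everywhere")
        if self.convention != "pull-back":
            raise ValueError("only the pull-back convention is supported")
        self.displacement = disp

    @property
    def max_magnitude_mm(self) -> float:
        return float(np.sqrt((self.displacement.astype(np.float64) ** 2)
                             .sum(axis=-1)).max())

    def to_nifti(self, path: str) -> None:
        # 4D NIfTI, vector dimension last
        aff = np.diag(list(self.grid.spacing) + [1.0])
        aff[:3, 3] = self.grid.origin
        nib.save(nib.Nifti1Image(self.displacement.astype(np.float32), aff), path)

    @classmethod
    def from_nifti(cls, path: str) -> "VectorField":
        img = nib.load(path)
        aff = img.affine
        spacing = tuple(float(v) for v in np.diag(aff[:3, :3]))
        origin = tuple(float(v) for v in aff[:3, 3])
        data = np.asanyarray(img.dataobj).astype(np.float32)
        if data.ndim != 4 or data.shape[-1] != 3:
            raise ValueError("expected a 4D NIfTI with vector dimension last")
        return cls(Grid(origin, spacing, data.shape[:3]), data)

    @classmethod
    def zeros(cls, grid: Grid) -> "VectorField":
        return cls(grid, np.zeros(grid.dims + (3,), dtype=np.float32))


@dataclass
class StructureSet:
    """Named binary masks on a stated grid, plus CTV prescriptions.

    ``prescriptions`` maps CTV names to ``(dose_gy, n_fractions)``.
    """

    grid: Grid
    masks: Dict[str, np.ndarray]
    prescriptions: Dict[str, Tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in list(self.masks.items()):
            m = np.asarray(m)
            if m.shape != self.grid.dims:
                raise ValueError(f"mask '{name}' shape {m.shape} != grid {self.grid.dims}")
            self.masks[name] = m.astype(bool)
        for name, (dose, nfx) in self.prescriptions.items():
            if dose <= 0 or nfx < 1:
                raise ValueError(f"invalid prescription for '{name}': {dose} Gy / {nfx} fx")

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> Iterator[str]:
        return iter(self.masks)

    def ctv_names(self) -> Tuple[str, ...]:
        return tuple(n for n in self.masks if n in self.prescriptions)

    def volume_mm3(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.grid.voxel_volume_mm3()

    def copy(self) -> "StructureSet":
        return StructureSet(
            self.grid,
            {k: v.copy() for k, v in self.masks.items()},
            dict(self.prescriptions),
        )

    def subset(self, names) -> "StructureSet":
        return StructureSet(
            self.grid,
            {n: self.masks[n] for n in names if n in self.masks},
            {n: p for n, p in self.prescriptions.items() if n in names},
        )

    def save(self, directory: str) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        aff = np.diag(list(self.grid.spacing) + [1.0])
        aff[:3, 3] = self.grid.origin
        for name, m in self.masks.items():
            nib.save(nib.Nifti1Image(m.astype(np.uint8), aff),
                     os.path.join(directory, f"{name}.nii.gz"))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Defined as 1.0 when both masks are empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must be on conforming grids")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)
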
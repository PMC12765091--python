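"""Domain types, grid arithmetic, resampling and volume I/O.

All volumes live on an axis-aligned voxel lattice (:class:`VolumeGrid`).
Conventions are fixed package-wide:

* voxel indices are 0-based; array axis order is (x, y, z);
* a voxel occupies the closed axis-aligned box of edge ``spacing``
  centred on its centre; world coordinate of index ``i`` along an axis
  is ``origin + i * spacing``;
* dose is stored and reported in Gy, distances in mm, volumes in mm³.

Volumes are exchanged as NIfTI (``.nii``/``.nii.gz``) with a diagonal
affine built from spacing and origin; DICOM-RT is a non-goal.  Grids must
be compatible before any cross-volume operation — the package refuses
with :class:`GridMismatchError` rather than resampling silently;
resampling is always explicit (:func:`resample_nearest`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import nibabel as nib
import numpy as np

GRID_ATOL_MM = 1e-6


class VolumeFormatError(ValueError):
    """Raised when a file is not a readable 3D volume."""


class VolumeValidationError(ValueError):
    """Raised when voxel values violate the dose/mask contract."""


class GridMismatchError(ValueError):
    """Raised when an operation receives volumes on incompatible grids."""


class EmptyStructureError(ValueError):
    """Raised when an operation requires a non-empty mask."""


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel lattice geometry shared by all volumes of one case.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts per axis, each >= 1.
    spacing : tuple of float
        Physical voxel edge lengths in mm, each > 0.
    origin : tuple of float
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("grid must be three-dimensional")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def compatible_with(self, other: "VolumeGrid", atol: float = GRID_ATOL_MM) -> bool:
        """True iff shape matches and spacing/origin agree within ``atol`` mm."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol, rtol=0.0)
            and np.allclose(self.origin, other.origin, atol=atol, rtol=0.0)
        )

    def require_compatible(self, other: "VolumeGrid") -> None:
        if not self.compatible_with(other):
            raise GridMismatchError(
                f"incompatible grids: {self} vs {other}; resample explicitly first"
            )

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centres, shape (N, 3)."""
        axes = [
            self.origin[k] + np.arange(self.shape[k]) * self.spacing[k]
            for k in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def affine(self) -> np.ndarray:
        """4x4 NIfTI affine mapping voxel indices to world mm."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff


@dataclass
class StructureMask:
    """One organ's binary occupancy on a grid."""

    organ_id: str
    grid: VolumeGrid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.occupancy)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {arr.shape} does not match grid shape {self.grid.shape}"
            )
        self.occupancy = arr.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    @property
    def volume_mm3(self) -> float:
        """Physical volume: occupied voxels times voxel volume."""
        return self.voxel_count * self.grid.voxel_volume_mm3

    def with_occupancy(self, occupancy: np.ndarray, organ_id: str | None = None) -> "StructureMask":
        return StructureMask(organ_id or self.organ_id, self.grid, occupancy)


@dataclass
class DoseGrid:
    """Scalar dose in Gy per voxel on a grid.  Non-negative and finite."""

    grid: VolumeGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.dose, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {arr.shape} does not match grid shape {self.grid.shape}"
            )
        n_bad = int(np.count_nonzero(~np.isfinite(arr) | (arr < 0)))
        if n_bad:
            raise VolumeValidationError(
                f"dose volume contains {n_bad} invalid voxel(s) (NaN, infinite or negative)"
            )
        self.dose = arr


@dataclass
class StructureSet:
    """All organ masks of one case plus the planning target volume (PTV)."""

    case_id: str
    masks: dict[str, StructureMask] = field(default_factory=dict)
    ptv: StructureMask | None = None

    def __post_init__(self) -> None:
        grids = [m.grid for m in self.masks.values()]
        if self.ptv is not None:
            grids.append(self.ptv.grid)
        for g in grids[1:]:
            grids[0].require_compatible(g)
        for organ_id, mask in self.masks.items():
            if mask.organ_id != organ_id:
                raise ValueError(
                    f"mask keyed {organ_id!r} carries organ_id {mask.organ_id!r}"
                )

    def __iter__(self) -> Iterator[StructureMask]:
        return iter(self.masks.values())

    def __len__(self) -> int:
        return len(self.masks)


# ---------------------------------------------------------------------------
# I/O


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    if img.ndim != 3:
        raise VolumeFormatError(f"expected a 3D volume, got {img.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in np.asarray(img.affine)[:3, 3])
    return VolumeGrid(shape=tuple(img.shape), spacing=spacing, origin=origin)


def read_volume(path: str | Path, as_mask: bool) -> StructureMask | DoseGrid:
    """Read a 3D NIfTI volume as a binary mask or a dose grid.

    Masks binarize voxel values at > 0.5.  Dose volumes are taken in Gy as
    stored; NaN or negative voxels raise :class:`VolumeValidationError`
    naming the number of offending voxels.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise VolumeFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    grid = _grid_from_img(img)
    data = np.asarray(img.dataobj, dtype=float)
    if as_mask:
        organ_id = path.name.removesuffix(".gz").removesuffix(".nii")
        return StructureMask(organ_id=organ_id, grid=grid, occupancy=data > 0.5)
    return DoseGrid(grid=grid, dose=data)


def write_volume(volume: StructureMask | DoseGrid, path: str | Path) -> None:
    """Write a mask (as uint8 0/1) or dose grid (float32 Gy) to NIfTI."""
    if isinstance(volume, StructureMask):
        data = volume.occupancy.astype(np.uint8)
    else:
        data = volume.dose.astype(np.float32)
    img = nib.Nifti1Image(data, volume.grid.affine())
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(Path(path)))


def resample_nearest(src: StructureMask, target: VolumeGrid) -> StructureMask:
    """Nearest-neighbour resampling of a mask onto another lattice.

    Each target voxel centre is mapped to the nearest source voxel centre;
    centres outside the source extent are unoccupied.  Identity (voxelwise)
    when the grids are already compatible.
    """
    if src.grid.compatible_with(target):
        return StructureMask(src.organ_id, target, src.occupancy.copy())
    out = np.zeros(target.shape, dtype=bool)
    # nearest source index per target axis, computed separably
    idx = []
    inside = []
    for k in range(3):
        centers = target.origin[k] + np.arange(target.shape[k]) * target.spacing[k]
        frac = (centers - src.grid.origin[k]) / src.grid.spacing[k]
        near = np.floor(frac + 0.5).astype(int)  # half-way ties round up
        ok = (frac >= -0.5) & (frac <= src.grid.shape[k] - 0.5)
        idx.append(np.clip(near, 0, src.grid.shape[k] - 1))
        inside.append(ok)
    occ = src.occupancy[np.ix_(idx[0], idx[1], idx[2])]
    box = np.ix_(inside[0], inside[1], inside[2])
    mask3d = np.zeros(target.shape, dtype=bool)
    mask3d[box] = True
    out[mask3d] = occ[mask3d]
    return StructureMask(src.organ_id, target, out)
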
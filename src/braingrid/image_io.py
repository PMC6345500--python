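"""NIfTI volume I/O, canonical orientation and grid labelmap export.

Masks are read with nibabel and reoriented to canonical RAS+ axis order on
load; reorientation permutes/flips the array and updates the affine together,
so the world coordinate of every voxel center is unchanged.  Classification
always happens in world millimetres through the affine — masks are never
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import BrainGrid

__all__ = [
    "VolumeMask",
    "ReferenceGeometry",
    "read_mask",
    "write_mask",
    "make_reference_geometry",
    "export_grid_labelmap",
    "write_labelmap",
]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or not np.all(np.isfinite(affine)):
        raise ValueError("affine must be a finite 4x4 matrix")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular; voxel volume undefined")
    return affine


@dataclass
class VolumeMask:
    """A binary 3-D volume with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3-D, got {self.data.ndim}-D")
        self.affine = _check_affine(self.affine)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_foreground * self.voxel_volume

    def foreground_world_coords(self) -> np.ndarray:
        """(N, 3) world-mm coordinates of foreground voxel centers."""
        idx = np.argwhere(self.data)
        if len(idx) == 0:
            return np.empty((0, 3), dtype=float)
        return nib.affines.apply_affine(self.affine, idx)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounds spanned by the corner voxel centers."""
        shape = np.asarray(self.data.shape)
        corners = np.array([[i, j, k] for i in (0, shape[0] - 1)
                            for j in (0, shape[1] - 1)
                            for k in (0, shape[2] - 1)], dtype=float)
        world = nib.affines.apply_affine(self.affine, corners)
        return world.min(axis=0), world.max(axis=0)


@dataclass(frozen=True)
class ReferenceGeometry:
    """Target sampling geometry for labelmap export: shape + affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    space_tag: str = "MNI"

    def __post_init__(self) -> None:
        shape = tuple(int(v) for v in self.shape)
        if len(shape) != 3 or any(v <= 0 for v in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", _check_affine(self.affine))

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) world coordinates of every voxel center, C order."""
        grid = np.indices(self.shape).reshape(3, -1).T
        return nib.affines.apply_affine(self.affine, grid)


def make_reference_geometry(
    shape: tuple[int, int, int] = (91, 109, 91),
    voxel_size_mm: float = 2.0,
    space_tag: str = "MNI",
) -> ReferenceGeometry:
    """RAS+ geometry whose world origin lies at the volume center.

    The default matches the common 2 mm MNI template dimensions.  The voxel
    at ``(shape-1)/2`` maps to the world origin exactly when shape is odd.
    """
    shape = tuple(int(v) for v in shape)
    if any(v <= 0 for v in shape) or voxel_size_mm <= 0:
        raise ValueError("shape and voxel_size_mm must be positive")
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
    return ReferenceGeometry(shape=shape, affine=affine, space_tag=space_tag)


def read_mask(path, foreground_threshold: float = 0.5) -> VolumeMask:
    """Load a NIfTI segmentation as a binary mask in canonical orientation.

    Values strictly greater than ``foreground_threshold`` are foreground,
    which binarizes probabilistic segmentations sensibly at the default 0.5.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:  # drop trailing singleton dims
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return VolumeMask(data=data > foreground_threshold, affine=img.affine)


def write_mask(mask: VolumeMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def export_grid_labelmap(geometry: ReferenceGeometry, grid: BrainGrid) -> np.ndarray:
    """Label every voxel of ``geometry`` with its cell ID (1..48).

    Membership is decided by the voxel center's world coordinate, so the
    result is deterministic and idempotent for a fixed geometry.
    """
    ids = grid.label_points(geometry.voxel_centers())
    return ids.reshape(geometry.shape).astype(np.int16)


def write_labelmap(geometry: ReferenceGeometry, grid: BrainGrid, path) -> None:
    labelmap = export_grid_labelmap(geometry, grid)
    img = nib.Nifti1Image(labelmap, geometry.affine)
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))
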
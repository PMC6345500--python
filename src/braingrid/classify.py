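"""Tumor-mask classification: infiltrated cells, volumes, plane distances.

A grid cell counts as infiltrated when the tumor's overlap volume with it
exceeds ``min_overlap_mm3`` (default 0: any foreground voxel whose center
falls in the cell infiltrates it).  Overlap is computed from voxel centers
through the mask's own affine — no resampling, so per-cell volumes sum to
the total mask volume exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .grid import BrainGrid, GridLabel
from .image_io import VolumeMask

__all__ = [
    "InfiltrationReport",
    "classify_mask",
    "plane_distances",
    "laterality_summary",
]


@dataclass
class InfiltrationReport:
    """Per-study classification result.

    ``cell_volumes`` maps each infiltrated :class:`GridLabel` to its overlap
    volume in mm^3; ``plane_distances`` maps plane names (``"x+33"`` ...) to
    the minimum unsigned distance in mm from tumor foreground to the plane
    (absent for empty masks, where the distance is undefined).
    """

    study_id: str
    space_tag: str
    cell_volumes: dict[GridLabel, float]
    total_volume_mm3: float
    plane_distances: dict[str, float] = field(default_factory=dict)
    acquisition_date: Optional[str] = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cell_volumes.values()):
            raise ValueError("cell overlap volumes must be non-negative")

    @property
    def cells(self) -> frozenset[GridLabel]:
        return frozenset(self.cell_volumes)

    @property
    def n_cells(self) -> int:
        return len(self.cell_volumes)

    @property
    def total_volume_cm3(self) -> float:
        return self.total_volume_mm3 / 1000.0

    @property
    def laterality(self) -> str:
        return laterality_summary(self)["laterality"]

    def to_dict(self) -> dict:
        cells = sorted(self.cell_volumes, key=lambda lb: lb.id)
        return {
            "study_id": self.study_id,
            "date": self.acquisition_date,
            "space": self.space_tag,
            "n_cells": self.n_cells,
            "cells": [
                {"label": str(lb), "id": lb.id, "volume_mm3": self.cell_volumes[lb]}
                for lb in cells
            ],
            "total_volume_cm3": self.total_volume_cm3,
            "plane_distances": dict(self.plane_distances),
            "laterality": self.laterality,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "InfiltrationReport":
        cell_volumes = {
            GridLabel.parse(c["label"]): float(c["volume_mm3"]) for c in d["cells"]
        }
        return cls(
            study_id=d.get("study_id", ""),
            space_tag=d.get("space", "MNI"),
            cell_volumes=cell_volumes,
            total_volume_mm3=float(d["total_volume_cm3"]) * 1000.0,
            plane_distances=dict(d.get("plane_distances", {})),
            acquisition_date=d.get("date"),
        )

    @classmethod
    def from_json(cls, path) -> "InfiltrationReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_cells(
        cls,
        cells,
        study_id: str = "",
        space_tag: str = "MNI",
        volume_cm3: float = 0.0,
        date: Optional[str] = None,
    ) -> "InfiltrationReport":
        """Build a report from a bare cell set (e.g. a visual PACS count).

        Per-cell volumes are unknown in that setting and stored as NaN is
        avoided; each cell gets an equal share of the total volume so the
        conservation invariant still holds.
        """
        labels = [c if isinstance(c, GridLabel) else GridLabel.parse(c) for c in cells]
        share = volume_cm3 * 1000.0 / len(labels) if labels else 0.0
        return cls(
            study_id=study_id,
            space_tag=space_tag,
            cell_volumes={lb: share for lb in labels},
            total_volume_mm3=volume_cm3 * 1000.0,
            acquisition_date=date,
        )


def classify_mask(
    mask: VolumeMask,
    grid: BrainGrid,
    min_overlap_mm3: float = 0.0,
    study_id: str = "",
    acquisition_date: Optional[str] = None,
) -> InfiltrationReport:
    """Classify a tumor mask against the grid.

    Returns an :class:`InfiltrationReport` with the infiltrated cells, their
    overlap volumes, the total volume and (for non-empty masks) the per-plane
    distances.
    """
    if min_overlap_mm3 < 0:
        raise ValueError("min_overlap_mm3 must be >= 0")
    coords = mask.foreground_world_coords()
    vv = mask.voxel_volume
    cell_volumes: dict[GridLabel, float] = {}
    if len(coords):
        ids = grid.label_points(coords)
        counts = np.bincount(ids, minlength=49)
        for cell_id in np.nonzero(counts)[0]:
            vol = float(counts[cell_id]) * vv
            if vol > min_overlap_mm3:
                cell_volumes[GridLabel.from_id(int(cell_id))] = vol
    report = InfiltrationReport(
        study_id=study_id,
        space_tag=grid.space_tag,
        cell_volumes=cell_volumes,
        total_volume_mm3=len(coords) * vv,
        acquisition_date=acquisition_date,
    )
    if len(coords):
        report.plane_distances = plane_distances(mask, grid)
    return report


def plane_distances(mask: VolumeMask, grid: BrainGrid) -> dict[str, float]:
    """Minimum unsigned distance (mm) from tumor foreground to each plane.

    Zero when the foreground spans the plane (voxel centers on both sides),
    mirroring how a grid line crossing the visible tumor border reads on the
    image.  Raises for empty masks, where the distance is undefined.
    """
    coords = mask.foreground_world_coords()
    if len(coords) == 0:
        raise ValueError("plane distances are undefined for an empty mask")
    axis_index = {"x": 0, "y": 1, "z": 2}
    out: dict[str, float] = {}
    for name, axis, value in grid.plane_items():
        delta = coords[:, axis_index[axis]] - value
        if delta.max() >= 0 and delta.min() <= 0:
            out[name] = 0.0
        else:
            out[name] = float(np.abs(delta).min())
    return out


def laterality_summary(report: InfiltrationReport) -> dict:
    """Hemispheric involvement derived from the infiltrated cells.

    A1/A2 cells are right-sided (radiological convention), A3/A4 left-sided;
    ``bilateral`` when both sides hold cells, ``indeterminate`` for an empty
    report.
    """
    n_right = sum(1 for lb in report.cells if lb.side == "right")
    n_left = sum(1 for lb in report.cells if lb.side == "left")
    if n_left and n_right:
        laterality = "bilateral"
    elif n_left:
        laterality = "left"
    elif n_right:
        laterality = "right"
    else:
        laterality = "indeterminate"
    return {"laterality": laterality, "n_left_cells": n_left, "n_right_cells": n_right}
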
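"""Brain-Grid geometry: landmark planes, cell labels and point classification.

The Brain-Grid partitions the whole brain into 48 cells ("grid voxels") by
intersecting eight landmark planes in stereotaxic space: three sagittal-axis
planes (constant Y, through the anterior insular point, the posterior insular
point and the parieto-occipital junction), two axial-axis planes (constant Z,
through the callosal-cingulate cistern and the inferior insular point) and
three lateral planes (constant X: right external-capsule line, midline, left
external-capsule line).  Cells are named ``A{1-4}C{1-3}S{1-4}``:

* A — axial slab, 1-4 right-to-left (radiological convention, A1 = patient
  right = largest world x in RAS+),
* C — coronal slab, 1-3 cranio-caudal (C1 above the callosal plane),
* S — sagittal slab, 1-4 anterior-to-posterior (S1 in front of the anterior
  insular plane).

World space is RAS+ millimetres (MNI convention).  Points that fall exactly
on a plane are assigned to the lower-index slab (anterior / cranial / right),
so the 48 half-open boxes tile all of space.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GridPlanes",
    "GridLabel",
    "BrainGrid",
    "build_default_grid",
    "parse_label",
    "MNI_PLANES",
    "TALAIRACH_PLANES",
]

_SPACE_TAGS = ("MNI", "Talairach", "subject")


@dataclass(frozen=True)
class GridPlanes:
    """The eight landmark plane coordinates defining the Brain-Grid.

    Parameters
    ----------
    x_planes : three world-mm X coordinates, strictly decreasing
        (right external-capsule line, midline, left line).
    y_planes : three world-mm Y coordinates, strictly decreasing
        (anterior insular point, posterior insular point, parieto-occipital
        junction).
    z_planes : two world-mm Z coordinates, strictly decreasing
        (callosal-cingulate plane, inferior insular plane).
    space_tag : ``"MNI"``, ``"Talairach"`` or ``"subject"`` for grids built
        from patient-specific landmarks.
    """

    x_planes: tuple[float, float, float]
    y_planes: tuple[float, float, float]
    z_planes: tuple[float, float]
    space_tag: str = "MNI"

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_planes", tuple(float(v) for v in self.x_planes))
        object.__setattr__(self, "y_planes", tuple(float(v) for v in self.y_planes))
        object.__setattr__(self, "z_planes", tuple(float(v) for v in self.z_planes))
        if len(self.x_planes) != 3 or len(self.y_planes) != 3 or len(self.z_planes) != 2:
            raise ValueError("expected 3 x-planes, 3 y-planes and 2 z-planes")
        for name, planes in (("x_planes", self.x_planes),
                             ("y_planes", self.y_planes),
                             ("z_planes", self.z_planes)):
            if not all(np.isfinite(planes)):
                raise ValueError(f"{name} must be finite, got {planes}")
            if not all(a > b for a, b in zip(planes, planes[1:])):
                raise ValueError(f"{name} must be strictly decreasing, got {planes}")
        if self.space_tag not in _SPACE_TAGS:
            raise ValueError(
                f"unknown space_tag {self.space_tag!r}; valid tags: {', '.join(_SPACE_TAGS)}"
            )

    def to_dict(self) -> dict:
        return {
            "space_tag": self.space_tag,
            "x_planes": list(self.x_planes),
            "y_planes": list(self.y_planes),
            "z_planes": list(self.z_planes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridPlanes":
        try:
            return cls(
                x_planes=tuple(d["x_planes"]),
                y_planes=tuple(d["y_planes"]),
                z_planes=tuple(d["z_planes"]),
                space_tag=d.get("space_tag", "subject"),
            )
        except KeyError as exc:
            raise ValueError(f"plane override document missing key {exc}") from None

    @classmethod
    def from_json(cls, path) -> "GridPlanes":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: Landmark plane constants in MNI space (world mm, RAS+).
MNI_PLANES = GridPlanes(
    x_planes=(33.0, 0.0, -33.0),
    y_planes=(28.0, -23.0, -68.0),
    z_planes=(33.0, -13.0),
    space_tag="MNI",
)

#: The same landmarks expressed in Talairach coordinates.
TALAIRACH_PLANES = GridPlanes(
    x_planes=(32.0, 0.0, -32.0),
    y_planes=(25.0, -24.0, -66.0),
    z_planes=(31.0, -7.0),
    space_tag="Talairach",
)

_LABEL_RE = re.compile(r"^A(\d+)-?C(\d+)-?S(\d+)$", re.IGNORECASE)


@dataclass(frozen=True, order=True)
class GridLabel:
    """One of the 48 Brain-Grid cells, coded (A, C, S)."""

    a: int
    c: int
    s: int

    def __post_init__(self) -> None:
        for name, value, hi in (("a", self.a, 4), ("c", self.c, 3), ("s", self.s, 4)):
            if not isinstance(value, (int, np.integer)) or not 1 <= value <= hi:
                raise ValueError(f"{name.upper()} index {value!r} out of range 1..{hi}")
        object.__setattr__(self, "a", int(self.a))
        object.__setattr__(self, "c", int(self.c))
        object.__setattr__(self, "s", int(self.s))

    def __str__(self) -> str:
        return f"A{self.a}C{self.c}S{self.s}"

    def __repr__(self) -> str:
        return f"GridLabel({self})"

    @property
    def id(self) -> int:
        """Integer cell ID in 1..48: ``(a-1)*12 + (c-1)*4 + s``.

        Fixed so that exported labelmaps are bit-stable across versions.
        """
        return (self.a - 1) * 12 + (self.c - 1) * 4 + self.s

    @classmethod
    def from_id(cls, cell_id: int) -> "GridLabel":
        if not 1 <= int(cell_id) <= 48:
            raise ValueError(f"cell id {cell_id!r} outside 1..48")
        i = int(cell_id) - 1
        return cls(a=i // 12 + 1, c=(i % 12) // 4 + 1, s=i % 4 + 1)

    @classmethod
    def parse(cls, text: str) -> "GridLabel":
        """Parse ``"A3C2S2"`` or ``"A3-C2-S2"`` (case-insensitive)."""
        m = _LABEL_RE.match(text.strip())
        if m is None:
            raise ValueError(f"malformed grid label {text!r}; expected e.g. 'A3C2S2'")
        return cls(a=int(m.group(1)), c=int(m.group(2)), s=int(m.group(3)))

    def mirror(self) -> "GridLabel":
        """Reflect across the midline: A index maps a -> 5-a; C, S unchanged.

        Used for the contralateral-landmark fallback when a tumor infiltrates
        or dislocates the landmarks on one side.
        """
        return GridLabel(a=5 - self.a, c=self.c, s=self.s)

    def neighbors(self) -> frozenset["GridLabel"]:
        """Face-adjacent cells in the 4x3x4 lattice (+-1 on exactly one axis).

        Midline adjacency A2<->A3 is included by construction, matching the
        trans-callosal spread routes of interest.
        """
        out = []
        for da, dc, ds in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            a, c, s = self.a + da, self.c + dc, self.s + ds
            if 1 <= a <= 4 and 1 <= c <= 3 and 1 <= s <= 4:
                out.append(GridLabel(a, c, s))
        return frozenset(out)

    @property
    def side(self) -> str:
        """``"right"`` for A1/A2 (radiological right), ``"left"`` for A3/A4."""
        return "right" if self.a <= 2 else "left"


def parse_label(text: str) -> GridLabel:
    """Module-level alias for :meth:`GridLabel.parse`."""
    return GridLabel.parse(text)


@dataclass(frozen=True)
class BrainGrid:
    """A Brain-Grid instance: landmark planes plus the 48-cell enumeration."""

    planes: GridPlanes = field(default_factory=lambda: MNI_PLANES)

    @property
    def space_tag(self) -> str:
        return self.planes.space_tag

    @property
    def n_cells(self) -> int:
        return 48

    @property
    def cells(self) -> tuple[GridLabel, ...]:
        """All 48 labels in cell-ID order."""
        return tuple(GridLabel.from_id(i) for i in range(1, 49))

    def __iter__(self) -> Iterator[GridLabel]:
        return iter(self.cells)

    def label_point(self, point: Sequence[float]) -> GridLabel:
        """Classify a single world-mm point into its grid cell.

        A increases as x decreases, C as z decreases, S as y decreases.
        A point exactly on a plane goes to the lower-index slab.
        """
        p = np.asarray(point, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError(f"point must be 3 finite world-mm coordinates, got {point!r}")
        x, y, z = p
        a = 1 + sum(x < v for v in self.planes.x_planes)
        c = 1 + sum(z < v for v in self.planes.z_planes)
        s = 1 + sum(y < v for v in self.planes.y_planes)
        return GridLabel(a=a, c=c, s=s)

    def label_points(self, points: np.ndarray) -> np.ndarray:
        """Vectorized classification of an (N, 3) array of world-mm points.

        Returns the (N,) int array of cell IDs (1..48).
        """
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"expected an (N, 3) array, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        a = np.ones(len(pts), dtype=np.int64)
        c = np.ones(len(pts), dtype=np.int64)
        s = np.ones(len(pts), dtype=np.int64)
        for v in self.planes.x_planes:
            a += x < v
        for v in self.planes.z_planes:
            c += z < v
        for v in self.planes.y_planes:
            s += y < v
        return (a - 1) * 12 + (c - 1) * 4 + s

    def plane_items(self) -> list[tuple[str, str, float]]:
        """The eight planes as (name, axis, world-mm value) triples.

        Names encode axis and value, e.g. ``"x+33"``, ``"y-68"``.
        """
        items: list[tuple[str, str, float]] = []
        for axis, values in (("x", self.planes.x_planes),
                             ("y", self.planes.y_planes),
                             ("z", self.planes.z_planes)):
            for v in values:
                items.append((f"{axis}{v:+g}", axis, v))
        return items


def build_default_grid(space_tag: str = "MNI") -> BrainGrid:
    """Build the Brain-Grid with the published landmark constants.

    ``space_tag`` must be ``"MNI"`` or ``"Talairach"``; the two constant sets
    are shipped as printed (no coordinate conversion is computed here).
    """
    if space_tag == "MNI":
        return BrainGrid(planes=MNI_PLANES)
    if space_tag == "Talairach":
        return BrainGrid(planes=TALAIRACH_PLANES)
    raise ValueError(
        f"unknown space_tag {space_tag!r}; valid tags: MNI, Talairach"
    )
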
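"""Synthetic lesion phantoms: bulky ellipsoids, digitated diffuse shapes,
and nested longitudinal growth series in MNI space.

The generator emulates the two margin phenotypes of low-grade glioma
hyperintensity: *bulky* lesions are plain ellipsoids with optional boundary
jitter, *diffuse* lesions add capsule-shaped digitations (finger-like
extensions along white-matter directions).  Growth series stack translated
and dilated lesions cumulatively so each study's mask is nested in the next,
mimicking slow continuous infiltration across serial MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .image_io import ReferenceGeometry, VolumeMask

__all__ = [
    "Digitation",
    "LesionSpec",
    "make_ellipsoid_lesion",
    "make_diffuse_lesion",
    "make_growth_series",
]


@dataclass(frozen=True)
class Digitation:
    """One finger-like extension: a capsule along ``direction``."""

    direction: tuple[float, float, float]
    length_mm: float
    radius_mm: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("digitation direction must be a non-zero vector")
        object.__setattr__(self, "direction", tuple(d / norm))
        if self.length_mm < 0 or self.radius_mm <= 0:
            raise ValueError("digitation length must be >= 0 and radius > 0")


@dataclass(frozen=True)
class LesionSpec:
    """Geometric description of one synthetic lesion."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    digitations: tuple[Digitation, ...] = ()
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        center = tuple(float(v) for v in self.center)
        radii = tuple(float(v) for v in self.radii)
        if len(center) != 3 or not all(np.isfinite(center)):
            raise ValueError("center must be 3 finite world-mm coordinates")
        if len(radii) != 3 or any(r <= 0 for r in radii):
            raise ValueError("radii must be 3 positive semi-axes in mm")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must lie in [0, 1]")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "digitations", tuple(self.digitations))

    def shifted(self, delta: Sequence[float]) -> "LesionSpec":
        return LesionSpec(
            center=tuple(np.asarray(self.center) + np.asarray(delta, dtype=float)),
            radii=self.radii,
            digitations=self.digitations,
            noise_fraction=self.noise_fraction,
            seed=self.seed,
        )

    def dilated(self, extra_mm: float) -> "LesionSpec":
        return LesionSpec(
            center=self.center,
            radii=tuple(r + extra_mm for r in self.radii),
            digitations=self.digitations,
            noise_fraction=self.noise_fraction,
            seed=self.seed,
        )


def _extent(spec: LesionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Conservative world-space bounding box of the lesion."""
    c = np.asarray(spec.center)
    r = np.asarray(spec.radii)
    lo, hi = c - r, c + r
    for d in spec.digitations:
        tip = c + np.asarray(d.direction) * d.length_mm
        lo = np.minimum(lo, tip - d.radius_mm)
        hi = np.maximum(hi, tip + d.radius_mm)
    return lo, hi


def _check_fov(spec: LesionSpec, geometry: ReferenceGeometry) -> None:
    centers = geometry.voxel_centers()
    fov_lo, fov_hi = centers.min(axis=0), centers.max(axis=0)
    lo, hi = _extent(spec)
    if np.any(lo < fov_lo) or np.any(hi > fov_hi):
        raise ValueError(
            f"lesion extent [{lo}, {hi}] exceeds the field of view "
            f"[{fov_lo}, {fov_hi}]"
        )


def _fill(spec: LesionSpec, geometry: ReferenceGeometry) -> np.ndarray:
    """Boolean foreground over geometry voxel centers (no jitter)."""
    pts = geometry.voxel_centers()
    c = np.asarray(spec.center)
    r = np.asarray(spec.radii)
    inside = np.sum(((pts - c) / r) ** 2, axis=1) <= 1.0
    for d in spec.digitations:
        axis = np.asarray(d.direction)
        rel = pts - c
        t = np.clip(rel @ axis, 0.0, d.length_mm)
        dist = np.linalg.norm(rel - t[:, None] * axis[None, :], axis=1)
        inside |= dist <= d.radius_mm
    return inside.reshape(geometry.shape)


def _jitter(data: np.ndarray, noise_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Flip a random subset of boundary voxels (both erosion and accretion)."""
    if noise_fraction == 0 or not data.any():
        return data
    from scipy import ndimage

    surface_in = data & ~ndimage.binary_erosion(data)
    surface_out = ndimage.binary_dilation(data) & ~data
    out = data.copy()
    for surface in (surface_in, surface_out):
        idx = np.argwhere(surface)
        if len(idx) == 0:
            continue
        flip = rng.random(len(idx)) < noise_fraction
        sel = idx[flip]
        out[sel[:, 0], sel[:, 1], sel[:, 2]] ^= True
    return out


def make_ellipsoid_lesion(spec: LesionSpec, geometry: ReferenceGeometry) -> VolumeMask:
    """Bulky phenotype: voxel centers inside the ellipsoid are foreground.

    Boundary jitter flips a ``noise_fraction`` share of surface voxels under
    the spec's seed, so identical specs give identical masks.
    """
    _check_fov(spec, geometry)
    rng = np.random.default_rng(spec.seed)
    data = _jitter(_fill(LesionSpec(spec.center, spec.radii, (), 0.0, spec.seed),
                         geometry),
                   spec.noise_fraction, rng)
    return VolumeMask(data=data, affine=geometry.affine.copy())


def make_diffuse_lesion(spec: LesionSpec, geometry: ReferenceGeometry) -> VolumeMask:
    """Diffuse phenotype: the core ellipsoid plus capsule digitations."""
    _check_fov(spec, geometry)
    rng = np.random.default_rng(spec.seed)
    data = _jitter(_fill(spec, geometry), spec.noise_fraction, rng)
    return VolumeMask(data=data, affine=geometry.affine.copy())


def make_growth_series(
    initial: LesionSpec,
    growth_vector_mm: Sequence[float],
    n_steps: int,
    geometry: ReferenceGeometry,
    radius_growth_mm: float = 1.0,
) -> list[VolumeMask]:
    """Nested longitudinal series emulating slow continuous progression.

    Step ``k`` translates the lesion by ``k * growth_vector_mm`` and dilates
    its radii by ``k * radius_growth_mm``; each study's mask is the union of
    all lesions up to that step, so the series is nested by construction.
    Growth that leaves the field of view is rejected at the offending step.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    growth = np.asarray(growth_vector_mm, dtype=float)
    if growth.shape != (3,) or not np.all(np.isfinite(growth)):
        raise ValueError("growth_vector_mm must be 3 finite mm components")
    masks: list[VolumeMask] = []
    acc = np.zeros(geometry.shape, dtype=bool)
    for k in range(n_steps):
        step_spec = initial.shifted(k * growth).dilated(k * radius_growth_mm)
        try:
            _check_fov(step_spec, geometry)
        except ValueError as exc:
            raise ValueError(f"growth step {k}: {exc}") from None
        rng = np.random.default_rng((initial.seed, k))
        acc = acc | _jitter(_fill(step_spec, geometry), initial.noise_fraction, rng)
        masks.append(VolumeMask(data=acc.copy(), affine=geometry.affine.copy()))
    return masks
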
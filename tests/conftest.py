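import numpy as np
import pytest

from braingrid import (
    BrainGrid,
    GridLabel,
    LesionSpec,
    build_default_grid,
    make_ellipsoid_lesion,
    make_reference_geometry,
)


@pytest.fixture(scope="session")
def mni_grid() -> BrainGrid:
    return build_default_grid("MNI")


@pytest.fixture(scope="session")
def geometry():
    """2 mm isotropic MNI-centered test geometry (91x109x91)."""
    return make_reference_geometry((91, 109, 91), 2.0)


@pytest.fixture(scope="session")
def small_geometry():
    """Coarse 4 mm geometry for fast property tests."""
    return make_reference_geometry((46, 55, 46), 4.0)


@pytest.fixture
def ball_mask(geometry):
    """5 mm-radius ball at MNI (-10, 0, 0): lies strictly inside A3C2S2."""
    spec = LesionSpec(center=(-10.0, 0.0, 0.0), radii=(5.0, 5.0, 5.0))
    return make_ellipsoid_lesion(spec, geometry)


def brute_force_label(point, grid: BrainGrid) -> GridLabel:
    """Independent oracle: test each of the 48 cells' half-open intervals.

    Slab bounds are rebuilt explicitly from the plane lists with +/-inf
    sentinels; a cell claims the point when low <= coord < high on every
    axis, with the planes as upper (exclusive) bounds toward increasing
    slab index.  Kept free of any call into the grid's own labeling path.
    """
    x, y, z = point

    def slabs(planes):
        edges = [np.inf] + list(planes) + [-np.inf]
        return [(edges[i + 1], edges[i]) for i in range(len(edges) - 1)]

    matches = []
    for a, (xlo, xhi) in enumerate(slabs(grid.planes.x_planes), start=1):
        for c, (zlo, zhi) in enumerate(slabs(grid.planes.z_planes), start=1):
            for s, (ylo, yhi) in enumerate(slabs(grid.planes.y_planes), start=1):
                # each slab is [low, high): the lower-index slab keeps its plane
                if xlo <= x < xhi and zlo <= z < zhi and ylo <= y < yhi:
                    matches.append(GridLabel(a, c, s))
    assert len(matches) == 1, f"point {point} matched {matches}"
    return matches[0]
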
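import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import treestatics as ts

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_tree():
    """13-beam / 42-node / 44-section synthetic tree with a hollow trunk span."""
    return ts.generate_tree(ts.PAPER_LIKE)


@pytest.fixture(scope="session")
def wind33():
    return ts.WindSpec(velocity=33.0, exposed_area=71.14)


@pytest.fixture()
def cantilever():
    return ts.minimal_cantilever(length=10.0, radius=0.15, E=10e9)


def raster_moments(ring, holes=(), resolution=4096):
    """Independent pixel-integration oracle for polygon section properties.

    Rasterizes the polygon (holes subtracted) on a resolution² grid over
    its bounding box with matplotlib's point-in-polygon test and
    accumulates area / centroid / second moments by pixel sums.
    """
    from matplotlib.path import Path as MplPath

    ring = np.asarray(ring, float)
    lo = ring.min(axis=0) - 1e-9
    hi = ring.max(axis=0) + 1e-9
    ny = nx = resolution
    dy = (hi[0] - lo[0]) / nx
    dz = (hi[1] - lo[1]) / ny
    ys = lo[0] + (np.arange(nx) + 0.5) * dy
    zs = lo[1] + (np.arange(ny) + 0.5) * dz
    outer = MplPath(ring)
    hole_paths = [MplPath(np.asarray(h, float)) for h in holes]
    px = dy * dz
    area = 0.0
    sy = sz = iy = iz = iyz = 0.0
    chunk = 256
    for i0 in range(0, ny, chunk):
        zz = zs[i0:i0 + chunk]
        Y, Z = np.meshgrid(ys, zz)
        pts = np.c_[Y.ravel(), Z.ravel()]
        inside = outer.contains_points(pts)
        for hp in hole_paths:
            inside &= ~hp.contains_points(pts)
        y, z = pts[inside, 0], pts[inside, 1]
        n = inside.sum()
        area += n * px
        sy += y.sum() * px
        sz += z.sum() * px
        iy += (z**2).sum() * px
        iz += (y**2).sum() * px
        iyz += (y * z).sum() * px
    cy, cz = sy / area, sz / area
    return {
        "area": area, "centroid": (cy, cz),
        "Iy": iy - area * cz**2, "Iz": iz - area * cy**2,
        "Iyz": iyz - area * cy * cz,
    }
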
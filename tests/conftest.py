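"""Shared fixtures and independent oracles for the test suite.

The dense projector oracle computes ray-pixel intersection lengths by
Liang-Barsky slab clipping of each ray against each pixel rectangle —
a completely separate route from the package's vectorized footprint
construction — so agreement checks are genuine cross-validation.
"""

from __future__ import annotations

import numpy as np
import pytest

from osemeat.phantom_geometry import (
    ImageGrid,
    ProjectionGeometry,
    generate_shepp_logan,
    make_geometry,
)
from osemeat.projector import SystemMatrix, build_system_matrix


def line_rect_length(
    ox: float, oy: float, vx: float, vy: float,
    x0: float, x1: float, y0: float, y1: float,
) -> float:
    """Length of the chord a unit-direction line (origin o, direction v)
    cuts from the rectangle [x0,x1] x [y0,y1] (slab clipping)."""
    tmin, tmax = -np.inf, np.inf
    for o, v, lo, hi in ((ox, vx, x0, x1), (oy, vy, y0, y1)):
        if abs(v) < 1e-15:
            if o < lo or o > hi:
                return 0.0
        else:
            t1, t2 = (lo - o) / v, (hi - o) / v
            if t1 > t2:
                t1, t2 = t2, t1
            tmin, tmax = max(tmin, t1), min(tmax, t2)
    return max(tmax - tmin, 0.0)


def dense_system_matrix(geometry: ProjectionGeometry, grid: ImageGrid) -> np.ndarray:
    """Brute-force dense q_ij by per-ray, per-pixel rectangle clipping."""
    nr, nc = grid.values.shape
    s = grid.pixel_size
    x, y = grid.pixel_centers()
    x, y = x.ravel(), y.ravel()
    dets = geometry.detector_positions()
    A = np.zeros((geometry.n_rays, x.size))
    for a_idx, ang in enumerate(geometry.angles_deg):
        th = np.deg2rad(ang)
        ux, uy = np.cos(th), np.sin(th)  # detector axis
        vx, vy = -np.sin(th), np.cos(th)  # ray direction
        for d_idx, t in enumerate(dets):
            ox, oy = t * ux, t * uy
            i = a_idx * geometry.n_detectors + d_idx
            for j in range(x.size):
                A[i, j] = line_rect_length(
                    ox, oy, vx, vy,
                    x[j] - s / 2, x[j] + s / 2,
                    y[j] - s / 2, y[j] + s / 2,
                )
    return A


@pytest.fixture(scope="session")
def phantom64() -> ImageGrid:
    return generate_shepp_logan(64)


@pytest.fixture(scope="session")
def small_system() -> tuple[ProjectionGeometry, ImageGrid, SystemMatrix]:
    """8x8 grid, 5 views, 12 detector bins — small enough for dense oracles."""
    grid = ImageGrid(np.zeros((8, 8)))
    geom = make_geometry(36.0, 180.0, 12)
    return geom, grid, build_system_matrix(geom, grid)


@pytest.fixture(scope="session")
def scaled_recon_setup(phantom64):
    """64x64 phantom, 60 views at 3 degrees: the scaled reconstruction bench."""
    from osemeat.phantom_geometry import default_detector_count
    from osemeat.projector import forward_project

    geom = make_geometry(3.0, 180.0, default_detector_count(64))
    A = build_system_matrix(geom, phantom64)
    y = forward_project(A, phantom64)
    return phantom64, geom, A, y
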
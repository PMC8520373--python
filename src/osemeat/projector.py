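"""Sparse parallel-beam projector: system matrix and forward projection.

The system matrix holds one weight q_ij per (ray i, pixel j) pair, equal
to the length of the intersection of the ray's line with the pixel
square (the exact line-integral footprint, as produced by Siddon-style
ray tracing).  For a parallel beam the intersection length of a line at
angle theta with a pixel depends only on the signed perpendicular
distance between the line and the pixel center, which makes the trace
fully vectorizable per view: every pixel is projected onto the detector
axis and contributes to the two or three detector bins whose rays pass
within its footprint.

Rays are indexed view-major: ray ``i = angle_index * n_detectors +
detector_index``.  Weights are unnormalized intersection lengths; the EM
update divides by the per-pixel sensitivity, so any global scale cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .phantom_geometry import GeometryError, ImageGrid, ProjectionGeometry


class CoverageError(GeometryError):
    """Detector array too narrow to cover the image at every angle."""


@dataclass
class SystemMatrix:
    """Sparse ray-pixel weights shared by the MLEM and OSEM updates."""

    weights: sp.csr_matrix  # shape (n_rays, n_pixels)
    geometry: ProjectionGeometry
    image_shape: tuple[int, int]
    pixel_size: float = 1.0

    @property
    def n_rays(self) -> int:
        return self.weights.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.weights.shape[1]

    def ray_to_angle(self, ray_index: int) -> int:
        return ray_index // self.geometry.n_detectors

    def rays_for_angles(self, angle_indices: Sequence[int]) -> np.ndarray:
        """Row indices of all rays belonging to the given views, view-major."""
        nd = self.geometry.n_detectors
        idx = np.asarray(angle_indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.geometry.n_angles):
            raise IndexError("angle index out of range")
        return (idx[:, None] * nd + np.arange(nd)[None, :]).ravel()

    def save_npz(self, path) -> None:
        sp.save_npz(path, self.weights)


@dataclass
class Sinogram:
    """Line-integral data y_i for every ray of a projection geometry."""

    values: np.ndarray
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.geometry.n_rays:
            raise ValueError("sinogram length does not match geometry ray count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")

    def per_angle(self) -> np.ndarray:
        """View as an (n_angles, n_detectors) array."""
        g = self.geometry
        return self.values.reshape(g.n_angles, g.n_detectors)

    def to_csv(self, path) -> None:
        """One row per view angle, one column per detector bin."""
        df = pd.DataFrame(
            self.per_angle(),
            index=pd.Index(self.geometry.angles_deg, name="angle_deg"),
            columns=np.arange(self.geometry.n_detectors),
        )
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, geometry: ProjectionGeometry) -> "Sinogram":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float).ravel(), geometry)


def _chord_lengths(offsets: np.ndarray, theta_rad: float, s: float) -> np.ndarray:
    """Length of the chord cut from an s-sided square by a line at angle
    ``theta`` whose perpendicular distance from the square center is
    ``offsets``.  Piecewise linear: a trapezoid of half-width
    s*(|cos|+|sin|)/2 with plateau s/max(|cos|,|sin|)."""
    c = abs(np.cos(theta_rad))
    sn = abs(np.sin(theta_rad))
    if min(c, sn) < 1e-12:
        # axis-aligned: box profile with a half-open boundary convention,
        # so a ray running exactly along a pixel edge is assigned to the
        # pixel on its left (keeps coverage and mass for even-sized grids)
        return np.where((offsets >= -0.5 * s) & (offsets < 0.5 * s), s, 0.0)
    half_width = 0.5 * s * (c + sn)
    plateau = s / max(c, sn)
    ell = (half_width - np.abs(offsets)) / (c * sn)
    return np.clip(ell, 0.0, plateau)


def build_system_matrix(geometry: ProjectionGeometry, grid: ImageGrid) -> SystemMatrix:
    """Trace every ray through the pixel grid and assemble q_ij.

    Raises :class:`CoverageError` if the detector array is narrower than
    the image diagonal (some pixels would be invisible at some angle).
    """
    nr, nc = grid.values.shape
    s = grid.pixel_size
    diagonal = s * float(np.hypot(nr, nc))
    det_width = geometry.n_detectors * geometry.detector_spacing
    if det_width < diagonal:
        raise CoverageError(
            f"detector width {det_width:.1f} < image diagonal {diagonal:.1f}"
        )

    x, y = grid.pixel_centers()
    x = x.ravel()
    y = y.ravel()
    pix = np.arange(x.size)
    nd = geometry.n_detectors
    spacing = geometry.detector_spacing
    t0 = -(nd - 1) / 2.0 * spacing

    rows_all: list[np.ndarray] = []
    cols_all: list[np.ndarray] = []
    data_all: list[np.ndarray] = []
    for a_idx, ang in enumerate(geometry.angles_deg):
        theta = np.deg2rad(ang)
        # projection of pixel centers on the detector axis
        p = x * np.cos(theta) + y * np.sin(theta)
        w = 0.5 * s * (abs(np.cos(theta)) + abs(np.sin(theta)))
        k_lo = np.ceil((p - w - t0) / spacing).astype(np.int64)
        n_off = int(np.floor(2.0 * w / spacing)) + 1
        for off in range(n_off + 1):
            k = k_lo + off
            valid = (k >= 0) & (k < nd)
            if not valid.any():
                continue
            kv = k[valid]
            d = (t0 + kv * spacing) - p[valid]
            ell = _chord_lengths(d, theta, s)
            nz = ell > 0.0
            if not nz.any():
                continue
            rows_all.append((a_idx * nd + kv[nz]).astype(np.int64))
            cols_all.append(pix[valid][nz])
            data_all.append(ell[nz])

    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    data = np.concatenate(data_all)
    mat = sp.coo_matrix(
        (data, (rows, cols)), shape=(geometry.n_rays, x.size)
    ).tocsr()
    return SystemMatrix(
        weights=mat, geometry=geometry, image_shape=(nr, nc), pixel_size=s
    )


def forward_project(A: SystemMatrix, image: ImageGrid | np.ndarray) -> Sinogram:
    """Compute y_i = sum_j q_ij g_j for every ray."""
    g = image.values if isinstance(image, ImageGrid) else np.asarray(image, float)
    if g.size != A.n_pixels:
        raise ValueError(
            f"image has {g.size} pixels, system matrix expects {A.n_pixels}"
        )
    return Sinogram(A.weights @ g.ravel(), A.geometry)


def forward_project_subset(
    A: SystemMatrix, image: ImageGrid | np.ndarray, subset: Iterable[int]
) -> np.ndarray:
    """Projections restricted to the rays of the given view indices.

    Output is ordered view-major in the order the subset lists its
    angles; concatenating all subsets of a partition and reordering by
    ray index reproduces :func:`forward_project` exactly.
    """
    g = image.values if isinstance(image, ImageGrid) else np.asarray(image, float)
    if g.size != A.n_pixels:
        raise ValueError("image/pixel-count mismatch")
    rows = A.rays_for_angles(list(subset))
    if rows.size == 0:
        return np.empty(0, dtype=float)
    return A.weights[rows] @ g.ravel()
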
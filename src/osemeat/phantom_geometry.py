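"""Shepp-Logan phantom generation and parallel-beam projection geometry.

The phantom is the standard ten-ellipse head phantom rasterized on an
``n x n`` grid by evaluating the ellipse table at pixel centers.  The
contrast-adjusted (Toft) intensity table is used, so intensities span
exactly [0, 1]: the skull ring is 1.0, brain tissue 0.2, the ventricles
0.0 and the small tumours 0.3.

Geometry convention: the image is centered on the grid center, angle 0
sends rays parallel to the y-axis (projection onto the x-axis), and
angles increase counter-clockwise.  Parallel-beam projections are
redundant over 360 degrees, so geometries normally span [0, 180).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Raised for inconsistent projection-geometry parameters."""


#: (intensity, semi_x, semi_y, center_x, center_y, rotation_deg) in the
#: normalized [-1, 1] coordinate frame; contrast-adjusted table.
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


@dataclass
class EllipseSpec:
    """One additive ellipse of the phantom, in normalized coordinates."""

    center_xy: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_deg: float
    additive_intensity: float

    def __post_init__(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass
class ImageGrid:
    """A square pixel grid holding one intensity value per pixel.

    ``values`` has shape ``(n_rows, n_cols)``; row 0 is the top of the
    image (y decreases with row index).  ``pixel_size`` is the physical
    side length of a pixel in arbitrary length units.
    """

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ImageGrid requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.values.size

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of pixel centers, image centered at 0."""
        nr, nc = self.values.shape
        cols = np.arange(nc) - (nc - 1) / 2.0
        rows = (nr - 1) / 2.0 - np.arange(nr)
        x = np.broadcast_to(cols * self.pixel_size, (nr, nc))
        y = np.broadcast_to((rows * self.pixel_size)[:, None], (nr, nc))
        return x, y


@dataclass
class ProjectionGeometry:
    """Equally spaced parallel-beam view angles plus a linear detector."""

    angles_deg: np.ndarray
    angular_interval_deg: float
    n_detectors: int
    detector_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.ndim != 1 or self.angles_deg.size == 0:
            raise GeometryError("angles_deg must be a non-empty 1-D sequence")
        diffs = np.diff(self.angles_deg)
        if self.angles_deg.size > 1 and not np.allclose(
            diffs, self.angular_interval_deg, atol=1e-9
        ):
            raise GeometryError("angles must be equally spaced by the interval")
        if self.n_detectors < 1:
            raise GeometryError("n_detectors must be positive")
        if self.detector_spacing <= 0:
            raise GeometryError("detector_spacing must be positive")

    @property
    def n_angles(self) -> int:
        return int(self.angles_deg.size)

    @property
    def n_rays(self) -> int:
        return self.n_angles * self.n_detectors

    def detector_positions(self) -> np.ndarray:
        """Signed detector-bin center coordinates, centered on the rotation axis."""
        k = np.arange(self.n_detectors) - (self.n_detectors - 1) / 2.0
        return k * self.detector_spacing

    def to_dict(self) -> dict:
        return {
            "interval_deg": self.angular_interval_deg,
            "span_deg": self.angular_interval_deg * self.n_angles,
            "n_detectors": self.n_detectors,
            "detector_spacing": self.detector_spacing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionGeometry":
        return make_geometry(
            d["interval_deg"],
            d["span_deg"],
            d["n_detectors"],
            detector_spacing=d.get("detector_spacing", 1.0),
        )


def generate_shepp_logan(n: int, pixel_size: float = 1.0) -> ImageGrid:
    """Rasterize the standard Shepp-Logan phantom on an ``n x n`` grid.

    Each pixel takes the sum of the intensities of the ellipses whose
    interior contains its center; the result is clipped to be
    non-negative.

    Parameters
    ----------
    n:
        Grid side length in pixels (at least 16).
    pixel_size:
        Physical pixel side length attached to the returned grid.
    """
    if n < 16:
        raise ValueError(f"phantom grid must be at least 16x16, got {n}")
    coords = (np.arange(n) - (n - 1) / 2.0) / (n / 2.0)
    x = coords[None, :]
    y = -coords[:, None]  # row 0 at the top
    img = np.zeros((n, n), dtype=float)
    for inten, sx, sy, cx, cy, rot in SHEPP_LOGAN_ELLIPSES:
        phi = math.radians(rot)
        dx = x - cx
        dy = y - cy
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        img += np.where((u / sx) ** 2 + (v / sy) ** 2 <= 1.0, inten, 0.0)
    np.clip(img, 0.0, None, out=img)
    return ImageGrid(img, pixel_size=pixel_size)


def default_detector_count(n: int) -> int:
    """Smallest odd detector count covering the diagonal of an n x n grid."""
    m = math.ceil(n * math.sqrt(2.0))
    return m if m % 2 == 1 else m + 1


def make_geometry(
    interval_deg: float,
    span_deg: float,
    n_detectors: int,
    detector_spacing: float = 1.0,
) -> ProjectionGeometry:
    """Build an equally spaced view-angle set ``{0, d, 2d, ..., span - d}``.

    ``span_deg`` must be an integer multiple of ``interval_deg``; with a
    1-degree interval over a 180-degree span this yields 180 views.
    """
    if interval_deg <= 0:
        raise GeometryError("interval_deg must be positive")
    ratio = span_deg / interval_deg
    n_angles = round(ratio)
    if n_angles < 1 or abs(ratio - n_angles) > 1e-9:
        raise GeometryError(
            f"span {span_deg} is not an integer multiple of interval {interval_deg}"
        )
    angles = np.arange(n_angles) * interval_deg
    return ProjectionGeometry(
        angles_deg=angles,
        angular_interval_deg=float(interval_deg),
        n_detectors=int(n_detectors),
        detector_spacing=float(detector_spacing),
    )
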
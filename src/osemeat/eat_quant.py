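"""Epicardial adipose tissue (EAT) volumetry on CT volumes.

Fat is segmented by Hounsfield-unit thresholding inside an axial slice
range.  The default window is -150..-50 HU, the standard CT fat window;
the slice range stands in for the manual anatomical bounds (origin of
the left pulmonary artery down to the left-ventricular apex) that a
reader marks on a workstation.  Volume is voxel count times voxel
volume, reported in millilitres.

A synthetic torso generator provides volumes with a known ground-truth
fat voxel count: a soft-tissue ellipsoid (+40 HU) containing an
ellipsoidal fat shell (-100 HU) against air (-1000 HU), with optional
Gaussian HU noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np


@dataclass
class FatWindow:
    """Inclusive HU interval treated as adipose tissue."""

    hu_low: float = -150.0
    hu_high: float = -50.0

    def __post_init__(self) -> None:
        if self.hu_low >= self.hu_high:
            raise ValueError("hu_low must be below hu_high")


@dataclass
class SliceBounds:
    """Inclusive axial slice range over which fat is counted."""

    start_slice: int
    end_slice: int

    def __post_init__(self) -> None:
        if self.start_slice < 0 or self.end_slice < self.start_slice:
            raise ValueError("require 0 <= start_slice <= end_slice")


@dataclass
class CTVolume:
    """A 3-D Hounsfield-unit array with voxel spacing in millimetres."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axial_axis: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume requires a 3-D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.axial_axis not in (0, 1, 2):
            raise ValueError("axial_axis must be 0, 1 or 2")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[self.axial_axis]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz


@dataclass
class EATMeasurement:
    volume_ml: float
    voxel_count: int
    window: FatWindow
    bounds: SliceBounds


def load_ct_volume(path) -> CTVolume:
    """Read a NIfTI volume; slice axis is the last (z) axis by convention."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(voxels=data, spacing_mm=zooms, axial_axis=2)


def segment_fat(
    volume: CTVolume, window: FatWindow, bounds: SliceBounds
) -> np.ndarray:
    """Boolean mask: HU within the fat window AND slice within bounds."""
    if bounds.end_slice >= volume.n_slices:
        raise ValueError(
            f"end_slice {bounds.end_slice} outside volume with "
            f"{volume.n_slices} slices"
        )
    mask = (volume.voxels >= window.hu_low) & (volume.voxels <= window.hu_high)
    slice_idx = np.arange(volume.n_slices)
    in_bounds = (slice_idx >= bounds.start_slice) & (slice_idx <= bounds.end_slice)
    shape = [1, 1, 1]
    shape[volume.axial_axis] = volume.n_slices
    return mask & in_bounds.reshape(shape)


def measure_eat(
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
    window: FatWindow | None = None,
    bounds: SliceBounds | None = None,
) -> EATMeasurement:
    """Convert a fat mask into a volume in mL (1 mL = 1000 mm^3)."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("voxel spacing must be positive")
    count = int(mask.sum())
    voxel_mm3 = spacing_mm[0] * spacing_mm[1] * spacing_mm[2]
    return EATMeasurement(
        volume_ml=count * voxel_mm3 / 1000.0,
        voxel_count=count,
        window=window or FatWindow(),
        bounds=bounds or SliceBounds(0, max(mask.shape[0] - 1, 0)),
    )


def average_measurements(a: EATMeasurement, b: EATMeasurement) -> EATMeasurement:
    """Two-reader average, mirroring the dual-observer workstation protocol."""
    return EATMeasurement(
        volume_ml=0.5 * (a.volume_ml + b.volume_ml),
        voxel_count=round(0.5 * (a.voxel_count + b.voxel_count)),
        window=a.window,
        bounds=a.bounds,
    )


def generate_synthetic_ct(
    n_slices: int = 40,
    slice_shape: tuple[int, int] = (64, 64),
    fat_fraction: float = 0.15,
    noise_sd_hu: float = 0.0,
    seed: int = 0,
) -> tuple[CTVolume, int]:
    """Torso-like test volume with a known pericardial-fat voxel count.

    The body is a soft-tissue ellipsoid at +40 HU filling most of the
    field of view; a concentric ellipsoidal shell at -100 HU emulates
    the fat sac, its thickness chosen so the shell holds approximately
    ``fat_fraction`` of the body voxels; the background is air at
    -1000 HU.  Gaussian noise with sd ``noise_sd_hu`` is added on top.
    Returns the volume and the exact shell voxel count.
    """
    if not (0.0 < fat_fraction < 1.0):
        raise ValueError("fat_fraction must lie in (0, 1)")
    if n_slices < 4 or min(slice_shape) < 8:
        raise ValueError("volume too small for a torso model")
    rng = np.random.default_rng(seed)
    nz, (ny, nx) = n_slices, slice_shape
    z, y, x = np.meshgrid(
        np.linspace(-1, 1, nz),
        np.linspace(-1, 1, ny),
        np.linspace(-1, 1, nx),
        indexing="ij",
    )
    r2 = (z / 0.9) ** 2 + (y / 0.85) ** 2 + (x / 0.85) ** 2
    body = r2 <= 1.0
    # shell of relative radius [r_in, 1): volume fraction 1 - r_in^3
    r_in = (1.0 - fat_fraction) ** (1.0 / 3.0)
    shell = body & (r2 > r_in**2)
    hu = np.full((nz, ny, nx), -1000.0)
    hu[body] = 40.0
    hu[shell] = -100.0
    truth_count = int(shell.sum())
    if noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, noise_sd_hu, hu.shape)
    return CTVolume(voxels=hu, spacing_mm=(1.0, 1.0, 1.0), axial_axis=0), truth_count
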
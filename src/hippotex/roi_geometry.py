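"""Circular and spherical ROI masks around a seed voxel.

A 2D ROI is a disc of voxels in one slice (the coronal slice, by default);
a 3D ROI is a ball. Distances are Euclidean between voxel centers, measured
in voxel units on all axes (slice thickness is not corrected for), and the
boundary is inclusive: a voxel belongs to the ROI iff its center lies within
``radius_vox`` of the seed. ROIs that would be clipped by the volume edge are
refused rather than truncated, because a truncated ROI silently changes every
downstream statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import MaskFormatError, ParameterError, RoiOutOfBoundsError


@dataclass
class RoiMask:
    """Boolean ROI mask aligned to a parent volume grid."""

    mask: np.ndarray
    shape_kind: str  # "circle2d" | "sphere3d" | "external"
    center: tuple[int, int, int] | None = None
    radius_vox: float | None = None
    slice_axis: int | None = None  # fixed axis for circle2d

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise MaskFormatError("ROI mask must be a 3D boolean grid")
        if not self.mask.any():
            raise MaskFormatError("ROI mask has no true voxel")
        if self.shape_kind not in ("circle2d", "sphere3d", "external"):
            raise ParameterError(f"unknown shape_kind {self.shape_kind!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _check_center(vol_shape, center) -> tuple[int, int, int]:
    center = tuple(int(c) for c in center)
    if len(center) != 3 or len(vol_shape) != 3:
        raise ParameterError("vol_shape and center must have 3 components")
    for c, n in zip(center, vol_shape):
        if not (0 <= c < n):
            raise RoiOutOfBoundsError(f"center {center} outside grid {tuple(vol_shape)}")
    return center


def _check_fits(vol_shape, center, radius: float, axes) -> None:
    reach = math.floor(radius)
    for a in axes:
        if center[a] - reach < 0 or center[a] + reach > vol_shape[a] - 1:
            raise RoiOutOfBoundsError(
                f"ROI of radius {radius} at {center} clipped by grid {tuple(vol_shape)} "
                f"along axis {a}; partial ROIs are refused"
            )


def circular_mask(
    vol_shape, center, radius_vox: float, slice_axis: int = 1
) -> RoiMask:
    """Disc of voxels in the slice ``center[slice_axis]``.

    True exactly for in-slice voxels whose center lies within ``radius_vox``
    (inclusive) of the seed, in voxel units over the two varying axes.
    """
    center = _check_center(vol_shape, center)
    if radius_vox <= 0:
        raise ParameterError("radius_vox must be positive")
    if slice_axis not in (0, 1, 2):
        raise ParameterError(f"slice_axis must be 0, 1 or 2, got {slice_axis}")
    varying = [a for a in range(3) if a != slice_axis]
    _check_fits(vol_shape, center, radius_vox, varying)
    grids = np.ogrid[tuple(slice(0, n) for n in vol_shape)]
    d2 = sum((grids[a] - center[a]) ** 2 for a in varying)
    mask = (d2 <= radius_vox**2) & (grids[slice_axis] == center[slice_axis])
    return RoiMask(mask, "circle2d", center, float(radius_vox), slice_axis)


def spherical_mask(vol_shape, center, radius_vox: float) -> RoiMask:
    """Ball of voxels whose centers lie within ``radius_vox`` of the seed."""
    center = _check_center(vol_shape, center)
    if radius_vox <= 0:
        raise ParameterError("radius_vox must be positive")
    _check_fits(vol_shape, center, radius_vox, range(3))
    grids = np.ogrid[tuple(slice(0, n) for n in vol_shape)]
    d2 = sum((grids[a] - center[a]) ** 2 for a in range(3))
    return RoiMask(d2 <= radius_vox**2, "sphere3d", center, float(radius_vox))


def concentric_rois(
    vol_shape, center, radii=(3.0, 5.0, 8.0), slice_axis: int = 1
) -> tuple[list[RoiMask], list[RoiMask]]:
    """Concentric discs and balls sharing one seed.

    Returns ``(circles, spheres)``, one of each per radius, so the default
    three radii yield the six ROIs analyzed per hippocampus.
    """
    radii = [float(r) for r in radii]
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ParameterError(f"radii must be strictly increasing, got {radii}")
    circles = [circular_mask(vol_shape, center, r, slice_axis) for r in radii]
    spheres = [spherical_mask(vol_shape, center, r) for r in radii]
    return circles, spheres


def load_external_mask(path, vol_shape) -> RoiMask:
    """Load a binary NIfTI mask drawn externally (replaces interactive tracing)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.get_fdata())
    data = np.squeeze(data)
    if data.shape != tuple(vol_shape):
        raise MaskFormatError(
            f"mask shape {data.shape} does not match volume shape {tuple(vol_shape)}"
        )
    values = np.unique(data)
    if not np.all(np.isin(values, (0.0, 1.0))):
        raise MaskFormatError(f"mask is not binary; values found: {values[:10]}")
    if not data.any():
        raise MaskFormatError("external mask is empty")
    return RoiMask(data.astype(bool), "external")
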
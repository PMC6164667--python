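"""ROI intensity preprocessing: mean +/- 3 sigma outlier rejection and
uniform quantization to a small gray-level alphabet.

Both steps are applied per ROI, not per volume. Rejection discards voxels
(they become holes that no downstream pair or run may bridge); it never
clips intensities to the interval boundary. Quantization maps the surviving
intensity range uniformly onto levels 1..Ng, which makes every downstream
texture feature invariant to affine intensity rescaling of the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MaskFormatError, ParameterError
from .roi_geometry import RoiMask
from .volume_io import Volume


@dataclass
class QuantizedRoi:
    """Quantized gray levels over the ROI bounding box.

    ``levels`` holds integers 1..n_levels on valid cells and 0 elsewhere;
    ``valid`` marks cells that are in-mask and survived outlier rejection.
    """

    levels: np.ndarray
    valid: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.levels.shape != self.valid.shape:
            raise ParameterError("levels and valid grids must share a shape")
        if self.n_valid < 1:
            raise ParameterError("quantized ROI must have at least one valid cell")
        lv = self.levels[self.valid]
        if lv.min() < 1 or lv.max() > self.n_levels:
            raise ParameterError("valid levels must lie in 1..n_levels")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def normalize_mu3sigma(
    volume: Volume, mask: RoiMask, sigma_multiplier: float = 3.0
):
    """Reject in-mask voxels outside ``mu +/- k*sigma`` of the ROI intensities.

    mu and sigma are the mean and population standard deviation of the
    in-mask intensities. Returns ``(values, valid, mu, sigma)`` where
    ``values`` is the untouched intensity grid and ``valid`` flags in-mask
    voxels inside the acceptance interval (always >= 1, since the mean
    itself is always inside).
    """
    if volume.data.shape != mask.mask.shape:
        raise MaskFormatError("mask shape does not match volume shape")
    if sigma_multiplier <= 0:
        raise ParameterError("sigma_multiplier must be positive")
    inside = volume.data[mask.mask]
    if inside.size == 0:
        raise MaskFormatError("empty ROI mask")
    mu = float(inside.mean())
    sigma = float(inside.std())  # population formula (divide by n)
    if sigma == 0.0:
        # constant ROI (or variance underflow): the interval is degenerate
        # and rejection is meaningless — keep every in-mask voxel
        valid = mask.mask.copy()
    else:
        lo, hi = mu - sigma_multiplier * sigma, mu + sigma_multiplier * sigma
        valid = mask.mask & (volume.data >= lo) & (volume.data <= hi)
    assert valid.any(), "mean is always inside its own acceptance interval"
    return volume.data, valid, mu, sigma


def quantize(values: np.ndarray, valid: np.ndarray, n_levels: int = 64) -> QuantizedRoi:
    """Uniformly bin valid intensities onto levels 1..n_levels.

    ``level = min(floor((x - xmin) * Ng / (xmax - xmin)) + 1, Ng)`` with
    xmin/xmax over valid cells; a constant ROI maps entirely to level 1.
    The result is cropped to the bounding box of the valid cells.
    """
    if n_levels < 2:
        raise ParameterError(f"n_levels must be >= 2, got {n_levels}")
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise MaskFormatError("no valid cells to quantize")
    bbox = tuple(
        slice(int(idx.min()), int(idx.max()) + 1) for idx in np.nonzero(valid)
    )
    vals = np.asarray(values, dtype=np.float64)[bbox]
    vbox = valid[bbox]
    x = vals[vbox]
    xmin, xmax = float(x.min()), float(x.max())
    levels = np.zeros(vals.shape, dtype=np.int64)
    if xmax == xmin:
        levels[vbox] = 1
    else:
        scaled = np.floor((vals[vbox] - xmin) * n_levels / (xmax - xmin)) + 1
        levels[vbox] = np.minimum(scaled, n_levels).astype(np.int64)
    return QuantizedRoi(levels=levels, valid=vbox, n_levels=n_levels)
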
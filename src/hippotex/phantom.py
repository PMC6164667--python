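"""Synthetic three-group phantom cohorts with controlled regional texture.

Each phantom volume is ``mean_intensity + gradient * axis0 + noise`` where
the noise field is Gaussian white noise of standard deviation ``noise_sd``
convolved with a Gaussian kernel of full-width-half-maximum
``smooth_fwhm_vox`` voxels. Smoothing injects spatial autocorrelation —
the texture knob: larger FWHM means smoother, more correlated local
texture, which GLCM Correlation rises with and Contrast falls with.
Phantoms are abstract blobs, not anatomically realistic brains: the
pipeline consumes intensities under masks, so anatomy is irrelevant to
its correctness.

Randomness uses numpy's PCG64 generator; per-subject streams are spawned
from a single ``SeedSequence`` so cohorts are bit-reproducible for a given
seed, independent of generation order.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError
from .volume_io import Volume, write_volume

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class GroupParams:
    """Texture parameters of one phantom group."""

    mean_intensity: float = 1000.0
    noise_sd: float = 100.0
    smooth_fwhm_vox: float = 0.0
    gradient: float = 0.0  # intensity per voxel along axis 0


def _default_group_params() -> dict[str, GroupParams]:
    # Graded spatial autocorrelation across diagnostic groups; equal means
    # and noise so texture, not brightness, separates them.
    return {
        "CN": GroupParams(smooth_fwhm_vox=0.5, gradient=2.0),
        "EMCI": GroupParams(smooth_fwhm_vox=1.0, gradient=2.0),
        "AD": GroupParams(smooth_fwhm_vox=1.5, gradient=2.0),
    }


@dataclass
class PhantomSpec:
    """Cohort-level description of a synthetic study.

    Defaults mirror a three-group study of 35 subjects per group with two
    seed points (left/right) far enough from the volume edge that the
    largest standard ROI (radius 8) fits.
    """

    n_per_group: int = 35
    vol_shape: tuple[int, int, int] = (48, 48, 48)
    centers: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {"left": (16, 24, 24), "right": (32, 24, 24)}
    )
    group_params: dict[str, GroupParams] = field(default_factory=_default_group_params)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.2)
    seed: int = 0
    max_radius: float = 8.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if len(self.vol_shape) != 3 or min(self.vol_shape) < 1:
            raise ParameterError("vol_shape must be 3 positive ints")
        if not self.centers:
            raise ParameterError("at least one seed center is required")
        reach = math.floor(self.max_radius)
        for side, c in self.centers.items():
            if len(c) != 3:
                raise ParameterError(f"center {side!r} must have 3 components")
            for a in range(3):
                if c[a] - reach < 0 or c[a] + reach > self.vol_shape[a] - 1:
                    raise ParameterError(
                        f"center {side!r}={c} cannot hold a radius-{self.max_radius} "
                        f"sphere inside {self.vol_shape}"
                    )
        if not self.group_params:
            raise ParameterError("group_params must not be empty")


def generate_subject_volume(
    shape, params: GroupParams, rng: np.random.Generator, spacing=(1.0, 1.0, 1.2)
) -> Volume:
    """One phantom volume: mean + axial gradient + (smoothed) white noise."""
    noise = rng.standard_normal(shape) * params.noise_sd
    if params.smooth_fwhm_vox > 0:
        noise = gaussian_filter(noise, sigma=params.smooth_fwhm_vox * _FWHM_TO_SIGMA)
    ax0 = np.arange(shape[0], dtype=float)[:, None, None]
    data = params.mean_intensity + params.gradient * ax0 + noise
    return Volume(data=data, spacing=spacing)


def generate_cohort(spec: PhantomSpec, out_dir: str | Path | None = None):
    """Generate the cohort; optionally write NIfTI volumes + manifest CSVs.

    Returns a list of ``(Volume, subject_id, group)``. With ``out_dir``,
    each volume is written as ``<subject_id>.nii.gz`` alongside
    ``centers.csv`` (subject_id, side, x, y, z — 0-based voxel indices)
    and ``groups.csv`` (subject_id, group, filename).
    """
    ss = np.random.SeedSequence(spec.seed)
    groups = list(spec.group_params)
    children = ss.spawn(len(groups) * spec.n_per_group)
    cohort = []
    k = 0
    for g in groups:
        params = spec.group_params[g]
        for i in range(spec.n_per_group):
            rng = np.random.Generator(np.random.PCG64(children[k]))
            k += 1
            vol = generate_subject_volume(spec.vol_shape, params, rng, spec.spacing)
            cohort.append((vol, f"{g}{i:03d}", g))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "groups.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject_id", "group", "filename"])
            for vol, sid, g in cohort:
                fname = f"{sid}.nii.gz"
                write_volume(vol, out_dir / fname)
                w.writerow([sid, g, fname])
        with open(out_dir / "centers.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject_id", "side", "x", "y", "z"])
            for _, sid, _ in cohort:
                for side, c in spec.centers.items():
                    w.writerow([sid, side, c[0], c[1], c[2]])
    return cohort


WORKED_EXAMPLE_SEED = 20180529
WORKED_EXAMPLE_SHAPE = (32, 32, 32)
WORKED_EXAMPLE_CENTER = (16, 16, 16)


def worked_example(out_dir: str | Path | None = None):
    """The tiny documented fixture: one smoothed-noise phantom and its ROI.

    Returns ``(Volume, center)``; with ``out_dir`` also writes the volume
    and a centers CSV. The features of its radius-5 spherical ROI are
    frozen in ``data/worked_example_features.json`` and regression-tested
    against recomputation.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(WORKED_EXAMPLE_SEED)))
    params = GroupParams(smooth_fwhm_vox=1.2, gradient=2.0)
    vol = generate_subject_volume(WORKED_EXAMPLE_SHAPE, params, rng)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_volume(vol, out_dir / "worked_example.nii.gz")
        with open(out_dir / "centers.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject_id", "side", "x", "y", "z"])
            w.writerow(["example000", "left", *WORKED_EXAMPLE_CENTER])
    return vol, WORKED_EXAMPLE_CENTER
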
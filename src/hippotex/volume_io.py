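"""Volume and feature-table I/O.

Volumes are read from NIfTI-1/NIfTI-2 files in their native voxel grid:
no resampling or spatial normalization is applied, and intensities are
taken as stored (after the format's own scl_slope/scl_inter scaling).
Feature tables are plain CSV with a fixed column order so that cohorts
can be assembled, written and re-read losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import TableFormatError, VolumeFormatError

#: The 25 texture features of the panel, in canonical column order:
#: 3 histogram ("global") features, 9 GLCM ("local") features and
#: 13 GLRLM ("regional") features.
HISTOGRAM_FEATURES = ("Global Variance", "Skewness", "Kurtosis")
GLCM_FEATURES = (
    "Energy",
    "Contrast",
    "Entropy",
    "Homogeneity",
    "Correlation",
    "Sum Average",
    "Variance",
    "Dissimilarity",
    "Autocorrelation",
)
GLRLM_FEATURES = (
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "RP",
    "LGRE",
    "HGRE",
    "SRLGE",
    "SRHGE",
    "LRLGE",
    "LRHGE",
    "GLV",
    "RLV",
)
FEATURE_NAMES = HISTOGRAM_FEATURES + GLCM_FEATURES + GLRLM_FEATURES

#: Metadata columns preceding the feature columns in a feature table.
META_COLUMNS = ("subject_id", "group", "roi_id", "side", "shape", "radius_vox")

_AXIS_PLANE = {
    "R": "sagittal",
    "L": "sagittal",
    "A": "coronal",
    "P": "coronal",
    "S": "axial",
    "I": "axial",
}


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary scanner units).
    spacing
        Millimetres per voxel along each grid axis.
    axis_labels
        Anatomical plane each grid axis runs through
        (``sagittal``/``coronal``/``axial``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_labels: tuple[str, str, str] = ("sagittal", "coronal", "axial")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeFormatError(
                f"volume must be 3D with all dims >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be 3 positive reals, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeFormatError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def coronal_axis(self) -> int:
        """Index of the grid axis running through coronal slices."""
        try:
            return self.axis_labels.index("coronal")
        except ValueError:
            return 1


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume in its native grid.

    scl_slope/scl_inter are honored (the standard intensity scaling of the
    format); orientation is read only to label axes with anatomical planes.
    Singleton trailing dimensions (e.g. a 4th dim of length 1) are squeezed.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.get_fdata(dtype=np.float64))
    except IOError:
        raise
    except Exception as exc:  # nibabel raises a zoo of format errors
        raise VolumeFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim < 3:
        raise VolumeFormatError(f"{path}: expected >= 3 spatial dims, got {data.ndim}")
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: non-singleton extra dimensions, shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    try:
        codes = nib.orientations.aff2axcodes(img.affine)
        labels = tuple(_AXIS_PLANE[c] for c in codes)
    except Exception:
        labels = ("sagittal", "coronal", "axial")
    return Volume(data=data, spacing=spacing, axis_labels=labels)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal (RAS) affine from its spacing."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data, affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def feature_table_columns() -> list[str]:
    """Full ordered column list of a feature table CSV."""
    return list(META_COLUMNS) + list(FEATURE_NAMES)


def new_feature_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a feature table from row dicts, enforcing column order."""
    table = pd.DataFrame(rows)
    missing = [c for c in feature_table_columns() if c not in table.columns]
    for c in missing:
        table[c] = np.nan
    return table[feature_table_columns()]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV; missing feature values become ``NA``."""
    if len(table) == 0:
        raise TableFormatError("refusing to write an empty feature table")
    _check_columns(table)
    table.to_csv(path, index=False, na_rep="NA")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table CSV written by :func:`write_feature_table`.

    ``NA`` cells come back as missing (NaN). Unknown or absent feature
    columns are a format error.
    """
    table = pd.read_csv(
        path, na_values=["NA"], keep_default_na=False, float_precision="round_trip"
    )
    _check_columns(table)
    for name in FEATURE_NAMES:
        table[name] = pd.to_numeric(table[name], errors="raise")
    return table


def _check_columns(table: pd.DataFrame) -> None:
    expected = feature_table_columns()
    got = list(table.columns)
    if got != expected:
        unknown = [c for c in got if c not in expected]
        absent = [c for c in expected if c not in got]
        raise TableFormatError(
            f"feature table columns mismatch (unknown={unknown}, missing={absent})"
        )
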
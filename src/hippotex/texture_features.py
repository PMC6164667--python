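"""Rotation-invariant histogram, GLCM and GLRLM texture features.

The 25-feature panel per ROI:

* 3 histogram features on the quantized gray levels (Global Variance,
  Skewness, Kurtosis — Kurtosis is non-excess, so a normal distribution
  gives 3);
* 9 features of the gray-level co-occurrence matrix (GLCM), built at step
  distance 1 and averaged over directions;
* 13 features of the gray-level run-length matrix (GLRLM), likewise
  direction-averaged.

Rotation invariance comes from computing one matrix per ROI as a weighted
average over directions: the 4 in-plane directions (0/45/90/135 degrees),
equally weighted, for 2D ROIs; the 13 unique directions of the voxel
26-neighborhood for 3D ROIs, weighted inversely to the discretization step
length |d| so that diagonal directions (which advance sqrt(2) or sqrt(3)
voxels per step) are not over-counted. Because the weights depend only on
|d|, the averaged matrices — hence all features — are invariant under
in-plane rotations/flips (2D) and grid axis permutations (3D).

Voxels rejected by preprocessing are holes: no co-occurrence pair and no
run ever bridges one. Degenerate statistics (Correlation, Skewness and
Kurtosis of a constant ROI) are reported missing (NaN), never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateRoiError, ParameterError
from .preprocessing import QuantizedRoi, normalize_mu3sigma, quantize
from .roi_geometry import RoiMask
from .volume_io import FEATURE_NAMES, GLCM_FEATURES, GLRLM_FEATURES, Volume


@dataclass(frozen=True)
class DirectionSet:
    """Voxel offsets (one per antipodal pair) and their averaging weights."""

    offsets: tuple[tuple[int, int, int], ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.weights):
            raise ParameterError("offsets and weights must align")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ParameterError("direction weights must sum to 1")
        offs = set(self.offsets)
        for d in offs:
            if tuple(-c for c in d) in offs:
                raise ParameterError(f"offset set contains an antipodal pair: {d}")


def directions(
    mode: str, slice_axis: int = 1, weighting: str | None = None
) -> DirectionSet:
    """Direction set for matrix averaging.

    ``mode='2d'`` gives the 4 in-plane directions embedded in the plane
    orthogonal to ``slice_axis``; ``mode='3d'`` gives the 13 unique
    directions of the 26-neighborhood. ``weighting`` is ``'equal'`` or
    ``'inverse_length'`` (default: equal in 2D, inverse_length in 3D).
    """
    if mode == "2d":
        if slice_axis not in (0, 1, 2):
            raise ParameterError(f"slice_axis must be 0, 1 or 2, got {slice_axis}")
        a, b = [ax for ax in range(3) if ax != slice_axis]
        plane = [(0, 1), (1, 1), (1, 0), (1, -1)]  # 0, 45, 90, 135 degrees
        offsets = []
        for da, db in plane:
            off = [0, 0, 0]
            off[a], off[b] = da, db
            offsets.append(tuple(off))
        weighting = weighting or "equal"
    elif mode == "3d":
        offsets = [
            (dx, dy, dz)
            for dx in (0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
            and ((dx > 0) or (dx == 0 and dy > 0) or (dx == 0 and dy == 0 and dz > 0))
        ]
        assert len(offsets) == 13
        weighting = weighting or "inverse_length"
    else:
        raise ParameterError(f"mode must be '2d' or '3d', got {mode!r}")

    if weighting == "equal":
        raw = [1.0] * len(offsets)
    elif weighting == "inverse_length":
        raw = [1.0 / math.sqrt(sum(c * c for c in d)) for d in offsets]
    else:
        raise ParameterError(f"unknown weighting {weighting!r}")
    total = sum(raw)
    return DirectionSet(tuple(offsets), tuple(w / total for w in raw))


def _offset_slices(shape, off):
    s1, s2 = [], []
    for n, d in zip(shape, off):
        if d >= 0:
            s1.append(slice(0, n - d))
            s2.append(slice(d, n))
        else:
            s1.append(slice(-d, n))
            s2.append(slice(0, n + d))
    return tuple(s1), tuple(s2)


@dataclass
class Glcm:
    """Direction-averaged co-occurrence probability matrix (symmetric, sum 1)."""

    p: np.ndarray
    n_levels: int


def glcm(qroi: QuantizedRoi, dirs: DirectionSet) -> Glcm:
    """Build the direction-averaged GLCM of a quantized ROI.

    Per direction, every ordered pair of valid voxels at displacement
    +/- d is counted (symmetric counting), the directional matrix is
    normalized to sum 1, and the normalized matrices are averaged with
    the direction weights. Directions with no valid pair carry no
    information and are dropped, the remaining weights renormalized.
    """
    ng = qroi.n_levels
    p = np.zeros((ng, ng))
    used_weight = 0.0
    for off, w in zip(dirs.offsets, dirs.weights):
        s1, s2 = _offset_slices(qroi.levels.shape, off)
        both = qroi.valid[s1] & qroi.valid[s2]
        npairs = int(both.sum())
        if npairs == 0:
            continue
        i = qroi.levels[s1][both] - 1
        j = qroi.levels[s2][both] - 1
        c = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
        c = c + c.T  # count (i,j) and (j,i)
        p += w * (c / c.sum())
        used_weight += w
    if used_weight == 0.0:
        raise DegenerateRoiError("no valid voxel pair along any direction")
    p /= used_weight
    return Glcm(p=p, n_levels=ng)


def glcm_features(m: Glcm) -> dict[str, float]:
    """The 9 GLCM features.

    With p(i,j) over levels i,j = 1..Ng, marginal p_x(i) = sum_j p(i,j),
    mu = sum_i i p_x(i) and sigma^2 = sum_i (i - mu)^2 p_x(i) (the marginals
    coincide by symmetry):

    * Energy         = sum p^2
    * Contrast       = sum (i-j)^2 p
    * Entropy        = -sum_{p>0} p log2 p   (bits)
    * Homogeneity    = sum p / (1 + |i-j|)
    * Correlation    = (sum i j p - mu^2) / sigma^2   (missing when sigma=0)
    * Sum Average    = sum_k k p_{x+y}(k),  p_{x+y}(k) = sum_{i+j=k} p(i,j)
    * Variance       = sum (i - mu)^2 p
    * Dissimilarity  = sum |i-j| p
    * Autocorrelation= sum i j p
    """
    p = m.p
    ng = m.n_levels
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    var_marg = float(((i - mu) ** 2 * px).sum())
    pos = p[p > 0]
    autocorr = float((ii * jj * p).sum())
    feats = {
        "Energy": float((p**2).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Entropy": float(-(pos * np.log2(pos)).sum()),
        "Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Correlation": (autocorr - mu * mu) / var_marg if var_marg > 0 else float("nan"),
        "Sum Average": float(((ii + jj) * p).sum()),
        "Variance": float(((ii - mu) ** 2 * p).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "Autocorrelation": autocorr,
    }
    return feats


@dataclass
class Glrlm:
    """Direction-averaged run-length matrix.

    ``r[i-1, j-1]`` is the (weight-averaged, hence real-valued) number of
    maximal runs of gray level i and length j; ``n_runs`` is their total
    weight and ``n_voxels`` the count of valid ROI voxels.
    """

    r: np.ndarray
    n_runs: float
    n_voxels: int
    n_levels: int


def glrlm(qroi: QuantizedRoi, dirs: DirectionSet) -> Glrlm:
    """Build the direction-averaged GLRLM of a quantized ROI.

    A run is a maximal sequence of consecutive valid voxels of equal level
    along a direction; it breaks at the grid edge, at an invalid voxel, or
    at a level change. Each direction's run-count matrix is accumulated with
    its averaging weight.
    """
    shape = qroi.levels.shape
    ng = qroi.n_levels
    lmax = max(shape)
    r = np.zeros((ng, lmax))
    lev = qroi.levels.ravel()
    val = qroi.valid.ravel()
    idx = np.indices(shape).reshape(3, -1)
    for off, w in zip(dirs.offsets, dirs.weights):
        # Sort cells by (line, position-along-line): each cell lies t steps
        # from its line's entry point into the grid, and the entry point
        # identifies the line.
        t = np.full(idx.shape[1], max(shape) + 1)
        for a in range(3):
            if off[a] > 0:
                t = np.minimum(t, idx[a])
            elif off[a] < 0:
                t = np.minimum(t, shape[a] - 1 - idx[a])
        start = [idx[a] - t * off[a] for a in range(3)]
        line = (start[0] * shape[1] + start[1]) * shape[2] + start[2]
        order = np.lexsort((t, line))
        s_lev, s_val, s_line = lev[order], val[order], line[order]
        # run continues at k if cell k-1 is valid, same line, same level
        cont = np.zeros(len(order), dtype=bool)
        cont[1:] = (
            s_val[1:] & s_val[:-1]
            & (s_line[1:] == s_line[:-1])
            & (s_lev[1:] == s_lev[:-1])
        )
        begins = np.flatnonzero(s_val & ~cont)
        ends_next = np.ones(len(order), dtype=bool)
        ends_next[:-1] = ~cont[1:]
        ends = np.flatnonzero(s_val & ends_next)
        lengths = ends - begins + 1
        np.add.at(r, (s_lev[begins] - 1, lengths - 1), w)
    n_runs = float(r.sum())
    if n_runs <= 0:
        raise DegenerateRoiError("ROI produced no runs")
    return Glrlm(r=r, n_runs=n_runs, n_voxels=qroi.n_valid, n_levels=ng)


def glrlm_features(g: Glrlm) -> dict[str, float]:
    """The 13 GLRLM features.

    With rho(i,j) = r(i,j)/Nr, gray marginal r_g(i) = sum_j r(i,j), length
    marginal r_l(j) = sum_i r(i,j), mu_g = sum i rho and mu_l = sum j rho:

    SRE = sum rho/j^2; LRE = sum rho j^2; GLN = sum_i r_g(i)^2 / Nr;
    RLN = sum_j r_l(j)^2 / Nr; RP = Nr/Np; LGRE = sum rho/i^2;
    HGRE = sum rho i^2; SRLGE = sum rho/(i^2 j^2); SRHGE = sum rho i^2/j^2;
    LRLGE = sum rho j^2/i^2; LRHGE = sum rho i^2 j^2;
    GLV = sum rho (i - mu_g)^2; RLV = sum rho (j - mu_l)^2.
    """
    r = g.r
    nr = g.n_runs
    rho = r / nr
    i = np.arange(1, r.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, r.shape[1] + 1)[None, :].astype(float)
    rg = r.sum(axis=1)
    rl = r.sum(axis=0)
    mu_g = float((i * rho).sum())
    mu_l = float((j * rho).sum())
    return {
        "SRE": float((rho / j**2).sum()),
        "LRE": float((rho * j**2).sum()),
        "GLN": float((rg**2).sum() / nr),
        "RLN": float((rl**2).sum() / nr),
        "RP": nr / g.n_voxels,
        "LGRE": float((rho / i**2).sum()),
        "HGRE": float((rho * i**2).sum()),
        "SRLGE": float((rho / (i**2 * j**2)).sum()),
        "SRHGE": float((rho * i**2 / j**2).sum()),
        "LRLGE": float((rho * j**2 / i**2).sum()),
        "LRHGE": float((rho * i**2 * j**2).sum()),
        "GLV": float((rho * (i - mu_g) ** 2).sum()),
        "RLV": float((rho * (j - mu_l) ** 2).sum()),
    }


def histogram_features(qroi: QuantizedRoi) -> dict[str, float]:
    """Global Variance, Skewness and Kurtosis of the quantized levels.

    Population central moments; Kurtosis is non-excess (normal -> 3).
    Skewness and Kurtosis are missing for a constant ROI (sigma = 0).
    """
    x = qroi.levels[qroi.valid].astype(float)
    mu = x.mean()
    var = float(((x - mu) ** 2).mean())
    if var > 0:
        sd = math.sqrt(var)
        skew = float(((x - mu) ** 3).mean()) / sd**3
        kurt = float(((x - mu) ** 4).mean()) / var**2
    else:
        skew = kurt = float("nan")
    return {"Global Variance": var, "Skewness": skew, "Kurtosis": kurt}


def extract_features(
    volume: Volume,
    mask: RoiMask,
    n_gray_levels: int = 64,
    sigma_multiplier: float = 3.0,
    weighting: str | None = None,
) -> dict[str, float]:
    """Full per-ROI pipeline: normalize, quantize, compute the 25 features.

    The direction mode is inferred from the mask: ``circle2d`` masks use the
    4-direction in-plane set, everything else the 13-direction 3D set.
    Returns an ordered mapping with exactly the 25 canonical feature names;
    degenerate statistics are NaN.
    """
    values, valid, _, _ = normalize_mu3sigma(volume, mask, sigma_multiplier)
    qroi = quantize(values, valid, n_gray_levels)
    if mask.shape_kind == "circle2d":
        dirs = directions("2d", slice_axis=mask.slice_axis, weighting=weighting)
    else:
        dirs = directions("3d", weighting=weighting)
    feats: dict[str, float] = {}
    feats.update(histogram_features(qroi))
    feats.update(glcm_features(glcm(qroi, dirs)))
    feats.update(glrlm_features(glrlm(qroi, dirs)))
    out = {name: feats[name] for name in FEATURE_NAMES}
    assert len(out) == 25
    return out
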
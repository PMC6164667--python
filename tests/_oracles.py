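"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (explicit loops, full enumeration)
and shares no code with the package.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def lattice_disc_count(radius: float) -> int:
    """Number of integer points (i, j) with i^2 + j^2 <= r^2."""
    reach = int(np.floor(radius))
    return sum(
        1
        for i in range(-reach, reach + 1)
        for j in range(-reach, reach + 1)
        if i * i + j * j <= radius * radius
    )


def lattice_ball_count(radius: float) -> int:
    """Number of integer points (i, j, k) with i^2 + j^2 + k^2 <= r^2."""
    reach = int(np.floor(radius))
    return sum(
        1
        for i in range(-reach, reach + 1)
        for j in range(-reach, reach + 1)
        for k in range(-reach, reach + 1)
        if i * i + j * j + k * k <= radius * radius
    )


def brute_glcm(levels, valid, offsets, weights, n_levels):
    """Symmetric, direction-averaged GLCM by explicit pair enumeration."""
    levels = np.asarray(levels)
    valid = np.asarray(valid, dtype=bool)
    shape = np.array(levels.shape)
    p = np.zeros((n_levels, n_levels))
    used = 0.0
    for off, w in zip(offsets, weights):
        d = np.array(off)
        c = np.zeros((n_levels, n_levels))
        for cell in itertools.product(*[range(n) for n in shape]):
            cell = np.array(cell)
            nb = cell + d
            if (nb < 0).any() or (nb >= shape).any():
                continue
            if valid[tuple(cell)] and valid[tuple(nb)]:
                i = levels[tuple(cell)] - 1
                j = levels[tuple(nb)] - 1
                c[i, j] += 1
                c[j, i] += 1
        if c.sum() > 0:
            p += w * c / c.sum()
            used += w
    if used == 0:
        raise ValueError("no pairs in any direction")
    return p / used


def brute_glrlm(levels, valid, offsets, weights, n_levels):
    """Direction-averaged run-length matrix by explicit run walking."""
    levels = np.asarray(levels)
    valid = np.asarray(valid, dtype=bool)
    shape = np.array(levels.shape)
    lmax = int(shape.max())
    r = np.zeros((n_levels, lmax))
    for off, w in zip(offsets, weights):
        d = np.array(off)
        for cell in itertools.product(*[range(n) for n in shape]):
            cell = np.array(cell)
            if not valid[tuple(cell)]:
                continue
            prev = cell - d
            prev_in = (prev >= 0).all() and (prev < shape).all()
            if (
                prev_in
                and valid[tuple(prev)]
                and levels[tuple(prev)] == levels[tuple(cell)]
            ):
                continue  # not a run start
            length = 1
            nxt = cell + d
            while (
                (nxt >= 0).all()
                and (nxt < shape).all()
                and valid[tuple(nxt)]
                and levels[tuple(nxt)] == levels[tuple(cell)]
            ):
                length += 1
                nxt = nxt + d
            r[levels[tuple(cell)] - 1, length - 1] += w
    return r


def brute_glcm_features(p):
    """GLCM feature formulas evaluated with explicit (i, j) loops."""
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    var_m = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    out = dict.fromkeys(
        ["Energy", "Contrast", "Entropy", "Homogeneity", "Sum Average",
         "Variance", "Dissimilarity", "Autocorrelation"], 0.0
    )
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            a, b = i + 1, j + 1
            out["Energy"] += v * v
            out["Contrast"] += (a - b) ** 2 * v
            if v > 0:
                out["Entropy"] -= v * np.log2(v)
            out["Homogeneity"] += v / (1 + abs(a - b))
            out["Sum Average"] += (a + b) * v
            out["Variance"] += (a - mu) ** 2 * v
            out["Dissimilarity"] += abs(a - b) * v
            out["Autocorrelation"] += a * b * v
    out["Correlation"] = (
        (out["Autocorrelation"] - mu * mu) / var_m if var_m > 0 else float("nan")
    )
    return out


def mww_exact_p(x, y) -> float:
    """Two-sided exact MWW p by enumerating all rank splits (tie-free input)."""
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == nx + ny, "oracle requires tie-free input"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    center = nx * ny / 2
    n_extreme = 0
    for xs in itertools.combinations(range(1, nx + ny + 1), nx):
        u = sum(xs) - nx * (nx + 1) / 2
        if abs(u - center) >= abs(u_obs - center):
            n_extreme += 1
    return n_extreme / comb(nx + ny, nx)


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values, by the definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda k: p[k])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        k = order[rank - 1]
        running = min(running, min(1.0, m * p[k] / rank))
        adj[k] = running
    return adj
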
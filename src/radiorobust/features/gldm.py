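"""Grey-level dependence matrix features (14).

A voxel's dependence is the number of its 26-neighbours inside the VOI
whose grey level differs by at most α = 0, plus one for the centre voxel.
"""

from __future__ import annotations

import numpy as np

from radiorobust.features.base import EPS, OFFSETS_26, FeatureInvalid

FEATURE_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)


def _shift(arr: np.ndarray, offset) -> np.ndarray:
    """Array shifted by offset with zero fill (levels are 0 outside mask)."""
    out = np.zeros_like(arr)
    src, dst = [], []
    for d, n in zip(offset, arr.shape):
        if d > 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        elif d < 0:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
        else:
            src.append(slice(None))
            dst.append(slice(None))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def dependence_matrix(disc: np.ndarray, n_levels: int,
                      alpha: int = 0) -> np.ndarray:
    inside = disc > 0
    dep = np.zeros(disc.shape, dtype=np.int64)
    for off in OFFSETS_26:
        nb = _shift(disc, off)
        dep += (inside & (nb > 0)
                & (np.abs(disc - nb) <= alpha)).astype(np.int64)
    dep = dep + 1  # dependence size includes the centre voxel
    levels = disc[inside]
    sizes = dep[inside]
    mat = np.zeros((n_levels, 27), dtype=np.float64)
    np.add.at(mat, (levels - 1, sizes - 1), 1.0)
    used = np.nonzero(mat.sum(axis=0))[0]
    return mat[:, : used[-1] + 1]


def compute(disc: np.ndarray, mask: np.ndarray, n_levels: int) -> dict:
    n_vox = int(mask.sum())
    if n_vox < 2:
        raise FeatureInvalid("insufficient-voxels")
    d = dependence_matrix(disc, n_levels)
    nd = d.sum()
    i = np.arange(1, d.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, d.shape[1] + 1, dtype=np.float64)[None, :]
    p = d / nd
    di = d.sum(axis=1)
    dj = d.sum(axis=0)
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    p_nz = p[p > 0]

    return {
        "DependenceEntropy": float(-np.sum(p_nz * np.log2(p_nz + EPS))),
        "DependenceNonUniformity": float(np.sum(dj**2) / nd),
        "DependenceNonUniformityNormalized": float(np.sum(dj**2) / nd**2),
        "DependenceVariance": float(np.sum(p * (j - mu_j) ** 2)),
        "GrayLevelNonUniformity": float(np.sum(di**2) / nd),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(d * i**2) / nd),
        "LargeDependenceEmphasis": float(np.sum(d * j**2) / nd),
        "LargeDependenceHighGrayLevelEmphasis": float(
            np.sum(d * i**2 * j**2) / nd),
        "LargeDependenceLowGrayLevelEmphasis": float(
            np.sum(d * j**2 / i**2) / nd),
        "LowGrayLevelEmphasis": float(np.sum(d / i**2) / nd),
        "SmallDependenceEmphasis": float(np.sum(d / j**2) / nd),
        "SmallDependenceHighGrayLevelEmphasis": float(
            np.sum(d * i**2 / j**2) / nd),
        "SmallDependenceLowGrayLevelEmphasis": float(
            np.sum(d / (i**2 * j**2)) / nd),
    }
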
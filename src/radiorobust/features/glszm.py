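"""Grey-level size-zone matrix features (16).

Zones are 26-connected components of equal grey level inside the VOI.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from radiorobust.features.base import EPS, FeatureInvalid

FEATURE_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

_STRUCT = np.ones((3, 3, 3), dtype=bool)


def size_zone_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    zones: list[tuple[int, int]] = []
    max_size = 0
    for level in np.unique(disc[disc > 0]):
        labelled, n = ndimage.label(disc == level, structure=_STRUCT)
        if n == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        for s in sizes:
            zones.append((int(level), int(s)))
            max_size = max(max_size, int(s))
    if not zones:
        raise FeatureInvalid("insufficient-voxels")
    mat = np.zeros((n_levels, max_size), dtype=np.float64)
    for level, s in zones:
        mat[level - 1, s - 1] += 1.0
    return mat


def compute(disc: np.ndarray, mask: np.ndarray, n_levels: int) -> dict:
    n_vox = int(mask.sum())
    if n_vox < 2:
        raise FeatureInvalid("insufficient-voxels")
    z = size_zone_matrix(disc, n_levels)
    nz = z.sum()
    i = np.arange(1, z.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, z.shape[1] + 1, dtype=np.float64)[None, :]
    p = z / nz
    zi = z.sum(axis=1)
    zj = z.sum(axis=0)
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    p_nz = p[p > 0]

    return {
        "GrayLevelNonUniformity": float(np.sum(zi**2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(zi**2) / nz**2),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "HighGrayLevelZoneEmphasis": float(np.sum(z * i**2) / nz),
        "LargeAreaEmphasis": float(np.sum(z * j**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(z * i**2 * j**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(z * j**2 / i**2) / nz),
        "LowGrayLevelZoneEmphasis": float(np.sum(z / i**2) / nz),
        "SizeZoneNonUniformity": float(np.sum(zj**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(zj**2) / nz**2),
        "SmallAreaEmphasis": float(np.sum(z / j**2) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(z * i**2 / j**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(z / (i**2 * j**2)) / nz),
        "ZoneEntropy": float(-np.sum(p_nz * np.log2(p_nz + EPS))),
        "ZonePercentage": float(nz / n_vox),
        "ZoneVariance": float(np.sum(p * (j - mu_j) ** 2)),
    }
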
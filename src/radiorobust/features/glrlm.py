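"""Grey-level run-length matrix features (16).

Run-length counts are accumulated per direction by a vectorized
line-traversal (lexicographic sort on a line key that is invariant along
each lattice line) and averaged over the 13 unique 3D directions.
"""

from __future__ import annotations

import numpy as np

from radiorobust.features.base import EPS, DIRECTIONS_13, FeatureInvalid

FEATURE_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)


def _runs_along(disc: np.ndarray, direction) -> tuple[np.ndarray, np.ndarray]:
    """Grey levels and lengths of all in-mask runs along one direction."""
    dx, dy, dz = direction
    c = dx * dx + dy * dy + dz * dz
    idx = np.indices(disc.shape).reshape(3, -1)
    i, j, k = idx
    t = i * dx + j * dy + k * dz
    key = np.stack([i * c - t * dx, j * c - t * dy, k * c - t * dz])
    order = np.lexsort(np.vstack([t, key[::-1]]))
    v = disc.reshape(-1)[order]
    key_sorted = key[:, order]
    same_line = np.all(key_sorted[:, 1:] == key_sorted[:, :-1], axis=0)
    new_run = np.ones(v.size, dtype=bool)
    new_run[1:] = (~same_line) | (v[1:] != v[:-1])
    run_id = np.cumsum(new_run) - 1
    lengths = np.bincount(run_id)
    grays = v[new_run]
    keep = grays > 0
    return grays[keep], lengths[keep]


def run_length_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts averaged over the 13 directions."""
    max_len = max(disc.shape) + 1
    total = np.zeros((n_levels, max_len), dtype=np.float64)
    for direction in DIRECTIONS_13:
        grays, lengths = _runs_along(disc, direction)
        np.add.at(total, (grays - 1, lengths - 1), 1.0)
    if total.sum() == 0:
        raise FeatureInvalid("insufficient-voxels")
    total /= len(DIRECTIONS_13)
    # trim unused long-run columns
    used = np.nonzero(total.sum(axis=0))[0]
    return total[:, : used[-1] + 1]


def compute(disc: np.ndarray, mask: np.ndarray, n_levels: int) -> dict:
    n_vox = int(mask.sum())
    if n_vox < 2:
        raise FeatureInvalid("insufficient-voxels")
    r = run_length_matrix(disc, n_levels)
    nr = r.sum()
    i = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, r.shape[1] + 1, dtype=np.float64)[None, :]
    p = r / nr
    ri = r.sum(axis=1)
    rj = r.sum(axis=0)

    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    p_nz = p[p > 0]

    return {
        "GrayLevelNonUniformity": float(np.sum(ri**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(ri**2) / nr**2),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "HighGrayLevelRunEmphasis": float(np.sum(r * i**2) / nr),
        "LongRunEmphasis": float(np.sum(r * j**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(r * i**2 * j**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(r * j**2 / i**2) / nr),
        "LowGrayLevelRunEmphasis": float(np.sum(r / i**2) / nr),
        "RunEntropy": float(-np.sum(p_nz * np.log2(p_nz + EPS))),
        "RunLengthNonUniformity": float(np.sum(rj**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(rj**2) / nr**2),
        "RunPercentage": float(nr / n_vox),
        "RunVariance": float(np.sum(p * (j - mu_j) ** 2)),
        "ShortRunEmphasis": float(np.sum(r / j**2) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(r * i**2 / j**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(r / (i**2 * j**2)) / nr),
    }
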
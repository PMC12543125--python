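"""Neighbouring grey-tone difference matrix features (5)."""

from __future__ import annotations

import numpy as np

from radiorobust.features.base import OFFSETS_26, FeatureInvalid
from radiorobust.features.gldm import _shift

FEATURE_NAMES = (
    "Busyness",
    "Coarseness",
    "Complexity",
    "Contrast",
    "Strength",
)


def grey_tone_difference(disc: np.ndarray, n_levels: int):
    """Per-level voxel counts n_i, probabilities p_i and summed absolute
    differences s_i from the mean of in-VOI 26-neighbours."""
    inside = disc > 0
    nb_sum = np.zeros(disc.shape, dtype=np.float64)
    nb_cnt = np.zeros(disc.shape, dtype=np.float64)
    for off in OFFSETS_26:
        nb = _shift(disc, off)
        valid = nb > 0
        nb_sum += np.where(valid, nb, 0.0)
        nb_cnt += valid
    has_nb = inside & (nb_cnt > 0)
    if not has_nb.any():
        raise FeatureInvalid("insufficient-voxels")
    abar = nb_sum[has_nb] / nb_cnt[has_nb]
    levels = disc[has_nb]
    diffs = np.abs(levels - abar)
    n_i = np.bincount(levels, minlength=n_levels + 1)[1:].astype(np.float64)
    s_i = np.zeros(n_levels)
    np.add.at(s_i, levels - 1, diffs)
    p_i = n_i / n_i.sum()
    return n_i, p_i, s_i


def compute(disc: np.ndarray, mask: np.ndarray, n_levels: int) -> dict:
    if mask.sum() < 2:
        raise FeatureInvalid("insufficient-voxels")
    n_i, p_i, s_i = grey_tone_difference(disc, n_levels)
    n_total = n_i.sum()
    i_vals = np.arange(1, n_levels + 1, dtype=np.float64)
    present = p_i > 0
    ngp = int(present.sum())

    ps = float(np.sum(p_i * s_i))
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        ii = i_vals[present][:, None]
        jj = i_vals[present][None, :]
        pi = p_i[present][:, None]
        pj = p_i[present][None, :]
        si = s_i[present][:, None]
        sj = s_i[present][None, :]
        contrast = float(
            np.sum(pi * pj * (ii - jj) ** 2) / (ngp * (ngp - 1))
            * np.sum(s_i) / n_total
        )
        busy_den = float(np.sum(np.abs(ii * pi - jj * pj)))
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = float(
            np.sum(np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj))
            / n_total
        )
        s_sum = float(np.sum(s_i))
        strength = float(np.sum((pi + pj) * (ii - jj) ** 2)) / s_sum \
            if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
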
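"""Shared primitives of the feature backend: directions, discretization, crops."""

from __future__ import annotations

import numpy as np

EPS = np.spacing(1.0)


class FeatureInvalid(Exception):
    """A feature family cannot be computed on this VOI (too few voxels,
    or its texture matrix cannot be formed)."""


def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    # half of the 26-neighbourhood: keep offsets whose first nonzero
    # component is positive
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                for c in (dx, dy, dz):
                    if c != 0:
                        lead = c
                        break
                if lead > 0:
                    dirs.append((dx, dy, dz))
    return tuple(dirs)


#: the 13 unique 3D directions of 26-connectivity
DIRECTIONS_13 = _unique_directions()
assert len(DIRECTIONS_13) == 13

#: all 26 neighbour offsets
OFFSETS_26 = tuple(d for d in
                   ((dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                    for dz in (-1, 0, 1)) if d != (0, 0, 0))


def crop_to_mask(image: np.ndarray, mask: np.ndarray, pad: int = 1):
    """Crop image and mask to the mask's bounding box plus a 1-voxel margin."""
    idx = np.nonzero(mask)
    lo = [max(int(i.min()) - pad, 0) for i in idx]
    hi = [min(int(i.max()) + pad + 1, s) for i, s in zip(idx, mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return image[sl], mask[sl]


def discretize(image: np.ndarray, mask: np.ndarray, bin_count: int):
    """Fixed-bin-count discretization over the VOI's min-max range.

    Returns (levels, n_levels): ``levels`` is an int array over the full
    cropped grid with values 1..bin_count inside the mask and 0 outside;
    a constant VOI maps to a single level.
    """
    vals = image[mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(image.shape, dtype=np.int64)
    if vmax == vmin:
        levels[mask] = 1
        return levels, 1
    width = (vmax - vmin) / bin_count
    binned = np.floor((image[mask] - vmin) / width).astype(np.int64) + 1
    np.clip(binned, 1, bin_count, out=binned)
    levels[mask] = binned
    return levels, bin_count


def shifted_pairs(levels: np.ndarray, direction):
    """Grey-level pairs (a, b) of in-mask voxels one step apart along
    ``direction``; levels is 0 outside the mask."""
    dx, dy, dz = direction
    sl_a, sl_b = [], []
    for d, n in zip((dx, dy, dz), levels.shape):
        if d > 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        elif d < 0:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
        else:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    ok = (a > 0) & (b > 0)
    return a[ok], b[ok]
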
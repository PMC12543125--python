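"""Native IBSI-style radiomic feature backend.

Implements the standard 107-feature set over seven families — shape (14),
first-order (18), GLCM (24), GLDM (14), GLRLM (16), GLSZM (16) and
NGTDM (5) — using the conventions of this study: fixed-bin-count
discretization (bin width from the per-VOI min–max range), texture
matrices averaged over the 13 unique 3D directions (26-connectivity) with
a single-voxel offset for the co-occurrence matrix, and feature names as
used by common IBSI-compliant extractors.

The public entry point is :func:`compute_all_features`; texture families
raise :class:`FeatureInvalid` on VOIs too small to form their matrix, and
the caller records those as invalid rather than failing.
"""

from __future__ import annotations

import numpy as np

from radiorobust.features.base import (
    FeatureInvalid,
    DIRECTIONS_13,
    discretize,
    crop_to_mask,
)
from radiorobust.features import (
    firstorder,
    shape,
    glcm,
    gldm,
    glrlm,
    glszm,
    ngtdm,
)

__all__ = [
    "FeatureInvalid",
    "DIRECTIONS_13",
    "FAMILY_COUNTS",
    "FEATURE_REGISTRY",
    "compute_all_features",
    "discretize",
]

FAMILY_COUNTS = {
    "shape": 14,
    "first-order": 18,
    "GLCM": 24,
    "GLDM": 14,
    "GLRLM": 16,
    "GLSZM": 16,
    "NGTDM": 5,
}

_FAMILY_MODULES = {
    "shape": shape,
    "first-order": firstorder,
    "GLCM": glcm,
    "GLDM": gldm,
    "GLRLM": glrlm,
    "GLSZM": glszm,
    "NGTDM": ngtdm,
}

#: (family, feature_name) pairs of the fixed 107-feature registry
FEATURE_REGISTRY = tuple(
    (family, name)
    for family, mod in _FAMILY_MODULES.items()
    for name in mod.FEATURE_NAMES
)

assert len(FEATURE_REGISTRY) == 107


def compute_all_features(
    image: np.ndarray,
    mask: np.ndarray,
    spacing,
    bin_count: int = 64,
) -> tuple[dict[tuple[str, str], float], dict[str, str]]:
    """Compute the full 107-feature set for one VOI.

    Parameters
    ----------
    image, mask
        Same-shaped 3D arrays; the VOI is ``mask != 0``.
    spacing
        Voxel spacing (mm) per axis.
    bin_count
        Fixed number of intensity bins spanning the VOI's min–max range.

    Returns
    -------
    values : dict mapping (family, feature_name) -> float
        Only valid features appear.
    invalid : dict mapping family -> reason
        Families whose matrix could not be formed on this VOI.
    """
    mask = np.asarray(mask) != 0
    if not mask.any():
        return {}, {f: "empty-voi" for f in FAMILY_COUNTS}

    img_c, mask_c = crop_to_mask(np.asarray(image, dtype=np.float64), mask)
    intensities = img_c[mask_c]
    disc, n_levels = discretize(img_c, mask_c, bin_count)

    values: dict[tuple[str, str], float] = {}
    invalid: dict[str, str] = {}

    for family, mod in _FAMILY_MODULES.items():
        try:
            if family == "shape":
                feats = mod.compute(mask_c, spacing)
            elif family == "first-order":
                feats = mod.compute(intensities, disc, mask_c, spacing,
                                    n_levels)
            else:
                feats = mod.compute(disc, mask_c, n_levels)
        except FeatureInvalid as exc:
            invalid[family] = str(exc)
            continue
        for name in mod.FEATURE_NAMES:
            values[(family, name)] = float(feats[name])
    return values, invalid
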
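"""First-order intensity statistics (18 features).

Computed on the raw in-VOI intensities; Entropy and Uniformity use the
fixed-bin-count histogram of the discretized VOI.
"""

from __future__ import annotations

import numpy as np

from radiorobust.features.base import EPS, FeatureInvalid

FEATURE_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def compute(intensities, disc, mask, spacing, n_levels) -> dict[str, float]:
    v = np.asarray(intensities, dtype=np.float64)
    if v.size < 1:
        raise FeatureInvalid("empty-voi")
    voxel_volume = float(np.prod(spacing))

    mean = v.mean()
    centred = v - mean
    m2 = np.mean(centred**2)
    m3 = np.mean(centred**3)
    m4 = np.mean(centred**4)

    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]

    hist = np.bincount(disc[mask], minlength=n_levels + 1)[1:]
    p = hist / hist.sum()
    p_nz = p[p > 0]

    energy = float(np.sum(v**2))
    out = {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": float(-np.sum(p_nz * np.log2(p_nz + EPS))),
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(centred))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(v**2))),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
    return out
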
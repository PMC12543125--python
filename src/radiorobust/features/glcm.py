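"""Grey-level co-occurrence matrix features (24).

The symmetric co-occurrence counts at a single-voxel offset are averaged
over the 13 unique 3D directions before feature computation.
"""

from __future__ import annotations

import numpy as np

from radiorobust.features.base import (
    EPS,
    DIRECTIONS_13,
    FeatureInvalid,
    shifted_pairs,
)

FEATURE_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "MCC",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)


def cooccurrence_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric GLCM counts averaged over the 13 directions."""
    total = np.zeros((n_levels, n_levels), dtype=np.float64)
    n_dirs_with_pairs = 0
    for direction in DIRECTIONS_13:
        a, b = shifted_pairs(disc, direction)
        if a.size == 0:
            continue
        counts = np.zeros((n_levels, n_levels), dtype=np.float64)
        np.add.at(counts, (a - 1, b - 1), 1.0)
        total += counts + counts.T
        n_dirs_with_pairs += 1
    if n_dirs_with_pairs == 0 or total.sum() == 0:
        raise FeatureInvalid("insufficient-voxels")
    return total / len(DIRECTIONS_13)


def _mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    psub = p[np.ix_(keep, keep)]
    pxs, pys = px[keep], py[keep]
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    q = (psub / pxs[:, None]) @ (psub / pys[None, :]).T
    eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
    if eig.size < 2:
        return 1.0
    second = max(eig[1], 0.0)
    return float(np.sqrt(min(second, 1.0)))


def compute(disc: np.ndarray, mask: np.ndarray, n_levels: int) -> dict:
    if mask.sum() < 2:
        raise FeatureInvalid("insufficient-voxels")
    p = cooccurrence_matrix(disc, n_levels)
    p = p / p.sum()
    ng = n_levels

    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(px * i))
    mu_y = float(np.sum(py * i))
    sd_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))
    sd_y = float(np.sqrt(np.sum(py * (i - mu_y) ** 2)))

    # diagonal (|i-j|) and cross-diagonal (i+j) probabilities
    k_diff = np.arange(ng, dtype=np.float64)          # 0 .. ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)  # 2 .. 2ng
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    nz = p > 0
    joint_entropy = float(-np.sum(p[nz] * np.log2(p[nz] + EPS)))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0] + EPS)))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0] + EPS)))
    pxpy = px[:, None] * py[None, :]
    both = nz & (pxpy > 0)
    hxy1 = float(-np.sum(p[both] * np.log2(pxpy[both] + EPS)))
    hxy2 = float(-np.sum(pxpy[pxpy > 0] * np.log2(pxpy[pxpy > 0] + EPS)))

    imc1 = (joint_entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    imc2 = float(np.sqrt(max(imc2_arg, 0.0)))

    diff_avg = float(np.sum(k_diff * p_diff))
    contrast = float(np.sum(p * (ii - jj) ** 2))
    correlation = 1.0
    if sd_x > 0 and sd_y > 0:
        correlation = float(
            (np.sum(p * ii * jj) - mu_x * mu_y) / (sd_x * sd_y))

    off_diag = np.abs(ii - jj) > 0
    inverse_variance = float(
        np.sum(p[off_diag] / (ii - jj)[off_diag] ** 2))

    p_sum_nz = p_sum[p_sum > 0]
    p_diff_nz = p_diff[p_diff > 0]

    return {
        "Autocorrelation": float(np.sum(p * ii * jj)),
        "ClusterProminence": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 2)),
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(
            -np.sum(p_diff_nz * np.log2(p_diff_nz + EPS))),
        "DifferenceVariance": float(
            np.sum(p_diff * (k_diff - diff_avg) ** 2)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng**2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inverse_variance,
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": joint_entropy,
        "MaximumProbability": float(p.max()),
        "MCC": _mcc(p, px, py),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(p_sum_nz * np.log2(p_sum_nz + EPS))),
        "SumSquares": float(np.sum(p * (ii - mu_x) ** 2)),
    }
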
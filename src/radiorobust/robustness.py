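"""Feature robustness: within-region CV and agreement ICC per investigation group.

A feature is *robust* to a group's parameter variations when the mean of
its within-region percentage coefficients of variation across regions
(CV_mean) stays below 10% and the intraclass correlation coefficient
(two-way, absolute agreement, single measurement; regions are the
subjects, parameter levels the repeated measurements) exceeds 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "cv_per_region",
    "cv_mean",
    "icc_agreement",
    "classify_robust",
    "RobustnessModel",
    "RobustnessResults",
]

#: relative scale below which a region mean makes %CV meaningless
NEAR_ZERO_MEAN_EPS = 1e-8


def level_pivot(sub: pd.DataFrame) -> pd.DataFrame:
    """Regions x levels matrix of one feature x group.

    Pivots on the level label when present (distinct update combinations
    can share a numeric x-value, and the categorical algorithm group has
    none), falling back to the numeric x-value column.
    """
    col = "level" if "level" in sub.columns else "x_value"
    return sub.pivot_table(index="region", columns=col, values="value",
                           aggfunc="mean")


def cv_per_region(values) -> float:
    """Within-region percentage coefficient of variation over levels.

    100 * sample SD / |mean|.  Returns NaN (flagged) when the mean is
    within ``NEAR_ZERO_MEAN_EPS`` of zero relative to the SD, where %CV is
    meaningless (features such as skewness cross zero).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 parameter levels")
    if not np.all(np.isfinite(v)):
        raise ValueError("CV requires finite values")
    sd = v.std(ddof=1)
    mean = v.mean()
    if abs(mean) <= NEAR_ZERO_MEAN_EPS * max(sd, 1.0):
        return float("nan")
    return float(100.0 * sd / abs(mean))


def cv_mean(per_region_cvs) -> float:
    """Arithmetic mean of per-region CVs over unflagged regions.

    NaN entries (near-zero-mean regions) are excluded; all-NaN input
    marks the feature unassessable (returns NaN).
    """
    cvs = np.asarray(per_region_cvs, dtype=float)
    if cvs.size == 0:
        raise ValueError("no regions survive filtering")
    ok = np.isfinite(cvs)
    if not ok.any():
        return float("nan")
    return float(cvs[ok].mean())


def icc_agreement(matrix) -> float:
    """Two-way, single-measurement, absolute-agreement ICC.

    ``matrix`` is regions x levels (complete).  Computed from the two-way
    ANOVA mean squares: (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    with MSR/MSC/MSE the rows(regions)/columns(levels)/error mean squares.
    Returns NaN for a degenerate (0/0) decomposition, e.g. a constant
    matrix; negative values are reported as computed.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("ICC input must be a 2D regions x levels matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 regions and >= 2 levels")
    if not np.all(np.isfinite(x)):
        raise ValueError(
            "ICC matrix is incomplete; run the invalid-feature filter first")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def classify_robust(cv_mean_value: float, icc_value: float,
                    cv_threshold: float = 10.0,
                    icc_threshold: float = 0.90) -> bool:
    """Robust iff CV_mean < threshold and ICC > threshold; flags => not robust."""
    if not np.isfinite(cv_mean_value) or not np.isfinite(icc_value):
        return False
    return bool(cv_mean_value < cv_threshold and icc_value > icc_threshold)


@dataclass
class RobustnessResults:
    """Per feature x group robustness records with the per-region CVs."""

    frame: pd.DataFrame
    per_region: pd.DataFrame
    cv_threshold: float
    icc_threshold: float
    log: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Robust-feature proportion per group and per family."""
        f = self.frame.dropna(subset=["robust"])
        by_group = f.groupby("group")["robust"].mean().rename("prop_robust")
        by_family = f.groupby("family")["robust"].mean().rename("prop_robust")
        out = pd.concat(
            [by_group.reset_index().assign(stratum="group")
             .rename(columns={"group": "level"}),
             by_family.reset_index().assign(stratum="family")
             .rename(columns={"family": "level"})],
            ignore_index=True,
        )
        return out[["stratum", "level", "prop_robust"]]

    def matrix(self, feature: str, group: str) -> pd.DataFrame:
        """Regions x levels value matrix used for one record."""
        sub = self.per_region[(self.per_region.feature == feature)
                              & (self.per_region.group == group)]
        return sub

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


class RobustnessModel:
    """Classify every feature x group of a long-format feature table.

    Parameters
    ----------
    table
        Long-format feature records with columns
        (feature, family, region, group, x_value, value); already passed
        through the invalid-feature filter so each feature x group forms a
        complete regions x levels matrix.
    cv_threshold, icc_threshold
        The robustness gate (defaults 10% and 0.90).
    """

    def __init__(self, table: pd.DataFrame, cv_threshold: float = 10.0,
                 icc_threshold: float = 0.90):
        required = {"feature", "region", "group", "x_value", "value"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"feature table lacks columns {sorted(missing)}")
        self.table = table
        self.cv_threshold = cv_threshold
        self.icc_threshold = icc_threshold

    def fit(self) -> RobustnessResults:
        rows = []
        region_rows = []
        log = []
        fam_lookup = {}
        if "family" in self.table.columns:
            fam_lookup = (self.table.drop_duplicates("feature")
                          .set_index("feature")["family"].to_dict())
        for (group, feature), sub in self.table.groupby(["group", "feature"],
                                                        sort=True):
            pivot = level_pivot(sub)
            if pivot.isna().any().any():
                raise ValueError(
                    f"incomplete regions x levels matrix for feature "
                    f"{feature!r} in group {group!r}; run filter_invalid")
            n_regions, n_levels = pivot.shape
            cvs = {}
            for region, vals in pivot.iterrows():
                cv = cv_per_region(vals.to_numpy())
                cvs[region] = cv
                region_rows.append(dict(feature=feature, group=group,
                                        region=region, cv=cv))
            flagged = [r for r, c in cvs.items() if not np.isfinite(c)]
            if flagged:
                log.append(f"{group}/{feature}: near-zero-mean regions "
                           f"excluded from CV_mean: {flagged}")
            cvm = cv_mean(list(cvs.values()))
            icc = (icc_agreement(pivot.to_numpy())
                   if n_regions >= 2 and n_levels >= 2 else float("nan"))
            rows.append(dict(
                feature=feature,
                family=fam_lookup.get(feature, ""),
                group=group,
                n_regions=n_regions,
                n_levels=n_levels,
                cv_mean=cvm,
                icc=icc,
                robust=classify_robust(cvm, icc, self.cv_threshold,
                                       self.icc_threshold),
            ))
        frame = pd.DataFrame(rows)
        per_region = pd.DataFrame(region_rows)
        return RobustnessResults(frame, per_region, self.cv_threshold,
                                 self.icc_threshold, log)
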
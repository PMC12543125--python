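"""Parametric correction of non-robust features.

For every non-robust feature x group (the categorical algorithm group is
never corrected), eight candidate response functions
f(x) = α·g(x) + β with g ∈ {x, x², x³, 1/x, 1/x², 1/x³, log x, 1/log x}
are fitted to the mean feature value per parameter level by weighted
least squares, with intrinsic weights equal to the reciprocal of the
across-region feature variance at each level.  The lowest-AIC candidate
is selected and each region's raw values are corrected with the
rearranged function, f_corrected(x) = (f(x) − β) / g(x).  A feature is
*correctable* when the correction significantly reduces the per-region
CVs (one-sided Wilcoxon signed-rank), improves the ICC, and the corrected
values meet the robustness gate; *moderately correctable* when the
reduction/improvement is there but the gate is not met; otherwise *not
correctable*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from radiorobust.functions import FAMILY_ORDER, g_transform
from radiorobust.grid import rescale_x
from radiorobust.robustness import (
    RobustnessResults,
    classify_robust,
    cv_mean,
    cv_per_region,
    icc_agreement,
    level_pivot,
)

__all__ = [
    "FitCandidate",
    "fit_candidates",
    "select_best",
    "apply_correction",
    "intrinsic_weights",
    "classify_correctability",
    "wilcoxon_reduction_p",
    "CorrectionModel",
    "CorrectionResults",
]

#: number of estimated parameters entering the AIC penalty (α, β, residual scale)
AIC_K = 3

#: cap on intrinsic weights relative to their median (zero-variance levels)
WEIGHT_CAP_FACTOR = 1e6

CATEGORY_CORRECTABLE = "correctable"
CATEGORY_MODERATE = "moderately correctable"
CATEGORY_NOT = "not correctable"


@dataclass(frozen=True)
class FitCandidate:
    family: str
    alpha: float
    beta: float
    aic: float
    weighted_rss: float
    n_points: int

    @property
    def admissible(self) -> bool:
        return (math.isfinite(self.alpha) and math.isfinite(self.beta)
                and math.isfinite(self.aic))


def intrinsic_weights(values_by_level: np.ndarray) -> np.ndarray:
    """Reciprocal across-region variance per level, capped for degeneracy.

    ``values_by_level`` is regions x levels.  Zero-variance levels would
    yield infinite weights; they are capped at 1e6 x the median finite
    weight (or 1.0 when every level is degenerate).
    """
    var = np.asarray(values_by_level, dtype=float).var(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / var
    finite = w[np.isfinite(w)]
    if finite.size == 0:
        return np.ones_like(w)
    cap = WEIGHT_CAP_FACTOR * np.median(finite)
    return np.minimum(w, cap)


def _wls(g: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted least squares for y = alpha*g + beta."""
    sw = w.sum()
    swg = np.sum(w * g)
    swgg = np.sum(w * g * g)
    swy = np.sum(w * y)
    swgy = np.sum(w * g * y)
    det = swgg * sw - swg**2
    if det <= 0 or not np.isfinite(det):
        return float("nan"), float("nan"), float("nan")
    alpha = (swgy * sw - swg * swy) / det
    beta = (swgg * swy - swg * swgy) / det
    resid = y - (alpha * g + beta)
    return alpha, beta, float(np.sum(w * resid**2))


def fit_candidates(x, y_mean, weights=None) -> list[FitCandidate]:
    """Fit all eight candidate families by weighted least squares.

    ``x`` must already be rescaled (positive, never 1).  AIC =
    n·ln(RSS_w/n) + 2k with k = 3; shared constants across candidates are
    dropped since every family sees the same n and weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_mean, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    n = x.size
    if n < 3:
        raise ValueError(
            "need at least 3 parameter levels to fit candidate functions")
    out = []
    for family in FAMILY_ORDER:
        g = g_transform(family, x)
        alpha, beta, rss = _wls(g, y, w)
        if not math.isfinite(rss):
            aic = float("nan")
        else:
            aic = n * math.log(max(rss, 1e-300) / n) + 2 * AIC_K
        out.append(FitCandidate(family, alpha, beta, aic, rss, n))
    return out


def select_best(candidates, log: list | None = None) -> FitCandidate | None:
    """Minimum-AIC admissible candidate; exact ties break by family order."""
    admissible = [c for c in candidates if c.admissible]
    if not admissible:
        if log is not None:
            log.append("no admissible candidate")
        return None
    best_aic = min(c.aic for c in admissible)
    tied = [c for c in admissible if c.aic == best_aic]
    if len(tied) > 1 and log is not None:
        log.append(f"AIC tie among {[c.family for c in tied]}; "
                   "first in family order kept")
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    return min(tied, key=lambda c: order[c.family])


def apply_correction(values: np.ndarray, best: FitCandidate,
                     x) -> np.ndarray:
    """Rearranged-function correction (raw − β) / g(x) per region.

    ``values`` is regions x levels (raw), x the rescaled level values.
    """
    g = g_transform(best.family, np.asarray(x, dtype=float))
    if np.any(g == 0):
        raise ValueError("g(x) = 0 at some level; rescale x upstream")
    return (np.asarray(values, dtype=float) - best.beta) / g[None, :]


def wilcoxon_reduction_p(pre_cvs, post_cvs) -> float:
    """One-sided Wilcoxon signed-rank p for post < pre on paired region CVs.

    Pairs with a non-finite CV on either side are dropped; with < 2
    usable pairs the test is undecidable and p = 1 is returned.  The
    exact null distribution is used whenever scipy can (small n, no
    zero-differences/ties).
    """
    pre = np.asarray(pre_cvs, dtype=float)
    post = np.asarray(post_cvs, dtype=float)
    ok = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[ok], post[ok]
    if pre.size < 2:
        return 1.0
    if np.all(post == pre):
        return 1.0
    res = stats.wilcoxon(post, pre, alternative="less",
                         zero_method="wilcox")
    return float(res.pvalue)


def classify_correctability(
    pre_cvs,
    post_cvs,
    icc_pre: float,
    icc_post: float,
    cv_threshold: float = 10.0,
    icc_threshold: float = 0.90,
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Category and Wilcoxon p from paired per-region CVs and the ICC pair."""
    p = wilcoxon_reduction_p(pre_cvs, post_cvs)
    icc_improved = (np.isfinite(icc_post) and
                    (not np.isfinite(icc_pre) or icc_post > icc_pre))
    if p < alpha and icc_improved:
        post_cv_mean = cv_mean(post_cvs)
        if classify_robust(post_cv_mean, icc_post, cv_threshold,
                           icc_threshold):
            return CATEGORY_CORRECTABLE, p
        return CATEGORY_MODERATE, p
    return CATEGORY_NOT, p


@dataclass
class CorrectionResults:
    """Correction outcomes plus the full 8-candidate AIC tables."""

    outcomes: pd.DataFrame
    fits: pd.DataFrame
    corrected: pd.DataFrame
    log: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Outcome-category counts per group."""
        return (self.outcomes.groupby(["group", "category"])
                .size().rename("n").reset_index())

    def to_csv(self, outcomes_path, fits_path=None) -> None:
        self.outcomes.to_csv(outcomes_path, index=False)
        if fits_path is not None:
            self.fits.to_csv(fits_path, index=False)


class CorrectionModel:
    """Fit-and-correct every non-robust feature x group of a study.

    Parameters
    ----------
    table
        Filtered long-format feature table (same contract as
        :class:`~radiorobust.robustness.RobustnessModel`).
    robustness
        The fitted robustness results; only non-robust (feature, group)
        pairs are corrected.
    exclude_groups
        Groups never corrected; defaults to the categorical algorithm
        group.
    """

    def __init__(self, table: pd.DataFrame, robustness: RobustnessResults,
                 exclude_groups=("algorithm",), cv_threshold: float = 10.0,
                 icc_threshold: float = 0.90, alpha: float = 0.05,
                 rescale: bool = True):
        self.table = table
        self.robustness = robustness
        self.exclude_groups = set(exclude_groups)
        self.cv_threshold = cv_threshold
        self.icc_threshold = icc_threshold
        self.alpha = alpha
        self.rescale = rescale

    def fit(self) -> CorrectionResults:
        log: list[str] = []
        outcome_rows, fit_rows, corrected_rows = [], [], []
        rob = self.robustness.frame.set_index(["feature", "group"])

        for (group, feature), sub in self.table.groupby(["group", "feature"],
                                                        sort=True):
            if group in self.exclude_groups:
                continue
            try:
                rec = rob.loc[(feature, group)]
            except KeyError:
                continue
            if bool(rec["robust"]):
                continue

            pivot = level_pivot(sub)
            if "level" in sub.columns:
                x_lookup = (sub.drop_duplicates("level")
                            .set_index("level")["x_value"])
                x_raw = x_lookup.reindex(pivot.columns).to_numpy(dtype=float)
            else:
                x_raw = pivot.columns.to_numpy(dtype=float)
            values = pivot.to_numpy()
            x = (np.asarray(rescale_x(group, x_raw), dtype=float)
                 if self.rescale else x_raw)

            if x.size < 3:
                log.append(f"{group}/{feature}: <3 levels, unassessable")
                outcome_rows.append(self._outcome(feature, group, rec, None,
                                                  float("nan"), float("nan"),
                                                  float("nan"),
                                                  "unassessable"))
                continue

            y_mean = values.mean(axis=0)
            weights = intrinsic_weights(values)
            candidates = fit_candidates(x, y_mean, weights)
            for c in candidates:
                fit_rows.append(dict(feature=feature, group=group,
                                     family=c.family, alpha=c.alpha,
                                     beta=c.beta, aic=c.aic,
                                     weighted_rss=c.weighted_rss,
                                     n_points=c.n_points))
            sel_log: list[str] = []
            best = select_best(candidates, sel_log)
            log.extend(f"{group}/{feature}: {m}" for m in sel_log)
            if best is None:
                outcome_rows.append(self._outcome(feature, group, rec, None,
                                                  float("nan"), float("nan"),
                                                  float("nan"), CATEGORY_NOT))
                continue

            corrected = apply_correction(values, best, x)
            pre_cvs = [cv_per_region(v) for v in values]
            post_cvs = [cv_per_region(v) for v in corrected]
            cv_mean_post = cv_mean(post_cvs)
            icc_post = icc_agreement(corrected)
            category, p = classify_correctability(
                pre_cvs, post_cvs, float(rec["icc"]), icc_post,
                self.cv_threshold, self.icc_threshold, self.alpha)
            outcome_rows.append(self._outcome(feature, group, rec, best,
                                              cv_mean_post, icc_post, p,
                                              category))
            for ri, region in enumerate(pivot.index):
                for xi, xv in enumerate(x_raw):
                    corrected_rows.append(dict(
                        feature=feature, group=group, region=region,
                        x_value=float(xv), value=float(corrected[ri, xi])))

        return CorrectionResults(pd.DataFrame(outcome_rows),
                                 pd.DataFrame(fit_rows),
                                 pd.DataFrame(corrected_rows), log)

    @staticmethod
    def _outcome(feature, group, rec, best, cv_post, icc_post, p, category):
        return dict(
            feature=feature,
            group=group,
            family=rec.get("family", ""),
            best_family=None if best is None else best.family,
            alpha=float("nan") if best is None else best.alpha,
            beta=float("nan") if best is None else best.beta,
            aic=float("nan") if best is None else best.aic,
            cv_mean_pre=float(rec["cv_mean"]),
            icc_pre=float(rec["icc"]),
            cv_mean_corrected=cv_post,
            icc_corrected=icc_post,
            wilcoxon_p=p,
            category=category,
        )
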
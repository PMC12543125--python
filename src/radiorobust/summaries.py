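"""Study-level summaries of robustness/correctability outcomes.

Binary per-feature outcomes (robust yes/no, or correctable ∪ moderately
correctable yes/no) are summarised with a logistic mixed-effects model
with feature-specific random intercepts; each feature's predicted
probability within a stratum is PP = 1 / (1 + e^-(b + aX + u_feature)),
reported per stratum as median [IQR].  Strata (investigation groups) are
compared pairwise with a two-sample Cramér–von Mises permutation test
(full split enumeration when feasible) under Bonferroni adjustment, and
the relative influence of region volume/intensity vs the investigated
parameter on feature variability is expressed as odds ratios with 95%
confidence intervals from the same class of logistic mixed model.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb, expit
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

__all__ = [
    "cvm_statistic",
    "cvm_two_sample",
    "bonferroni",
    "pp_summary",
    "effect_odds_ratios",
    "OutcomeSummaryModel",
]

#: maximum number of splits enumerated exactly before falling back to
#: Monte-Carlo permutations
MAX_ENUMERATION = 100_000


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _stat_from_ranks(ra: np.ndarray, rb: np.ndarray) -> float:
    """Rank-form two-sample Cramér–von Mises statistic (midranks for ties)."""
    n, m = ra.size, rb.size
    big_n = n + m
    i = np.arange(1, n + 1)
    j = np.arange(1, m + 1)
    u = n * np.sum((np.sort(ra) - i) ** 2) + m * np.sum((np.sort(rb) - j) ** 2)
    return float(u / (n * m * big_n) - (4.0 * n * m - 1.0) / (6.0 * big_n))


def cvm_statistic(sample_a, sample_b) -> float:
    """Two-sample Cramér–von Mises statistic over the pooled midranks."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = _midranks(np.concatenate([a, b]))
    return _stat_from_ranks(ranks[: a.size], ranks[a.size:])


def cvm_two_sample(sample_a, sample_b, n_perm: int = 9_999,
                   seed: int | np.random.SeedSequence = 0
                   ) -> tuple[float, float]:
    """Two-sample Cramér–von Mises test with a permutation p-value.

    The null distribution is the statistic over re-splits of the pooled
    sample: every split is enumerated when their count is at most 1e5,
    otherwise ``n_perm`` seeded Monte-Carlo permutations are drawn and the
    p-value uses the (b + 1)/(n_perm + 1) estimator.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    big_n = n + m
    ranks = _midranks(np.concatenate([a, b]))
    observed = _stat_from_ranks(ranks[:n], ranks[n:])
    tol = 1e-12 * max(1.0, abs(observed))

    if comb(big_n, n, exact=True) <= MAX_ENUMERATION:
        count = total = 0
        idx_all = frozenset(range(big_n))
        for combo in itertools.combinations(range(big_n), n):
            ra = ranks[list(combo)]
            rb = ranks[list(idx_all.difference(combo))]
            if _stat_from_ranks(ra, rb) >= observed - tol:
                count += 1
            total += 1
        return observed, count / total

    rng = np.random.default_rng(seed)
    # vectorized permutations: each row permutes the pooled midranks
    count = 0
    chunk = 2_000
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(ranks, (k, 1)), axis=1)
        ra = np.sort(perm[:, :n], axis=1)
        rb = np.sort(perm[:, n:], axis=1)
        i = np.arange(1, n + 1)[None, :]
        j = np.arange(1, m + 1)[None, :]
        u = (n * np.sum((ra - i) ** 2, axis=1)
             + m * np.sum((rb - j) ** 2, axis=1))
        stat = u / (n * m * big_n) - (4.0 * n * m - 1.0) / (6.0 * big_n)
        count += int(np.sum(stat >= observed - tol))
        done += k
    return observed, (count + 1) / (n_perm + 1)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: p·m capped at 1."""
    p = np.asarray(p_values, dtype=float)
    n_tests = p.size if m is None else int(m)
    if n_tests < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(p * n_tests, 1.0)


def _fit_logistic_mixed(data: pd.DataFrame, outcome: str, fixed: str,
                        re_group: str):
    """Binomial mixed GLM with a random intercept per ``re_group`` level.

    Returns (fe_names, fe_mean, fe_sd, re_by_level).
    """
    formula = f"{outcome} ~ 0 + C({fixed})"
    vcf = {re_group: f"0 + C({re_group})"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM.from_formula(formula, vcf, data)
        # explicit start values: the library default draws the SD start
        # from the global RNG, which breaks run-to-run reproducibility
        n_par = model.k_fep + model.k_vcp + model.k_vc
        fit = model.fit_vb(mean=np.zeros(n_par),
                           sd=np.exp(-0.5) * np.ones(n_par))
    fe_names = list(model.exog_names)
    levels = sorted(data[re_group].astype(str).unique())
    re_by_level = dict(zip(levels, fit.vc_mean))
    return fe_names, np.asarray(fit.fe_mean), np.asarray(fit.fe_sd), \
        re_by_level


def pp_summary(outcomes: pd.DataFrame, x: str = "group",
               outcome: str = "outcome") -> pd.DataFrame:
    """Predicted-probability summary per level of a categorical predictor.

    ``outcomes`` holds one binary record per feature x level of ``x``.
    Fits logit P(outcome) = b + a·X + u_feature and evaluates each
    feature's PP from the fitted parameters; returns per level of X the
    median PP, the 25th/75th percentiles, and a degeneracy flag for
    levels whose outcomes are all 0 or all 1 (complete separation).
    """
    data = outcomes[["feature", x, outcome]].dropna().copy()
    data[outcome] = data[outcome].astype(int)
    if data.empty:
        raise ValueError("no outcomes to summarise")

    fe_names, fe_mean, _, re_by_feature = _fit_logistic_mixed(
        data, outcome, x, "feature")
    eta_by_level = {}
    for name, val in zip(fe_names, fe_mean):
        # patsy names the columns 'C(x)[level]'
        level = name.split("[", 1)[1].rstrip("]").removeprefix("T.")
        eta_by_level[level] = val

    rows = []
    for level, sub in data.groupby(x):
        pps = np.array([
            expit(eta_by_level[str(level)] + re_by_feature[str(f)])
            for f in sub["feature"].unique()
        ])
        degenerate = sub[outcome].nunique() == 1
        rows.append(dict(
            level=level,
            n_features=len(pps),
            pp_median=float(np.median(pps)),
            pp_q25=float(np.percentile(pps, 25)),
            pp_q75=float(np.percentile(pps, 75)),
            degenerate=degenerate,
            pp_values=pps,
        ))
    return pd.DataFrame(rows)


def effect_odds_ratios(effects_frame: pd.DataFrame,
                       contrasts=("volume", "intensity")) -> pd.DataFrame:
    """Odds of volume/intensity significance vs parameter significance.

    For each group, per-feature significance indicators of the three fixed
    effects are stacked into (feature, effect_type, significant) records
    and a logistic mixed model significant ~ effect_type + (1 | feature)
    is fitted; OR = exp(contrast coefficient vs the parameter effect) with
    a Wald-style 95% CI.  Complete separation (an effect type entirely
    significant or entirely not) is flagged and the CI reported unbounded.
    """
    rows = []
    for group, sub in effects_frame.groupby("group"):
        long = []
        for _, r in sub.iterrows():
            for eff in ("parameter",) + tuple(contrasts):
                long.append(dict(feature=r["feature"], effect=eff,
                                 sig=int(bool(r[f"sig_{eff}"]))))
        long = pd.DataFrame(long)
        sep_types = [eff for eff, s in long.groupby("effect")["sig"]
                     if s.nunique() == 1]
        try:
            fe_names, fe_mean, fe_sd, _ = _fit_logistic_mixed(
                long, "sig", "effect", "feature")
        except Exception:
            fe_names, fe_mean, fe_sd = [], np.array([]), np.array([])
        coef = {n.split("[", 1)[1].rstrip("]").removeprefix("T."): (m, s)
                for n, m, s in zip(fe_names, fe_mean, fe_sd)}
        for eff in contrasts:
            if eff in coef and "parameter" in coef:
                delta = coef[eff][0] - coef["parameter"][0]
                sd = math.hypot(coef[eff][1], coef["parameter"][1])
                lo, hi = delta - 1.96 * sd, delta + 1.96 * sd
                separated = eff in sep_types or "parameter" in sep_types
                rows.append(dict(
                    group=group,
                    contrast=f"{eff} vs parameter",
                    odds_ratio=math.exp(delta),
                    ci_low=math.exp(lo) if not separated else 0.0,
                    ci_high=math.exp(hi) if not separated else math.inf,
                    significant=bool(lo > 0 or hi < 0) and not separated,
                    separation=separated,
                ))
    return pd.DataFrame(rows)


@dataclass
class OutcomeSummaryResults:
    group_summary: pd.DataFrame
    pairwise: pd.DataFrame
    odds_ratios: pd.DataFrame | None = None
    log: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        s = self.group_summary.copy()
        s["pp"] = s.apply(
            lambda r: f"{r.pp_median:.3f} [{r.pp_q25:.3f}-{r.pp_q75:.3f}]",
            axis=1)
        return s[["group", "n_features", "pp", "degenerate"]]


class OutcomeSummaryModel:
    """Summarise binary outcomes across groups with pairwise comparisons.

    Parameters
    ----------
    outcomes
        One record per feature x group with a binary ``outcome`` column.
    effects_frame
        Optional fitted effects records for the odds-ratio analysis.
    """

    def __init__(self, outcomes: pd.DataFrame,
                 effects_frame: pd.DataFrame | None = None,
                 n_perm: int = 9_999, seed: int = 0):
        self.outcomes = outcomes
        self.effects_frame = effects_frame
        self.n_perm = n_perm
        self.seed = seed

    def fit(self) -> OutcomeSummaryResults:
        log: list[str] = []
        groups_summary = pp_summary(self.outcomes, x="group")
        levels = list(groups_summary["level"])
        pp_vectors = dict(zip(levels, groups_summary["pp_values"]))

        pairs = list(itertools.combinations(levels, 2))
        seed_seq = np.random.SeedSequence(self.seed)
        child_seeds = seed_seq.spawn(len(pairs))
        raw = []
        rows = []
        for (ga, gb), child in zip(pairs, child_seeds):
            stat, p = cvm_two_sample(pp_vectors[ga], pp_vectors[gb],
                                     self.n_perm, child)
            raw.append(p)
            rows.append(dict(group_a=ga, group_b=gb, statistic=stat,
                             p_raw=p))
        adj = bonferroni(raw, len(pairs)) if pairs else []
        pairwise = pd.DataFrame(rows)
        if pairs:
            pairwise["p_adjusted"] = adj

        or_frame = None
        if self.effects_frame is not None and not self.effects_frame.empty:
            or_frame = effect_odds_ratios(self.effects_frame)

        gs = groups_summary.drop(columns=["pp_values"])
        gs.insert(0, "group", gs.pop("level"))
        return OutcomeSummaryResults(gs, pairwise, or_frame, log)
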
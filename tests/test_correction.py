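"""Parametric correction: WLS fits, AIC selection, Wilcoxon gating."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radiorobust.correction import (
    CorrectionModel,
    apply_correction,
    classify_correctability,
    fit_candidates,
    intrinsic_weights,
    select_best,
    wilcoxon_reduction_p,
)
from radiorobust.functions import FAMILY_ORDER, g_transform
from radiorobust.phantom import FeatureSimSpec, simulate_feature_values
from radiorobust.robustness import RobustnessModel
from tests.conftest import make_feature_table


def test_family_order_has_eight_members():
    assert len(FAMILY_ORDER) == 8
    assert FAMILY_ORDER[0] == "a*x+b"


def test_g_transform_closed_forms():
    x = np.array([2.0, 4.0])
    np.testing.assert_allclose(g_transform("a*x+b", x), x)
    np.testing.assert_allclose(g_transform("a*x^2+b", x), x**2)
    np.testing.assert_allclose(g_transform("a/x^3+b", x), 1 / x**3)
    np.testing.assert_allclose(g_transform("a*log(x)+b", x), np.log(x))
    np.testing.assert_allclose(g_transform("a/log(x)+b", x), 1 / np.log(x))


def test_exact_recovery_every_family_zero_noise():
    x = np.linspace(2.0, 12.0, 11)
    for fam in FAMILY_ORDER:
        y = 2.0 * g_transform(fam, x) + 1.0
        best = select_best(fit_candidates(x, y))
        assert best.family == fam, fam
        assert best.alpha == pytest.approx(2.0, abs=1e-8)
        assert best.beta == pytest.approx(1.0, abs=1e-8)


def test_wls_matches_grid_search_oracle():
    rng = np.random.default_rng(9)
    x = np.linspace(2.0, 12.0, 11)
    g = g_transform("a/x+b", x)
    y = 1.7 / x + 0.4 + rng.normal(0, 0.05, x.size)
    w = rng.uniform(0.5, 2.0, x.size)
    cand = next(c for c in fit_candidates(x, y, w) if c.family == "a/x+b")
    # brute-force grid around the WLS solution
    alphas = np.linspace(cand.alpha - 0.2, cand.alpha + 0.2, 201)
    betas = np.linspace(cand.beta - 0.2, cand.beta + 0.2, 201)
    rss = np.array([[np.sum(w * (y - a * g - b) ** 2) for b in betas]
                    for a in alphas])
    i, j = np.unravel_index(rss.argmin(), rss.shape)
    assert alphas[i] == pytest.approx(cand.alpha, abs=2e-3)
    assert betas[j] == pytest.approx(cand.beta, abs=2e-3)
    assert rss.min() >= cand.weighted_rss - 1e-9


def test_aic_prefers_true_family_under_noise():
    rng_x = np.linspace(2.0, 12.0, 11)
    hits = 0
    for seed in range(20):
        spec = FeatureSimSpec(function_family="a/x^2+b",
                              alpha_range=(1.0, 3.0), beta_range=(0.0, 1.0),
                              noise_sd=0.002, x_levels=tuple(rng_x))
        tab = simulate_feature_values(spec, seed=seed)
        pivot = tab.pivot_table(index="region", columns="x_value",
                                values="value")
        vals = pivot.to_numpy()
        best = select_best(fit_candidates(pivot.columns.to_numpy(float),
                                          vals.mean(0),
                                          intrinsic_weights(vals)))
        hits += best.family == "a/x^2+b"
    assert hits >= 18


def test_select_best_tie_goes_to_family_order():
    cands = fit_candidates(np.array([2.0, 3.0, 4.0]),
                           np.array([1.0, 1.0, 1.0]))
    # constant data: every family fits exactly with alpha=0 -> AIC ties
    best = select_best(cands)
    assert best.family == FAMILY_ORDER[0]


def test_apply_correction_flattens_shared_beta():
    x = np.array([2.0, 4.0, 8.0])
    best = select_best(fit_candidates(x, 2.0 / x + 1.0))
    values = np.vstack([2.0 / x + 1.0, 5.0 / x + 1.0])
    corrected = apply_correction(values, best, x)
    np.testing.assert_allclose(corrected[0], 2.0)
    np.testing.assert_allclose(corrected[1], 5.0)


def test_intrinsic_weights_inverse_variance_with_cap():
    vals = np.array([[1.0, 10.0, 5.0],
                     [1.2, 30.0, 5.0],
                     [0.8, 20.0, 5.0]])
    w = intrinsic_weights(vals)
    assert w[0] > w[1]                     # tighter level -> larger weight
    assert np.isfinite(w).all() and (w > 0).all()   # zero-variance capped


def wilcoxon_enumeration_p(pre, post):
    """Oracle: exact one-sided signed-rank p by enumerating 2^n signs."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d < 0].sum()  # statistic: sum of ranks of negative diffs
    n = d.size
    count = 0
    total = 0
    for signs in itertools.product([1, -1], repeat=n):
        w = ranks[np.array(signs) < 0].sum()
        count += w >= w_obs  # "less" alternative: large negative-rank sum
        total += 1
    return count / total


def test_wilcoxon_matches_sign_enumeration():
    rng = np.random.default_rng(11)
    for trial in range(5):
        pre = rng.uniform(10, 30, 9)
        post = pre - rng.uniform(-2, 6, 9)
        p = wilcoxon_reduction_p(pre, post)
        assert p == pytest.approx(wilcoxon_enumeration_p(pre, post),
                                  abs=1e-12)


def test_wilcoxon_degenerate_inputs():
    assert wilcoxon_reduction_p([1.0], [0.5]) == 1.0
    assert wilcoxon_reduction_p([1.0, 2.0], [1.0, 2.0]) == 1.0
    assert wilcoxon_reduction_p([np.nan, 1.0, 2.0],
                                [np.nan, 1.0, 2.0]) == 1.0


def test_classify_correctability_categories():
    pre = np.full(9, 50.0)
    post_good = np.full(9, 2.0) + np.arange(9) * 0.1
    cat, p = classify_correctability(pre, post_good, icc_pre=0.2,
                                     icc_post=0.99)
    assert cat == "correctable" and p < 0.05
    post_partial = np.full(9, 20.0) + np.arange(9) * 0.1
    cat, _ = classify_correctability(pre, post_partial, icc_pre=0.2,
                                     icc_post=0.95)
    assert cat == "moderately correctable"
    cat, _ = classify_correctability(pre, pre.copy(), icc_pre=0.2,
                                     icc_post=0.1)
    assert cat == "not correctable"


def test_correction_model_zero_noise_multiplicative_is_correctable():
    # shared beta across regions: the pooled fit can fully remove the trend
    x_levels = (2.0, 3.0, 4.0, 6.0, 8.0, 10.0)
    rows = []
    rng = np.random.default_rng(21)
    alphas = rng.uniform(1, 3, 9)
    for i in range(9):
        for x in x_levels:
            rows.append(dict(feature="f0", family="synthetic",
                             region=f"region{i+1}", group="g1",
                             x_value=x, value=alphas[i] / x + 1.0))
    table = pd.DataFrame(rows)
    rob = RobustnessModel(table).fit()
    assert not rob.frame["robust"].iloc[0]
    res = CorrectionModel(table, rob, exclude_groups=(),
                          rescale=False).fit()
    rec = res.outcomes.iloc[0]
    assert rec["best_family"] == "a/x+b"
    assert rec["category"] == "correctable"
    assert rec["cv_mean_corrected"] < 1e-6


def test_correction_model_skips_robust_and_excluded():
    table = make_feature_table(["a*x+b"], noise_sd=0.0, seed=3,
                               group_name="algorithm")
    rob = RobustnessModel(table).fit()
    res = CorrectionModel(table, rob).fit()  # algorithm excluded by default
    assert res.outcomes.empty
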
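"""CV / ICC robustness classification against independent oracles."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from radiorobust.robustness import (
    RobustnessModel,
    classify_robust,
    cv_mean,
    cv_per_region,
    icc_agreement,
    level_pivot,
)
from tests.conftest import make_feature_table


def pingouin_icc_a1(matrix):
    """Oracle: pingouin's two-way absolute-agreement single-rater ICC."""
    n, k = matrix.shape
    df = pd.DataFrame(
        [(r, c, matrix[r, c]) for r in range(n) for c in range(k)],
        columns=["targets", "raters", "ratings"])
    res = pg.intraclass_corr(df, "targets", "raters", "ratings")
    return float(res.loc[res.Type == "ICC(A,1)", "ICC"].iloc[0])


def anova_icc(matrix):
    """Oracle: ICC(A,1) from a from-scratch two-way ANOVA decomposition."""
    x = np.asarray(matrix, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_cv_closed_forms():
    assert cv_per_region([1.0, 2.0, 3.0]) == pytest.approx(50.0)
    assert cv_per_region([2.0, 2.0, 2.0]) == 0.0
    assert np.isnan(cv_per_region([-1.0, 1.0]))  # zero mean


def test_cv_scale_invariance():
    base = [3.0, 4.0, 5.0]
    assert cv_per_region(base) == pytest.approx(
        cv_per_region([10 * v for v in base]))
    assert cv_per_region(base) == pytest.approx(
        cv_per_region([-v for v in base]))


def test_cv_requires_levels_and_finite():
    with pytest.raises(ValueError):
        cv_per_region([1.0])
    with pytest.raises(ValueError):
        cv_per_region([1.0, np.nan])


def test_cv_mean_excludes_flagged():
    assert cv_mean([10.0, 20.0, np.nan]) == pytest.approx(15.0)
    assert np.isnan(cv_mean([np.nan, np.nan]))
    with pytest.raises(ValueError):
        cv_mean([])


def test_icc_matches_pingouin_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        m = rng.normal(0, 1, (6, 5)) + rng.normal(0, 2, 6)[:, None]
        assert icc_agreement(m) == pytest.approx(pingouin_icc_a1(m),
                                                 abs=1e-10)


def test_icc_matches_anova_oracle():
    rng = np.random.default_rng(4)
    for _ in range(20):
        m = rng.normal(0, 1, (9, 11)) + rng.normal(0, 2, 9)[:, None]
        assert icc_agreement(m) == pytest.approx(anova_icc(m), abs=1e-12)


def test_icc_shift_and_scale_invariance():
    rng = np.random.default_rng(5)
    m = rng.normal(0, 1, (5, 4)) + np.arange(5)[:, None]
    base = icc_agreement(m)
    assert icc_agreement(m + 100.0) == pytest.approx(base, abs=1e-10)
    assert icc_agreement(m * 3.5) == pytest.approx(base, abs=1e-10)


def test_icc_edge_cases():
    # perfect agreement
    perfect = np.tile(np.arange(4.0)[:, None], (1, 3))
    assert icc_agreement(perfect) == pytest.approx(1.0)
    # constant matrix is degenerate
    assert np.isnan(icc_agreement(np.full((3, 3), 2.0)))
    with pytest.raises(ValueError):
        icc_agreement(np.array([[1.0, np.nan], [2.0, 3.0]]))
    with pytest.raises(ValueError):
        icc_agreement(np.array([[1.0, 2.0]]))


def test_icc_negative_reported_raw():
    # strong level effect, no region effect -> negative ICC possible
    m = np.array([[0.0, 10.0], [0.1, 9.9], [-0.1, 10.1]])
    assert icc_agreement(m) < 0
    assert not classify_robust(5.0, icc_agreement(m))


def test_classify_robust_gates():
    assert classify_robust(9.9, 0.91)
    assert not classify_robust(10.0, 0.95)   # CV strictly below
    assert not classify_robust(5.0, 0.90)    # ICC strictly above
    assert not classify_robust(np.nan, 0.99)
    assert not classify_robust(5.0, np.nan)


def test_level_pivot_keeps_duplicate_x_levels_separate():
    rows = []
    for level, x in [("1x32", 32.0), ("2x16", 32.0)]:
        for region in ("rA", "rB"):
            rows.append(dict(region=region, level=level, x_value=x,
                             value=hash((level, region)) % 7 + 1.0))
    pivot = level_pivot(pd.DataFrame(rows))
    assert pivot.shape == (2, 2)
    assert set(pivot.columns) == {"1x32", "2x16"}


def test_robustness_model_on_synthetic_tables():
    # a strongly level-dependent feature is not robust; a flat feature
    # with clear region separation is
    varying = make_feature_table(["a*x+b"], noise_sd=0.0, seed=1)
    rng = np.random.default_rng(2)
    rows = []
    for i in range(9):
        base = 10.0 * (i + 1)
        for x in (2.0, 3.0, 4.0, 6.0):
            rows.append(dict(feature="flat", family="synthetic",
                             region=f"region{i+1}", group="g1",
                             x_value=x, value=base + rng.normal(0, 0.01)))
    table = pd.concat([varying, pd.DataFrame(rows)], ignore_index=True)
    res = RobustnessModel(table).fit()
    rec = res.frame.set_index("feature")
    assert not rec.loc["f0", "robust"]
    assert rec.loc["flat", "robust"]
    assert rec.loc["flat", "cv_mean"] < 1.0
    assert rec.loc["flat", "icc"] > 0.99


def test_robustness_model_rejects_incomplete_matrix():
    table = make_feature_table(["a*x+b"], seed=0)
    table = table.drop(table.index[0])
    with pytest.raises(ValueError, match="incomplete"):
        RobustnessModel(table).fit()


def test_robustness_results_summary():
    table = make_feature_table(["a*x+b", "a/x+b"], noise_sd=0.01, seed=0)
    res = RobustnessModel(table).fit()
    summ = res.summary()
    assert {"stratum", "level", "prop_robust"} == set(summ.columns)
    assert (summ["prop_robust"] <= 1.0).all()
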
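"""Attribution of feature variability to region volume and intensity.

For each feature x investigation group, a linear mixed-effects model

    value ~ parameter + volume + intensity      (fixed effects)
    + per-region random intercept and random parameter slope

quantifies the differential influence of the varied
acquisition/reconstruction parameter, the region's volume (shape
MeshVolume) and its mean intensity (first-order Mean) on the feature.
The response and all continuous predictors are z-standardized per
feature x group so fixed-effect coefficients are comparable across
features.  For the categorical algorithm group, the parameter enters as
fixed categorical levels and the random structure reduces to per-region
intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["fit_feature_effects", "FeatureEffectsModel",
           "FeatureEffectsResults", "EFFECT_NAMES"]

EFFECT_NAMES = ("parameter", "volume", "intensity")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def fit_feature_effects(
    data: pd.DataFrame,
    categorical_parameter: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Fit the mixed model for one feature x group.

    Parameters
    ----------
    data
        Columns (region, parameter, volume, intensity, value); parameter
        numeric unless ``categorical_parameter``.
    categorical_parameter
        Algorithm-style groups: categorical fixed levels, random
        intercepts only; the parameter coefficient reported is the
        largest-magnitude level contrast and is marked non-comparable.

    Returns
    -------
    dict with coefficient/p-value/significance per effect, plus
    ``converged`` and ``comparable`` flags.
    """
    regions = data["region"].unique()
    if len(regions) < 2:
        raise ValueError(
            "random effects are unidentifiable with a single region")
    if data.groupby("region")["value"].size().min() < 3:
        raise ValueError("need >= 3 parameter levels per region")

    y = _zscore(data["value"].to_numpy(dtype=float))
    vol = _zscore(data["volume"].to_numpy(dtype=float))
    inten = _zscore(data["intensity"].to_numpy(dtype=float))
    groups = data["region"].to_numpy()

    if categorical_parameter:
        dummies = pd.get_dummies(data["parameter"].astype(str),
                                 drop_first=True, dtype=float)
        exog = np.column_stack([np.ones(len(y)), dummies.to_numpy(),
                                vol, inten])
        names = (["const"] + [f"parameter[{c}]" for c in dummies.columns]
                 + ["volume", "intensity"])
        exog_re = np.ones((len(y), 1))
    else:
        par = _zscore(data["parameter"].to_numpy(dtype=float))
        exog = np.column_stack([np.ones(len(y)), par, vol, inten])
        names = ["const", "parameter", "volume", "intensity"]
        exog_re = np.column_stack([np.ones(len(y)), par])

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            model = sm.MixedLM(y, exog, groups=groups, exog_re=exog_re)
            fit = model.fit(reml=True, method=["lbfgs", "bfgs"])
            converged = bool(fit.converged)
        except Exception:
            fit = None
            converged = False

    out = dict(converged=converged,
               comparable=not categorical_parameter)
    for eff in EFFECT_NAMES:
        out[f"coef_{eff}"] = float("nan")
        out[f"p_{eff}"] = float("nan")
        out[f"sig_{eff}"] = False
    if fit is None:
        return out

    params = dict(zip(names, fit.fe_params))
    pvals = dict(zip(names, fit.pvalues[: len(names)]))
    if categorical_parameter:
        level_names = [n for n in names if n.startswith("parameter[")]
        if level_names:
            lead = max(level_names, key=lambda n: abs(params[n]))
            params["parameter"] = params[lead]
            pvals["parameter"] = pvals[lead]
        else:
            params["parameter"], pvals["parameter"] = 0.0, float("nan")
    for eff in EFFECT_NAMES:
        coef = params.get(eff, float("nan"))
        p = pvals.get(eff, float("nan"))
        out[f"coef_{eff}"] = float(coef)
        out[f"p_{eff}"] = float(p)
        out[f"sig_{eff}"] = bool(np.isfinite(p) and p < alpha)
    return out


@dataclass
class FeatureEffectsResults:
    frame: pd.DataFrame
    log: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Share of features with a significant effect, per group and effect."""
        f = self.frame[self.frame.converged]
        rows = []
        for eff in EFFECT_NAMES:
            s = f.groupby("group")[f"sig_{eff}"].mean()
            for grp, v in s.items():
                rows.append(dict(group=grp, effect=eff, prop_significant=v))
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


class FeatureEffectsModel:
    """Mixed-effects attribution for every feature x group of a study.

    Parameters
    ----------
    table
        Filtered feature table (feature, family, region, group, x_value,
        value).
    covariates
        Per (region, group, x_value) volume and mean-intensity table from
        :func:`radiorobust.extraction.region_covariates`.
    categorical_groups
        Group names whose parameter is categorical (default: algorithm).
    """

    def __init__(self, table: pd.DataFrame, covariates: pd.DataFrame,
                 categorical_groups=("algorithm",), alpha: float = 0.05):
        self.table = table
        self.covariates = covariates
        self.categorical_groups = set(categorical_groups)
        self.alpha = alpha

    def fit(self) -> FeatureEffectsResults:
        log: list[str] = []
        cov = self.covariates.set_index(["group", "region", "level"])[
            ["mesh_volume", "mean_intensity"]]
        rows = []
        for (group, feature), sub in self.table.groupby(["group", "feature"],
                                                        sort=True):
            merged = sub.join(cov, on=["group", "region", "level"],
                              how="inner")
            if merged.empty:
                log.append(f"{group}/{feature}: no covariates, skipped")
                continue
            categorical = group in self.categorical_groups
            data = pd.DataFrame(dict(
                region=merged["region"].to_numpy(),
                parameter=(merged["level"].to_numpy()
                           if categorical and "level" in merged
                           else merged["x_value"].to_numpy()),
                volume=merged["mesh_volume"].to_numpy(),
                intensity=merged["mean_intensity"].to_numpy(),
                value=merged["value"].to_numpy(),
            ))
            try:
                res = fit_feature_effects(data, categorical, self.alpha)
            except ValueError as exc:
                log.append(f"{group}/{feature}: {exc}")
                continue
            if not res["converged"]:
                log.append(f"{group}/{feature}: non-convergence flagged")
            rows.append(dict(feature=feature, group=group,
                             family=sub["family"].iloc[0]
                             if "family" in sub else "", **res))
        return FeatureEffectsResults(pd.DataFrame(rows), log)
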
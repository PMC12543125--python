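"""Radiomic feature extraction over VOIs and the study's filtering rules.

Features are computed per VOI of a label map with the study conventions:
a fixed bin number of 64 for intensity discretization, co-occurrence and
run-length matrices averaged over the 13 unique 3D directions
(single-voxel offset for the former), and the fixed 107-feature registry
(shape 14, first-order 18, GLCM 24, GLDM 14, GLRLM 16, GLSZM 16,
NGTDM 5).  VOIs too small to form a texture matrix yield records with
``valid = False`` and a reason code; the invalid-feature filter then
removes the affected (feature, region) pair from the whole investigation
group so every downstream regions x levels matrix is complete.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from radiorobust.features import (
    FEATURE_REGISTRY,
    compute_all_features,
)
from radiorobust.phantom import ImageVolume, REGION_LABELS

__all__ = [
    "extract_features",
    "filter_invalid",
    "aggregate_nuisance",
    "region_covariates",
    "read_feature_csv",
]

_BACKENDS = {"native": compute_all_features}


def read_feature_csv(path) -> pd.DataFrame:
    """Read a feature/robustness CSV preserving literal level labels.

    pandas' default NA detection turns the z-filter level "None" into
    NaN; only empty cells are treated as missing here.
    """
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def extract_features(
    image: ImageVolume | np.ndarray,
    mask: ImageVolume | np.ndarray,
    bin_count: int = 64,
    spacing=None,
    region_names: dict[int, str] | None = None,
    backend: str = "native",
) -> pd.DataFrame:
    """Extract the 107-feature set for every labelled VOI.

    Parameters
    ----------
    image, mask
        Same-grid volume and integer label map (ImageVolume or arrays;
        ``spacing`` required for bare arrays).
    bin_count
        Fixed intensity bin count (study convention: 64).
    region_names
        Label -> region-name mapping; defaults to the phantom's nine VOIs
        for known labels and ``region<k>`` otherwise.
    backend
        Feature computation backend; "native" is the built-in IBSI-style
        extractor (an external extractor can be registered in its place).

    Returns
    -------
    DataFrame with one record per feature x region: columns (feature,
    family, region, value, valid, reason).
    """
    if backend not in _BACKENDS:
        raise ValueError(f"unknown backend {backend!r}")
    compute = _BACKENDS[backend]

    img = image.data if isinstance(image, ImageVolume) else np.asarray(image)
    if isinstance(mask, ImageVolume):
        lab = np.asarray(mask.data)
        spacing = spacing or mask.spacing
    else:
        lab = np.asarray(mask)
    if isinstance(image, ImageVolume):
        spacing = spacing or image.spacing
    if spacing is None:
        raise ValueError("spacing required when passing bare arrays")
    if img.shape != lab.shape:
        raise ValueError("image and mask must share the same grid")

    names = dict(REGION_LABELS)
    if region_names:
        names.update(region_names)

    rows = []
    for label in np.unique(lab[lab > 0]):
        region = names.get(int(label), f"region{int(label)}")
        values, invalid = compute(img, lab == label, spacing, bin_count)
        for family, feat in FEATURE_REGISTRY:
            if (family, feat) in values:
                rows.append(dict(feature=f"{family}_{feat}", family=family,
                                 region=region,
                                 value=values[(family, feat)],
                                 valid=True, reason=""))
            else:
                rows.append(dict(feature=f"{family}_{feat}", family=family,
                                 region=region, value=np.nan, valid=False,
                                 reason=invalid.get(family, "unknown")))
    return pd.DataFrame(rows)


def filter_invalid(records: pd.DataFrame
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Remove (feature, region) pairs invalid anywhere within a group.

    A pair invalid at one parameter level of a group cannot enter that
    group's regions x levels matrix at any level; the whole pair is
    excluded from that group and logged.  Returns the filtered records
    and the exclusion log.
    """
    required = {"feature", "region", "group", "valid"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns {sorted(missing)}")
    bad = (records.loc[~records["valid"].astype(bool),
                       ["group", "feature", "region", "reason"]]
           .drop_duplicates(["group", "feature", "region"]))
    log = [
        f"excluded {r.feature} / {r.region} from group {r.group}: {r.reason}"
        for r in bad.itertuples()
    ]
    if bad.empty:
        return records.copy(), log
    key_cols = ["group", "feature", "region"]
    bad_idx = pd.MultiIndex.from_frame(bad[key_cols])
    rec_idx = pd.MultiIndex.from_frame(records[key_cols])
    keep = ~rec_idx.isin(bad_idx)
    return records.loc[keep].copy(), log


def aggregate_nuisance(records: pd.DataFrame, target: str,
                       nuisance: str) -> pd.DataFrame:
    """Average feature values over a nuisance axis of the update grid.

    For the OSEM-iterations group the 24 update-combination records are
    averaged over the 3 subset schemes per iteration count; for the
    subsets group, over the 8 iteration schemes per subset count.
    ``records`` must carry ``target`` and ``nuisance`` columns (e.g.
    iterations/subsets); an incomplete target x nuisance grid raises and
    names the missing cell.

    Returns records with one value per feature x region x target level;
    ``x_value``/``level`` are replaced by the target level.
    """
    for col in (target, nuisance):
        if col not in records.columns:
            raise ValueError(f"records lack the {col!r} column")
    nuisance_levels = sorted(records[nuisance].unique())
    rows = []
    for (feature, region, tgt), sub in records.groupby(
            ["feature", "region", target], sort=True):
        present = sorted(sub[nuisance].unique())
        if present != nuisance_levels:
            missing = sorted(set(nuisance_levels) - set(present))
            raise ValueError(
                f"incomplete grid: feature {feature!r}, region {region!r}, "
                f"{target}={tgt} is missing {nuisance}={missing}")
        first = sub.iloc[0]
        rows.append(dict(
            feature=feature,
            family=first.get("family", ""),
            region=region,
            group=first.get("group", ""),
            level=str(tgt),
            x_value=float(tgt),
            value=float(sub["value"].mean()),
            valid=bool(sub["valid"].all()) if "valid" in sub else True,
            reason="",
        ))
    return pd.DataFrame(rows)


def region_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Per-region volume and intensity covariates for the effects models.

    Volume is the shape MeshVolume feature and intensity the first-order
    Mean, pulled from the same extraction records; returns one row per
    (region, group, level).
    """
    if records.empty:
        raise ValueError("empty feature table")
    vol = records[records["feature"] == "shape_MeshVolume"]
    inten = records[records["feature"] == "first-order_Mean"]
    if vol.empty or inten.empty:
        raise ValueError(
            "records must include shape_MeshVolume and first-order_Mean")
    keys = ["region", "group", "level"]
    v = vol.set_index(keys)["value"].rename("mesh_volume")
    m = inten.set_index(keys)["value"].rename("mean_intensity")
    x = (records.drop_duplicates(keys).set_index(keys)["x_value"]
         if "x_value" in records.columns else None)
    out = pd.concat([v, m], axis=1)
    if x is not None:
        out["x_value"] = x
    out = out.dropna(subset=["mesh_volume", "mean_intensity"]).reset_index()
    return out
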
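"""Feature extraction: registry, closed-form values and table utilities."""

import numpy as np
import pandas as pd
import pytest

from radiorobust.extraction import (
    aggregate_nuisance,
    extract_features,
    filter_invalid,
    region_covariates,
)
from radiorobust.features import (
    FAMILY_COUNTS,
    FEATURE_REGISTRY,
    compute_all_features,
)
from radiorobust.features.base import DIRECTIONS_13, OFFSETS_26, discretize
from radiorobust.phantom import ImageVolume

EXPECTED_FAMILY_COUNTS = {
    "shape": 14,
    "first-order": 18,
    "GLCM": 24,
    "GLDM": 14,
    "GLRLM": 16,
    "GLSZM": 16,
    "NGTDM": 5,
}


def _ball_volume(shape=(24, 24, 24), radius=9.0, spacing=(1.0, 1.0, 1.0),
                 seed=0):
    z, y, x = np.indices(shape)
    c = (np.array(shape) - 1) / 2.0
    mask = ((x - c[2]) ** 2 + (y - c[1]) ** 2 + (z - c[0]) ** 2) <= radius**2
    rng = np.random.default_rng(seed)
    img = 10.0 + rng.normal(0, 1, shape)
    return (ImageVolume(img, spacing),
            ImageVolume(mask.astype(np.int16), spacing))


def test_registry_counts():
    assert FAMILY_COUNTS == EXPECTED_FAMILY_COUNTS
    assert sum(FAMILY_COUNTS.values()) == 107
    assert len(FEATURE_REGISTRY) == 107


def test_direction_set():
    assert len(DIRECTIONS_13) == 13
    assert len(OFFSETS_26) == 26
    # the 13 directions plus their negations cover the 26-neighbourhood
    cover = {tuple(d) for d in DIRECTIONS_13}
    cover |= {tuple(-np.array(d)) for d in DIRECTIONS_13}
    assert cover == {tuple(o) for o in OFFSETS_26}


def test_compute_all_features_count_and_validity():
    img, mask = _ball_volume()
    values, invalid = compute_all_features(img.data, mask.data.astype(bool),
                                           mask.spacing)
    assert len(values) + sum(FAMILY_COUNTS[f] for f in invalid) == 107
    assert invalid == {}
    assert all(np.isfinite(v) for v in values.values())


def test_first_order_closed_forms():
    img, mask = _ball_volume()
    values, _ = compute_all_features(img.data, mask.data.astype(bool),
                                     mask.spacing)
    x = img.data[mask.data.astype(bool)]
    assert values[("first-order", "Mean")] == pytest.approx(x.mean())
    assert values[("first-order", "Energy")] == pytest.approx(np.sum(x**2))
    assert values[("first-order", "Variance")] == pytest.approx(x.var())
    assert values[("first-order", "Range")] == pytest.approx(np.ptp(x))
    assert values[("first-order", "Maximum")] == pytest.approx(x.max())
    assert values[("first-order", "10Percentile")] == pytest.approx(
        np.percentile(x, 10))


def test_constant_voi_degenerate_values():
    img, mask = _ball_volume()
    flat = ImageVolume(np.full_like(img.data, 7.0), img.spacing)
    values, invalid = compute_all_features(flat.data, mask.data.astype(bool),
                                           mask.spacing)
    assert values[("first-order", "Variance")] == pytest.approx(0.0)
    assert values[("first-order", "Uniformity")] == pytest.approx(1.0)
    assert abs(values[("first-order", "Entropy")]) < 1e-9
    assert values[("GLCM", "Correlation")] == pytest.approx(1.0)
    assert abs(values[("GLSZM", "ZoneEntropy")]) < 1e-9


def test_mesh_volume_close_to_analytic_sphere():
    img, mask = _ball_volume(shape=(40, 40, 40), radius=15.0)
    values, _ = compute_all_features(img.data, mask.data.astype(bool),
                                     mask.spacing)
    analytic = 4.0 / 3.0 * np.pi * 15.0**3
    assert values[("shape", "MeshVolume")] == pytest.approx(analytic,
                                                            rel=0.02)
    # marching cubes on a binary mask overestimates the surface
    # (staircase artefact), so sphericity sits a little below 1
    assert 0.85 < values[("shape", "Sphericity")] <= 1.0


def test_single_voxel_invalidates_texture():
    img = np.ones((5, 5, 5))
    mask = np.zeros((5, 5, 5), bool)
    mask[2, 2, 2] = True
    values, invalid = compute_all_features(img, mask, (1, 1, 1))
    assert set(invalid) == {"GLCM", "GLRLM", "GLSZM", "GLDM", "NGTDM"}
    assert len(values) == 107 - sum(FAMILY_COUNTS[f] for f in invalid)


def test_discretize_fixed_bin_count():
    x = np.linspace(0.0, 1.0, 100)
    disc, n_levels = discretize(x, np.ones(100, bool), 64)
    assert n_levels == 64
    assert disc.min() == 1 and disc.max() == 64
    const, n1 = discretize(np.full(10, 3.0), np.ones(10, bool), 64)
    assert n1 == 1 and set(const) == {1}


def test_extract_features_frame():
    img, mask = _ball_volume()
    frame = extract_features(img, mask)
    assert len(frame) == 107
    assert set(frame["family"].value_counts().to_dict().items()) == set(
        EXPECTED_FAMILY_COUNTS.items())
    assert frame["valid"].all()
    assert (frame["feature"].str.split("_").str[0]
            == frame["family"]).all()


def test_filter_invalid_drops_feature_region_pairs():
    rows = []
    for level, x in [("1", 1.0), ("2", 2.0)]:
        for region in ("rA", "rB"):
            for feat, ok in [("f_good", True),
                             ("f_bad", not (level == "2" and region == "rB"))]:
                rows.append(dict(feature=feat, family="fam", region=region,
                                 group="g", level=level, x_value=x,
                                 value=1.0, valid=ok,
                                 reason="" if ok else "degenerate"))
    table = pd.DataFrame(rows)
    filtered, log = filter_invalid(table)
    kept = set(zip(filtered["feature"], filtered["region"]))
    assert ("f_bad", "rB") not in kept
    assert ("f_bad", "rA") in kept and ("f_good", "rB") in kept
    assert any("f_bad" in line for line in log)


def _updates_records():
    rows = []
    for it in (1, 2):
        for su in (16, 28):
            for region in ("rA", "rB"):
                rows.append(dict(feature="f0", family="fam", region=region,
                                 group="osem_updates", level=f"{it}x{su}",
                                 x_value=float(it * su), value=float(it * 10 + su),
                                 valid=True, reason="",
                                 iterations=it, subsets=su))
    return pd.DataFrame(rows)


def test_aggregate_nuisance_means():
    agg = aggregate_nuisance(_updates_records(), target="iterations",
                             nuisance="subsets")
    sub = agg[(agg.feature == "f0") & (agg.region == "rA")]
    got = sub.set_index("x_value")["value"].to_dict()
    # mean over subsets {16, 28} at each iteration count
    assert got == {1.0: pytest.approx(32.0), 2.0: pytest.approx(42.0)}
    assert (agg["level"] == agg["x_value"].astype(int).astype(str)).all()


def test_aggregate_nuisance_incomplete_grid_raises():
    records = _updates_records().iloc[:-1]
    with pytest.raises(ValueError, match="incomplete grid"):
        aggregate_nuisance(records, target="iterations", nuisance="subsets")


def test_region_covariates():
    rows = []
    for region, vol, mean in [("rA", 100.0, 9.0), ("rB", 50.0, 4.0)]:
        rows.append(dict(feature="shape_MeshVolume", family="shape",
                         region=region, group="g", level="1", x_value=1.0,
                         value=vol, valid=True, reason=""))
        rows.append(dict(feature="first-order_Mean", family="first-order",
                         region=region, group="g", level="1", x_value=1.0,
                         value=mean, valid=True, reason=""))
    cov = region_covariates(pd.DataFrame(rows))
    assert len(cov) == 2
    row = cov[cov.region == "rA"].iloc[0]
    assert row.mesh_volume == 100.0 and row.mean_intensity == 9.0
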
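"""Shared fixtures: small phantom volumes and synthetic feature tables."""

import numpy as np
import pandas as pd
import pytest

from radiorobust.phantom import (
    EffectModel,
    FeatureSimSpec,
    PhantomSpec,
    build_activity_map,
    make_voi_masks,
    simulate_feature_values,
)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(axial_extent=120.0)


@pytest.fixture(scope="session")
def activity_128(phantom_spec):
    """Noise-free activity map on the coarse 128 grid (fast)."""
    return build_activity_map(phantom_spec, 128)


@pytest.fixture(scope="session")
def masks_128(phantom_spec):
    masks, warnings_ = make_voi_masks(phantom_spec, 128)
    return masks, warnings_


@pytest.fixture(scope="session")
def effect_model():
    return EffectModel()


def make_feature_table(families, noise_sd=0.0, seed=0, regions=9,
                       x_levels=(2.0, 3.0, 4.0, 6.0, 8.0, 10.0),
                       group_name="g1"):
    """Long-format table with one synthetic feature per requested family."""
    frames = []
    for i, fam in enumerate(families):
        spec = FeatureSimSpec(function_family=fam, alpha_range=(1.0, 3.0),
                              beta_range=(5.0, 10.0), noise_sd=noise_sd,
                              regions=regions, x_levels=x_levels,
                              group_name=group_name, feature_name=f"f{i}")
        frames.append(simulate_feature_values(spec, seed=seed + i))
    table = pd.concat(frames, ignore_index=True)
    table["family"] = "synthetic"
    return table


@pytest.fixture()
def synthetic_table():
    return make_feature_table(["a/x+b", "a*x+b", "a*log(x)+b"],
                              noise_sd=0.02, seed=100)


def null_effects_frame(seed=0, n_regions=9, n_levels=11):
    """(region, parameter, volume, intensity, value) rows with covariates
    varying per region x level and no volume/intensity effect on value."""
    rng = np.random.default_rng(seed)
    x = np.linspace(2, 12, n_levels)
    rows = []
    for i in range(n_regions):
        a = rng.uniform(1, 2)
        b = rng.uniform(0, 1)
        vol = rng.uniform(1, 10) + rng.normal(0, 1, x.size)
        inten = rng.uniform(1, 10) + rng.normal(0, 1, x.size)
        for j, xv in enumerate(x):
            rows.append(dict(region=f"r{i}", parameter=xv, volume=vol[j],
                             intensity=inten[j],
                             value=a * xv + b + rng.normal(0, 0.1)))
    return pd.DataFrame(rows)
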
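"""Digital phantom geometry, reconstruction effects and determinism."""

import numpy as np
import pytest

from radiorobust.grid import SettingSpec
from radiorobust.phantom import (
    REGION_LABELS,
    EffectModel,
    FeatureSimSpec,
    GeometryError,
    ImageVolume,
    PhantomSpec,
    build_activity_map,
    load_nifti,
    make_voi_masks,
    measured_activity_ratio,
    save_nifti,
    simulate_feature_values,
    simulate_reconstruction,
)


def test_phantom_spec_defaults(phantom_spec):
    assert phantom_spec.sphere_diameters == (37, 28, 22, 17, 13, 10)
    assert phantom_spec.sphere_activity == 20.0
    assert phantom_spec.background_activity == 5.0


def test_phantom_spec_validation():
    with pytest.raises(GeometryError):
        PhantomSpec(sphere_diameters=(10, 20, 30))  # not decreasing
    with pytest.raises(GeometryError):
        PhantomSpec(sphere_activity=-1)


def test_activity_values(activity_128, masks_128):
    masks, _ = masks_128
    lab = masks.data
    act = activity_128.data
    # lung insert carries zero activity, background its nominal value
    assert act[lab == 9].max() == 0.0
    bg = act[np.isin(lab, (7, 8))]
    np.testing.assert_allclose(bg.mean(), 5.0, rtol=0.02)


def test_interior_sphere_background_ratio(activity_128, masks_128):
    masks, _ = masks_128
    ratio = measured_activity_ratio(activity_128, masks)
    assert ratio == pytest.approx(4.0, rel=0.02)


def test_voi_labels_complete_and_disjoint(masks_128):
    masks, warnings_ = masks_128
    labels = set(np.unique(masks.data)) - {0}
    assert labels == set(REGION_LABELS)
    assert warnings_ == []


def test_reconstruction_deterministic(activity_128, effect_model):
    spec = SettingSpec(matrix_size=128)
    a = simulate_reconstruction(activity_128, spec, effect_model, 7)
    b = simulate_reconstruction(activity_128, spec, effect_model, 7)
    c = simulate_reconstruction(activity_128, spec, effect_model, 8)
    np.testing.assert_array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_noise_scales_inverse_sqrt_time(effect_model):
    s1 = effect_model.noise_sigma(SettingSpec(acquisition_time=1))
    s4 = effect_model.noise_sigma(SettingSpec(acquisition_time=4))
    assert s1 / s4 == pytest.approx(2.0)


def test_noise_scales_sqrt_updates(effect_model):
    base = effect_model.noise_sigma(SettingSpec(iterations=2, subsets=28))
    quad = effect_model.noise_sigma(SettingSpec(iterations=8, subsets=28))
    assert quad / base == pytest.approx(2.0)


def test_tof_reduces_noise(effect_model):
    tof = effect_model.noise_sigma(SettingSpec(algorithm="TOF-OSEM"))
    plain = effect_model.noise_sigma(SettingSpec(algorithm="OSEM"))
    assert tof < plain


def test_bpl_beta_monotone_smoothing(effect_model):
    fwhms = [effect_model.beta_fwhm(b) for b in (50, 350, 1000)]
    assert fwhms[0] > fwhms[1] > fwhms[2] > 0


def test_gaussian_smoothing_lowers_peak(activity_128, effect_model):
    lo = simulate_reconstruction(
        activity_128, SettingSpec(matrix_size=128, gaussian_fwhm=0),
        effect_model, seed=0)
    hi = simulate_reconstruction(
        activity_128, SettingSpec(matrix_size=128, gaussian_fwhm=10),
        effect_model, seed=0)
    assert hi.data.max() < lo.data.max()


def test_zfilter_monotone_smoothing(activity_128, masks_128, effect_model):
    """Heavier z-filters reduce the within-sphere axial peak."""
    masks, _ = masks_128
    sphere = masks.data == 1
    peaks = []
    for zf in ("None", "Light", "Standard", "Heavy"):
        rec = simulate_reconstruction(
            activity_128, SettingSpec(matrix_size=128, z_filter=zf,
                                      gaussian_fwhm=0),
            effect_model, seed=0)
        peaks.append(rec.data[sphere].max())
    assert peaks == sorted(peaks, reverse=True)


def test_partial_volume_small_sphere(activity_128, masks_128, effect_model):
    """The 10 mm sphere's measured mean falls as the blur widens."""
    masks, _ = masks_128
    small = masks.data == 6
    means = []
    for fwhm in (0.0, 4.0, 8.0):
        rec = simulate_reconstruction(
            activity_128, SettingSpec(matrix_size=128, gaussian_fwhm=fwhm),
            effect_model, seed=0)
        means.append(rec.data[small].mean())
    assert means[0] > means[1] > means[2]


def test_matrix_resampling_changes_grid(activity_128, effect_model):
    rec = simulate_reconstruction(activity_128,
                                  SettingSpec(matrix_size=192),
                                  effect_model, seed=0)
    assert rec.data.shape[0] == 192 and rec.data.shape[1] == 192


def test_nifti_roundtrip(tmp_path):
    vol = ImageVolume(np.arange(24, dtype=float).reshape(2, 3, 4),
                      spacing=(1.5, 1.5, 2.0))
    save_nifti(vol, tmp_path / "v.nii.gz")
    back = load_nifti(tmp_path / "v.nii.gz")
    np.testing.assert_allclose(back.data, vol.data)
    np.testing.assert_allclose(back.spacing, vol.spacing)


def test_simulate_feature_values_closed_form():
    spec = FeatureSimSpec(function_family="a/x+b", alpha_range=(2.0, 2.0),
                          beta_range=(1.0, 1.0), noise_sd=0.0,
                          regions=2, x_levels=(10.0, 20.0))
    table = simulate_feature_values(spec, seed=0)
    v = table.set_index(["region", "x_value"])["value"]
    assert v[("region1", 10.0)] == pytest.approx(1.2)
    assert v[("region2", 20.0)] == pytest.approx(1.1)
    assert table.attrs["true_family"] == "a/x+b"


def test_simulate_feature_values_validation():
    with pytest.raises(ValueError):
        FeatureSimSpec(function_family="a*exp(x)+b")
    with pytest.raises(ValueError):
        FeatureSimSpec(x_levels=(1.0, 2.0))  # x == 1 forbidden
    with pytest.raises(ValueError):
        FeatureSimSpec(noise_sd=-0.1)
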
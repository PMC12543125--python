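"""Digital NEMA-IQ-style phantom and image-domain reconstruction surrogate.

The physical phantom carries six fillable spheres (internal diameters 37,
28, 22, 17, 13 and 10 mm) filled at a 4:1 activity ratio to a uniform
background, plus a central low-density "lung" cylinder.  This module
rasterizes that geometry onto any of the study's voxel grids with
subvoxel supersampling at insert boundaries, produces the nine analysis
VOIs (six spheres, two background samples, one lung sample), and applies
an image-domain surrogate for the acquisition/reconstruction effects under
study:

* resolution/contrast — 3D Gaussian blur whose FWHM combines an
  algorithm-dependent base width, the post-reconstruction Gaussian filter
  and (for BPL) a β-dependent width in quadrature, followed by an axial
  three-point kernel for the z-axis filter;
* noise — additive Gaussian with σ ∝ time^(-1/2) and σ ∝ updates^(+1/2),
  reduced by time-of-flight.

The surrogate reproduces the directions of the real parameter effects
(more smoothing ⇒ lower image variance, longer scans ⇒ less noise, more
updates ⇒ more noise), not scanner-accurate magnitudes; no sinogram,
attenuation or scatter physics is modelled.

A separate generator, :func:`simulate_feature_values`, draws feature
tables directly from a known response family v = α_r·g(x) + β_r + ε for
parameter-recovery tests of the correction stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from radiorobust.functions import FAMILY_ORDER, g_transform
from radiorobust.grid import SettingSpec, encode_zfilter

__all__ = [
    "ImageVolume",
    "PhantomSpec",
    "EffectModel",
    "FeatureSimSpec",
    "GeometryError",
    "REGION_LABELS",
    "build_activity_map",
    "make_voi_masks",
    "simulate_reconstruction",
    "simulate_feature_values",
    "measured_activity_ratio",
    "save_nifti",
    "load_nifti",
]

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

REGION_LABELS = {
    1: "sphere1",
    2: "sphere2",
    3: "sphere3",
    4: "sphere4",
    5: "sphere5",
    6: "sphere6",
    7: "Bckgrnd1R",
    8: "Bckgrnd2L",
    9: "LungInsert",
}
LABEL_BY_NAME = {v: k for k, v in REGION_LABELS.items()}


class GeometryError(ValueError):
    """Raised when phantom geometry cannot be rasterized on the grid."""


@dataclass
class ImageVolume:
    """3D scalar field with voxel spacing in mm, array index order (x, y, z)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def shape(self):
        return self.data.shape

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def save_nifti(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI with an RAS+ diagonal affine (spacing in mm)."""
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))


def load_nifti(path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.get_fdata()), spacing)


@dataclass
class PhantomSpec:
    """Geometry and activity of the digital image-quality phantom.

    Sphere centres default to the NEMA-IQ layout: coplanar, equally spaced
    on a 114.4 mm-diameter circle around the central lung insert.
    Activities are kBq/mL; the defaults give the study's 4:1
    sphere-to-background ratio with spheres at 20 kBq/mL.
    """

    sphere_diameters: tuple = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)
    sphere_activity: float = 20.0
    background_activity: float = 5.0
    lung_activity: float = 0.0
    field_of_view: float = 600.0       # transaxial, mm
    axial_extent: float = 180.0        # mm
    sphere_ring_diameter: float = 114.4
    lung_diameter: float = 50.0        # lung-insert cylinder
    background_voi_diameter: float = 30.0
    lung_voi_diameter: float = 25.0
    sphere_centres: tuple | None = None          # ((x, y, z) mm, ...) or None
    background_sample_centres: tuple = ((160.0, 0.0, 0.0), (-160.0, 0.0, 0.0))
    lung_sample_centre: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        d = tuple(float(v) for v in self.sphere_diameters)
        if any(v <= 0 for v in d):
            raise GeometryError("sphere diameters must be positive")
        if any(nxt >= prev for nxt, prev in zip(d[1:], d)):
            raise GeometryError("sphere diameters must be strictly decreasing")
        if self.sphere_activity < 0 or self.background_activity < 0 \
                or self.lung_activity < 0:
            raise GeometryError("activities must be non-negative")
        if self.field_of_view <= 0 or self.axial_extent <= 0:
            raise GeometryError("field of view and axial extent must be positive")
        if self.background_activity > 0:
            ratio = self.sphere_activity / self.background_activity
        else:
            ratio = math.inf
        self.activity_ratio = ratio

    def resolved_sphere_centres(self) -> list[tuple[float, float, float]]:
        if self.sphere_centres is not None:
            return [tuple(map(float, c)) for c in self.sphere_centres]
        r = self.sphere_ring_diameter / 2.0
        out = []
        for i in range(len(self.sphere_diameters)):
            ang = 2.0 * math.pi * i / max(len(self.sphere_diameters), 1)
            out.append((r * math.cos(ang), r * math.sin(ang), 0.0))
        return out


@dataclass
class EffectModel:
    """Constants of the image-domain reconstruction surrogate.

    noise_sigma0 is the background noise SD (kBq/mL) at the reference
    acquisition time and update count; base_fwhm_mm the intrinsic
    resolution of the simulated system.  fwhm(β) = bpl_fwhm_scale ·
    exp(−β / bpl_fwhm_decay) mm adds BPL smoothing; PSF modelling sharpens
    the base resolution by psf_contrast_gain and TOF scales noise by
    tof_noise_factor.
    """

    noise_sigma0: float = 0.5          # kBq/mL at reference conditions
    reference_time: float = 3.0        # min
    reference_updates: int = 56        # 2 iterations x 28 subsets
    update_noise_exponent: float = 0.5
    base_fwhm_mm: float = 4.0
    bpl_fwhm_scale: float = 7.0        # mm
    bpl_fwhm_decay: float = 350.0      # beta units
    psf_contrast_gain: float = 1.05
    tof_noise_factor: float = 0.85

    def beta_fwhm(self, beta: float) -> float:
        return self.bpl_fwhm_scale * math.exp(-beta / self.bpl_fwhm_decay)

    def noise_sigma(self, s: SettingSpec) -> float:
        sigma = self.noise_sigma0 * math.sqrt(
            self.reference_time / s.acquisition_time
        )
        if not s.is_bpl and s.updates is not None:
            sigma *= (s.updates / self.reference_updates) ** self.update_noise_exponent
        if s.is_tof:
            sigma *= self.tof_noise_factor
        return sigma

    def total_fwhm(self, s: SettingSpec) -> float:
        base = self.base_fwhm_mm
        if s.is_psf:
            base = base / self.psf_contrast_gain
        parts = [base**2, s.gaussian_fwhm**2]
        if s.is_bpl and s.beta is not None:
            parts.append(self.beta_fwhm(s.beta) ** 2)
        return math.sqrt(sum(parts))


def _grid_axes(matrix_size: int, slice_thickness: float, spec: PhantomSpec):
    dx = spec.field_of_view / matrix_size
    nz = max(int(round(spec.axial_extent / slice_thickness)), 1)
    xs = (np.arange(matrix_size) - (matrix_size - 1) / 2.0) * dx
    zs = (np.arange(nz) - (nz - 1) / 2.0) * slice_thickness
    return xs, zs, (dx, dx, slice_thickness)


def _check_inside(spec: PhantomSpec, centre, radius, spacing) -> None:
    half_fov = spec.field_of_view / 2.0
    half_ax = spec.axial_extent / 2.0
    cx, cy, cz = centre
    if (abs(cx) + radius > half_fov or abs(cy) + radius > half_fov
            or abs(cz) + radius > half_ax):
        raise GeometryError(
            f"insert at {centre} with radius {radius} mm extends outside "
            f"the {spec.field_of_view} x {spec.axial_extent} mm grid"
        )


def _sphere_occupancy(shape, xs, zs, spacing, centre, radius, supersample=4):
    """Fractional voxel occupancy of a sphere, supersampled at its boundary."""
    occ = np.zeros(shape, dtype=np.float64)
    dx, dy, dz = spacing
    half_diag = 0.5 * math.sqrt(dx**2 + dy**2 + dz**2)
    cx, cy, cz = centre
    # bounding box in index space
    i0 = np.searchsorted(xs, cx - radius - dx)
    i1 = np.searchsorted(xs, cx + radius + dx)
    j0 = np.searchsorted(xs, cy - radius - dy)
    j1 = np.searchsorted(xs, cy + radius + dy)
    k0 = np.searchsorted(zs, cz - radius - dz)
    k1 = np.searchsorted(zs, cz + radius + dz)
    if i0 >= i1 or j0 >= j1 or k0 >= k1:
        return occ
    gx = xs[i0:i1] - cx
    gy = xs[j0:j1] - cy
    gz = zs[k0:k1] - cz
    d = np.sqrt(gx[:, None, None] ** 2 + gy[None, :, None] ** 2
                + gz[None, None, :] ** 2)
    sub = occ[i0:i1, j0:j1, k0:k1]
    sub[d <= radius - half_diag] = 1.0
    boundary = (d > radius - half_diag) & (d < radius + half_diag)
    if np.any(boundary):
        bi, bj, bk = np.nonzero(boundary)
        s = supersample
        offs = (np.arange(s) + 0.5) / s - 0.5
        ox, oy, oz = np.meshgrid(offs * dx, offs * dy, offs * dz,
                                 indexing="ij")
        ox, oy, oz = ox.ravel(), oy.ravel(), oz.ravel()
        px = gx[bi][:, None] + ox[None, :]
        py = gy[bj][:, None] + oy[None, :]
        pz = gz[bk][:, None] + oz[None, :]
        inside = (px**2 + py**2 + pz**2) <= radius**2
        sub[bi, bj, bk] = inside.mean(axis=1)
    occ[i0:i1, j0:j1, k0:k1] = sub
    return occ


def _cylinder_occupancy(shape, xs, spacing, centre_xy, radius, supersample=4):
    """Fractional occupancy of an axial cylinder spanning the whole grid."""
    dx, dy = spacing[0], spacing[1]
    half_diag = 0.5 * math.sqrt(dx**2 + dy**2)
    cx, cy = centre_xy
    gx = xs - cx
    gy = xs - cy
    d = np.sqrt(gx[:, None] ** 2 + gy[None, :] ** 2)
    plane = np.zeros((shape[0], shape[1]), dtype=np.float64)
    plane[d <= radius - half_diag] = 1.0
    boundary = (d > radius - half_diag) & (d < radius + half_diag)
    if np.any(boundary):
        bi, bj = np.nonzero(boundary)
        s = supersample
        offs = (np.arange(s) + 0.5) / s - 0.5
        ox, oy = np.meshgrid(offs * dx, offs * dy, indexing="ij")
        ox, oy = ox.ravel(), oy.ravel()
        px = gx[bi][:, None] + ox[None, :]
        py = gy[bj][:, None] + oy[None, :]
        plane[bi, bj] = ((px**2 + py**2) <= radius**2).mean(axis=1)
    return np.repeat(plane[:, :, None], shape[2], axis=2)


def build_activity_map(
    spec: PhantomSpec,
    matrix_size: int,
    slice_thickness: float = 2.78,
    supersample: int = 4,
) -> ImageVolume:
    """Rasterize the noise-free activity concentration map.

    Voxels inside sphere i take ``sphere_activity``, inside the lung
    cylinder ``lung_activity``, elsewhere ``background_activity``; voxels
    straddling a boundary mix the two linearly by subvoxel occupancy.
    """
    if not spec.sphere_diameters:
        raise GeometryError("phantom has no sphere inserts")
    xs, zs, spacing = _grid_axes(matrix_size, slice_thickness, spec)
    shape = (matrix_size, matrix_size, len(zs))
    vol = np.full(shape, spec.background_activity, dtype=np.float64)

    lung = _cylinder_occupancy(shape, xs, spacing,
                               spec.lung_sample_centre[:2],
                               spec.lung_diameter / 2.0, supersample)
    vol += (spec.lung_activity - spec.background_activity) * lung

    for diam, centre in zip(spec.sphere_diameters,
                            spec.resolved_sphere_centres()):
        radius = diam / 2.0
        _check_inside(spec, centre, radius, spacing)
        occ = _sphere_occupancy(shape, xs, zs, spacing, centre, radius,
                                supersample)
        vol += (spec.sphere_activity - spec.background_activity) * occ

    return ImageVolume(vol, spacing)


def make_voi_masks(
    spec: PhantomSpec,
    matrix_size: int,
    slice_thickness: float = 2.78,
) -> tuple[ImageVolume, list[str]]:
    """Rasterize the nine analysis VOIs as an integer label map.

    Labels 1–6 are the sphere inserts (largest to smallest, VOI diameter =
    insert inner diameter), 7–8 spherical background samples, 9 a sphere
    inside the lung insert.  A voxel belongs to a VOI when its centre
    falls inside the VOI sphere.  Returns the label map and a list of
    low-voxel-count warnings (VOIs whose rasterization left < 2 voxels or
    none at all feed the extraction validity filter).
    """
    if not spec.sphere_diameters:
        raise GeometryError("phantom has no sphere inserts")
    xs, zs, spacing = _grid_axes(matrix_size, slice_thickness, spec)
    shape = (matrix_size, matrix_size, len(zs))
    labels = np.zeros(shape, dtype=np.uint8)

    vois = []
    for i, (diam, centre) in enumerate(
            zip(spec.sphere_diameters, spec.resolved_sphere_centres()), 1):
        vois.append((i, centre, diam / 2.0))
    for j, centre in enumerate(spec.background_sample_centres):
        vois.append((7 + j, tuple(centre), spec.background_voi_diameter / 2.0))
    vois.append((9, tuple(spec.lung_sample_centre), spec.lung_voi_diameter / 2.0))

    warnings = []
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    for label, centre, radius in vois:
        _check_inside(spec, centre, radius, spacing)
        cx, cy, cz = centre
        d2 = ((gx - cx) ** 2 + (gy - cy) ** 2)[:, :, None] \
            + ((zs - cz) ** 2)[None, None, :]
        inside = d2 <= radius**2
        if labels[inside].any():
            raise GeometryError(
                f"VOI {REGION_LABELS.get(label, label)} overlaps another VOI"
            )
        n = int(inside.sum())
        labels[inside] = label
        if n < 2:
            warnings.append(
                f"{REGION_LABELS.get(label, label)}: only {n} voxel(s) at "
                f"matrix size {matrix_size}"
            )
    return ImageVolume(labels, spacing), warnings


def _zfilter_kernel(weight: float) -> np.ndarray | None:
    """Axial smoothing kernel for an encoded z-filter weight.

    Heavier filters (larger encoded weight) smooth more: the 3-point
    kernel [1, c, 1]/(c+2) is used with centre weight c = 8/weight, so
    Light (2) → [1,4,1]/6, Standard (4) → [1,2,1]/4, Heavy (6) →
    [1,4/3,1]/(10/3).  "None" (weight 1) applies no filtering.
    """
    if weight <= 1.0:
        return None
    c = 8.0 / weight
    return np.array([1.0, c, 1.0]) / (c + 2.0)


def simulate_reconstruction(
    activity: ImageVolume,
    s: SettingSpec,
    model: EffectModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ImageVolume:
    """Apply the image-domain surrogate for one acquisition/reconstruction.

    Stages, in order: (1) resample onto the setting's transaxial matrix if
    the input grid differs; (2) 3D Gaussian blur at the combined FWHM
    (algorithm base ⊕ post-filter ⊕ BPL β-width, in quadrature);
    (3) axial z-filter kernel; (4) additive Gaussian noise with σ from the
    effect model.  Deterministic given (activity, s, model, seed).
    """
    model = model or EffectModel()
    data = np.asarray(activity.data, dtype=np.float64)
    spacing = tuple(activity.spacing)

    if data.shape[0] != s.matrix_size:
        zoom = s.matrix_size / data.shape[0]
        data = ndimage.zoom(data, (zoom, zoom, 1.0), order=1)
        spacing = (spacing[0] / zoom, spacing[1] / zoom, spacing[2])

    fwhm = model.total_fwhm(s)
    if fwhm > 0:
        sigma_vox = [fwhm * GAUSS_FWHM_TO_SIGMA / sp for sp in spacing]
        data = ndimage.gaussian_filter(data, sigma_vox, mode="nearest")

    kernel = _zfilter_kernel(encode_zfilter(s.z_filter))
    if kernel is not None:
        data = ndimage.convolve1d(data, kernel, axis=2, mode="nearest")

    sigma = model.noise_sigma(s)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, sigma, size=data.shape)

    return ImageVolume(data, spacing)


def measured_activity_ratio(
    activity: ImageVolume,
    labels: ImageVolume,
    sphere_label: int = 1,
    background_labels: tuple = (7, 8),
    erode: int = 1,
) -> float:
    """Sphere-to-background mean activity ratio from interior voxels.

    The sphere VOI is eroded by ``erode`` voxel shells so boundary voxels
    with partial-volume mixing do not bias the mean; the background mean
    comes from the background sample VOIs.
    """
    lab = np.asarray(labels.data)
    sphere = lab == sphere_label
    if erode > 0:
        sphere = ndimage.binary_erosion(sphere, iterations=erode)
    if not sphere.any():
        raise GeometryError("sphere VOI empty after erosion")
    bg = np.isin(lab, background_labels)
    if not bg.any():
        raise GeometryError("no background VOI voxels")
    return float(activity.data[sphere].mean() / activity.data[bg].mean())


@dataclass
class FeatureSimSpec:
    """Specification for drawing feature tables from a known response family.

    Values follow v(region r, level s) = α_r · g(x_s) + β_r + ε with
    ε ~ Normal(0, σ²); α_r and β_r are drawn uniformly per region from the
    configured ranges.  x_levels are taken as already rescaled (positive,
    never 1).
    """

    function_family: str = "a/x+b"
    alpha_range: tuple[float, float] = (0.5, 2.0)
    beta_range: tuple[float, float] = (0.0, 1.0)
    noise_sd: float = 0.0
    regions: int = 9
    x_levels: tuple = (10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0,
                       100.0, 125.0, 150.0)
    group_name: str = "synthetic_group"
    feature_name: str = "synthetic_feature"

    def __post_init__(self) -> None:
        if self.function_family not in FAMILY_ORDER:
            raise ValueError(f"unknown family {self.function_family!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.regions < 2:
            raise ValueError("need at least 2 regions")
        x = np.asarray(self.x_levels, dtype=float)
        if np.any(x <= 0) or np.any(x == 1.0):
            raise ValueError("x_levels must be positive and never 1")


def simulate_feature_values(spec: FeatureSimSpec, seed: int = 0):
    """Draw a long-format feature table from the spec's response family.

    Returns a pandas DataFrame with columns (feature, family, region,
    group, x_value, value, valid); ``DataFrame.attrs`` records the true
    family and the per-region (α_r, β_r).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    alphas = rng.uniform(*spec.alpha_range, size=spec.regions)
    betas = rng.uniform(*spec.beta_range, size=spec.regions)
    x = np.asarray(spec.x_levels, dtype=float)
    g = g_transform(spec.function_family, x)

    rows = []
    for r in range(spec.regions):
        eps = rng.normal(0.0, spec.noise_sd, size=x.size) if spec.noise_sd > 0 \
            else np.zeros(x.size)
        vals = alphas[r] * g + betas[r] + eps
        for xv, v in zip(x, vals):
            rows.append(dict(feature=spec.feature_name, family="synthetic",
                             region=f"region{r + 1}", group=spec.group_name,
                             x_value=float(xv), value=float(v), valid=True))
    table = pd.DataFrame(rows)
    table.attrs["true_family"] = spec.function_family
    table.attrs["true_alpha"] = alphas.tolist()
    table.attrs["true_beta"] = betas.tolist()
    return table
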
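"""Shape descriptors (14 features) of a binary VOI mask.

Surface area and mesh volume come from a marching-cubes triangulation of
the (zero-padded) mask; axis lengths from the principal components of the
physical voxel-centre coordinates; maximum diameters from the convex hull
of the surface vertices.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from radiorobust.features.base import FeatureInvalid

FEATURE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise distance; uses the convex hull when possible."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(points) > 10:
        try:
            pts = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (flat) geometry: brute force below
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    signed = np.einsum("ij,ij->i", v0, np.cross(v1, v2)) / 6.0
    return float(abs(signed.sum()))


def compute(mask: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask).astype(bool)
    n_vox = int(mask.sum())
    if n_vox < 1:
        raise FeatureInvalid("empty-voi")
    spacing = np.asarray(spacing, dtype=float)

    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))
    volume = _mesh_volume(verts, faces)

    coords = np.argwhere(mask) * spacing
    centred = coords - coords.mean(axis=0)
    if n_vox > 1:
        cov = np.cov(centred, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)

    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    # in-plane projections for the three 2D diameters:
    # Slice drops the axial (z) axis, Column drops y, Row drops x
    d_slice = _max_pairwise(verts[:, [0, 1]])
    d_column = _max_pairwise(verts[:, [0, 2]])
    d_row = _max_pairwise(verts[:, [1, 2]])

    sphericity = float((36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area) \
        if area > 0 else 0.0

    return {
        "MeshVolume": volume,
        "VoxelVolume": n_vox * float(np.prod(spacing)),
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / volume if volume > 0 else 0.0,
        "Sphericity": sphericity,
        "Maximum3DDiameter": _max_pairwise(verts),
        "Maximum2DDiameterSlice": d_slice,
        "Maximum2DDiameterColumn": d_column,
        "Maximum2DDiameterRow": d_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }
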
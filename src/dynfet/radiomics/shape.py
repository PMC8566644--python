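"""3D shape descriptors of a binary mask.

Surface quantities come from a marching-cubes mesh of the zero-padded
binary mask (level 0.5); axis lengths from the principal components of the
physical voxel-centre coordinates (population covariance).  The three
maximum 2D diameters are the largest pairwise distances between mesh
vertices sharing a coordinate along the fixed axis: ``Slice`` fixes z
(axial plane), ``Column`` fixes x, ``Row`` fixes y.

Degenerate masks (a single voxel, or an exactly planar/linear voxel set)
report zero for the undefined axis lengths and ratios rather than failing.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

__all__ = ["shape_features", "SHAPE_NAMES"]

SHAPE_NAMES = (
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


def _mesh(mask: np.ndarray, spacing: tuple[float, float, float]):
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]  # (n, 3, 3)
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(abs(signed.sum()))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (flat) point sets: fall through to brute force
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _max_planar_diameter(verts: np.ndarray, axis: int) -> float:
    """Largest vertex-pair distance within any plane orthogonal to ``axis``."""
    coords = np.round(verts[:, axis], 6)
    best = 0.0
    for val in np.unique(coords):
        pts = verts[coords == val]
        if len(pts) >= 2:
            best = max(best, _max_pairwise(np.delete(pts, axis, axis=1)))
    return best


def shape_features(
    mask: np.ndarray, spacing_mm: tuple[float, float, float]
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("shape features need a non-empty mask")
    spacing = tuple(float(s) for s in spacing_mm)
    n_vox = int(mask.sum())
    voxel_volume = float(np.prod(spacing))

    verts, faces = _mesh(mask, spacing)
    surface = float(measure.mesh_surface_area(verts, faces))
    volume = _mesh_volume(verts, faces)

    # principal axes of physical voxel-centre coordinates
    coords = np.argwhere(mask) * np.asarray(spacing)
    if n_vox > 1:
        cov = np.cov(coords, rowvar=False, bias=True)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
    else:
        eigvals = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(e) for e in eigvals)

    sphericity = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / surface if surface > 0 else 0.0

    return {
        "MeshVolume": volume,
        "VoxelVolume": n_vox * voxel_volume,
        "SurfaceArea": surface,
        "SurfaceVolumeRatio": surface / volume if volume > 0 else 0.0,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": _max_pairwise(verts),
        "Maximum2DDiameterSlice": _max_planar_diameter(verts, axis=2),
        "Maximum2DDiameterColumn": _max_planar_diameter(verts, axis=0),
        "Maximum2DDiameterRow": _max_planar_diameter(verts, axis=1),
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 0.0,
    }
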
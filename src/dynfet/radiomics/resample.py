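"""Isotropic resampling of a parametric image and its mask.

Resampling precedes feature extraction so that texture offsets span equal
physical distances along every axis.  The image is interpolated trilinearly,
the mask with nearest neighbours; the resampled grid shares the original
origin (first voxel centre) and has ``floor(n_old * sp_old / sp_new)``
voxels per axis.

Values flagged as missing (NaN, e.g. outside the tumour VOI on a TTP map)
are filled with their nearest defined neighbour before interpolation, so
trilinear weights never mix a defined edge voxel with an arbitrary fill
constant.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from ..parametric import ParametricImage, VoxelMask

__all__ = ["resample_isotropic"]


def _nearest_fill(grid: np.ndarray) -> np.ndarray:
    """Replace NaNs with the value of the nearest non-NaN voxel."""
    nan = np.isnan(grid)
    if not nan.any():
        return grid
    if nan.all():
        raise ValueError("image contains no defined voxels")
    idx = ndimage.distance_transform_edt(nan, return_distances=False, return_indices=True)
    return grid[tuple(idx)]


def _to_sitk(grid: np.ndarray, spacing: tuple[float, float, float]) -> sitk.Image:
    # numpy (x, y, z) -> SimpleITK expects (z, y, x) array layout
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(grid, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))


def resample_isotropic(
    image: ParametricImage, mask: VoxelMask, target_mm: float = 2.03
) -> tuple[ParametricImage, VoxelMask]:
    """Resample an image/mask pair onto an isotropic grid.

    Already-isotropic inputs at the target spacing are returned unchanged.
    Raises if the resampled mask is empty.
    """
    spacing = image.voxel_spacing_mm
    if all(abs(s - target_mm) < 1e-9 for s in spacing):
        return image, mask
    if image.grid.shape != mask.grid.shape:
        raise ValueError("image and mask grids must share a shape")

    new_size = [max(1, int(np.floor(n * s / target_mm))) for n, s in zip(image.grid.shape, spacing)]

    filled = _nearest_fill(np.asarray(image.grid, dtype=float))
    img = _to_sitk(filled, spacing)
    msk = _to_sitk(mask.grid.astype(np.uint8), spacing)

    rs = sitk.ResampleImageFilter()
    rs.SetOutputSpacing((target_mm,) * 3)
    rs.SetSize([int(n) for n in new_size])  # SimpleITK size order matches our (x, y, z)
    rs.SetOutputOrigin(img.GetOrigin())
    rs.SetOutputDirection(img.GetDirection())

    rs.SetInterpolator(sitk.sitkLinear)
    new_img = _from_sitk(rs.Execute(img))
    rs.SetInterpolator(sitk.sitkNearestNeighbor)
    new_msk = _from_sitk(rs.Execute(msk)).astype(bool)

    if not new_msk.any():
        raise ValueError("mask is empty after resampling")

    out_img = ParametricImage(new_img, image.kind, (target_mm,) * 3, dict(image.meta))
    return out_img, VoxelMask(new_msk, role=mask.role)
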
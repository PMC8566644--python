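"""Full 107-feature extraction from a parametric image and mask."""

from __future__ import annotations

import numpy as np

from ..parametric import ParametricImage, VoxelMask
from .discretize import DiscretizationRule, discretize
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .resample import resample_isotropic
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    texture_features,
)

__all__ = ["FEATURE_NAMES", "extract_all"]

#: The canonical 107 feature keys, ``family.Name``.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"firstorder.{n}" for n in FIRSTORDER_NAMES)
    + tuple(f"shape.{n}" for n in SHAPE_NAMES)
    + tuple(f"glcm.{n}" for n in GLCM_NAMES)
    + tuple(f"glrlm.{n}" for n in GLRLM_NAMES)
    + tuple(f"glszm.{n}" for n in GLSZM_NAMES)
    + tuple(f"gldm.{n}" for n in GLDM_NAMES)
    + tuple(f"ngtdm.{n}" for n in NGTDM_NAMES)
)
assert len(FEATURE_NAMES) == 107


def _crop_to_mask(grid: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return grid[sl], mask[sl]


def extract_all(
    image: ParametricImage,
    mask: VoxelMask,
    rule: DiscretizationRule,
    resample_mm: float | None = 2.03,
) -> dict[str, float]:
    """Resample, discretise and compute all 107 radiomic features.

    Returns a dict with the 107 ``family.Name`` keys plus two provenance
    entries under a leading underscore (``_bin_width``, ``_n_voxels``) that
    callers may strip or keep.
    """
    if mask.n_voxels == 0:
        raise ValueError("extract_all: mask is empty")
    if image.grid.shape != mask.grid.shape:
        raise ValueError("extract_all: image and mask shapes differ")

    if resample_mm is not None:
        try:
            image, mask = resample_isotropic(image, mask, resample_mm)
        except ValueError as exc:
            raise ValueError(f"extract_all: resampling failed: {exc}") from exc
    spacing = image.voxel_spacing_mm

    grid, mgrid = _crop_to_mask(image.grid, mask.grid)
    values = grid[mgrid]
    if np.isnan(values).any():
        raise ValueError("extract_all: masked values contain NaN")

    out: dict[str, float] = {}
    try:
        fo = first_order_features(values, rule, float(np.prod(spacing)))
    except ValueError as exc:
        raise ValueError(f"extract_all: first-order stage failed: {exc}") from exc
    out.update({f"firstorder.{k}": v for k, v in fo.items()})

    try:
        sh = shape_features(mgrid, spacing)
    except ValueError as exc:
        raise ValueError(f"extract_all: shape stage failed: {exc}") from exc
    out.update({f"shape.{k}": v for k, v in sh.items()})

    levels_grid = np.zeros(grid.shape, dtype=np.int64)
    levels_grid[mgrid], _ = discretize(values, rule)
    out.update(texture_features(levels_grid, mgrid))

    missing = [k for k in FEATURE_NAMES if k not in out]
    if missing:  # internal consistency guard
        raise RuntimeError(f"feature classes incomplete: {missing[:3]}...")
    out["_bin_width"] = rule.bin_width
    out["_n_voxels"] = float(mask.n_voxels)
    return out
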
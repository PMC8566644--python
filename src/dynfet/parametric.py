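"""Parametric imaging for dynamic amino-acid PET.

Turns a 4D dynamic study into three 3D parametric maps:

* ``TBR_5_15``  — early summation image (5–15 min p.i.) divided by the mean
  activity of a healthy-hemisphere background region,
* ``TBR_20_40`` — standard late summation image (20–40 min p.i.), normalised
  the same way,
* ``TTP``       — a six-level time-to-peak map encoding, per voxel, the time
  frame in which the time-activity curve (TAC) peaks.

Tumour delineation uses the conventional TBR >= 1.6 threshold on the late
summation image; studies with no voxel above threshold are "FET-negative"
and rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .frames import FrameSchedule

__all__ = [
    "DynamicStudy",
    "VoxelMask",
    "ParametricImage",
    "TTPCategory",
    "TTP_CATEGORIES",
    "TTP_REPRESENTATIVE_MIN",
    "FETNegativeError",
    "summation_image",
    "background_mean",
    "tbr_image",
    "tbr_from_study",
    "segment_tumour",
    "classify_voxel_ttp",
    "ttp_image",
]

#: Exclusion window for TTP: frames ending within the first 2.7 min are
#: dominated by the vascular blood flush and are ineligible for the peak.
BLOOD_FLUSH_CUTOFF_S = 162.0

#: Window (minutes) over which the late slope is fitted; a positive late
#: slope forces TTP category 6 regardless of the frame arg-max.
LATE_SLOPE_WINDOW_MIN = (15.0, 40.0)


class FETNegativeError(ValueError):
    """No voxel reaches the tumour-to-background threshold (FET-negative study)."""


@dataclass(frozen=True)
class TTPCategory:
    """One of the six ordinal time-to-peak classes."""

    ordinal: int
    bounds_min: tuple[float, float]
    representative_min: float


TTP_CATEGORIES: tuple[TTPCategory, ...] = tuple(
    TTPCategory(i + 1, (lo, hi), 0.5 * (lo + hi))
    for i, (lo, hi) in enumerate(
        [(0.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 20.0), (20.0, 30.0), (30.0, 40.0)]
    )
)

#: Numeric voxel encoding of each category: the interval midpoint in minutes.
TTP_REPRESENTATIVE_MIN = {c.ordinal: c.representative_min for c in TTP_CATEGORIES}


@dataclass
class DynamicStudy:
    """A 4D dynamic PET volume with its frame schedule and voxel spacing.

    ``volume4d`` is indexed ``(frame, x, y, z)``; activities are
    non-negative, in arbitrary units.
    """

    volume4d: np.ndarray
    schedule: FrameSchedule
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.volume4d = np.asarray(self.volume4d)
        if self.volume4d.ndim != 4:
            raise ValueError("volume4d must be 4D (frame, x, y, z)")
        if self.volume4d.shape[0] != len(self.schedule):
            raise ValueError(
                f"frame mismatch: volume has {self.volume4d.shape[0]} frames, "
                f"schedule has {len(self.schedule)}"
            )
        if np.any(self.volume4d < 0):
            raise ValueError("activities must be non-negative")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing components must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volume4d.shape[1:]


@dataclass
class VoxelMask:
    """A boolean voxel selection aligned to a study grid."""

    grid: np.ndarray
    role: str = "tumour"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class ParametricImage:
    """A 3D scalar map derived from a dynamic study."""

    grid: np.ndarray
    kind: str  # "TBR_5_15" | "TBR_20_40" | "TTP"
    voxel_spacing_mm: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("parametric image must be 3D")
        if self.kind not in ("TBR_5_15", "TBR_20_40", "TTP"):
            raise ValueError(f"unknown parametric image kind: {self.kind!r}")


def summation_image(study: DynamicStudy, window_min: tuple[float, float]) -> np.ndarray:
    """Duration-weighted mean of the frames whose mid-time falls in a window.

    A frame contributes iff its mid-time (minutes) lies in ``[t0, t1)``.  On
    the default 16-frame schedule the (20, 40) window selects exactly the two
    10-min frames (mid-times 24.67 and 34.67 min) and the (5, 15) window the
    two 5-min frames at mid-times 7.17 and 12.17 min.
    """
    t0, t1 = window_min
    mids = study.schedule.mid_times_min
    sel = (mids >= t0) & (mids < t1)
    if not sel.any():
        raise ValueError(f"no frame mid-time falls in the window [{t0}, {t1}) min")
    w = study.schedule.durations_s[sel]
    frames = study.volume4d[sel]
    return np.tensordot(w / w.sum(), frames, axes=(0, 0))


def background_mean(image: np.ndarray, background: VoxelMask) -> float:
    """Mean activity over the background VOI."""
    if background.n_voxels == 0:
        raise ValueError("background mask is empty")
    return float(np.asarray(image)[background.grid].mean())


def tbr_image(
    image: np.ndarray,
    bg: float,
    kind: str,
    voxel_spacing_mm: tuple[float, float, float],
) -> ParametricImage:
    """Normalise a summation image by the background mean to obtain a TBR map."""
    if bg <= 0:
        raise ValueError(f"background mean must be positive, got {bg}")
    return ParametricImage(np.asarray(image) / bg, kind, voxel_spacing_mm, {"background_mean": bg})


def tbr_from_study(
    study: DynamicStudy, background: VoxelMask, window_min: tuple[float, float], kind: str
) -> ParametricImage:
    """Summation image over ``window_min`` normalised by its own background mean."""
    img = summation_image(study, window_min)
    return tbr_image(img, background_mean(img, background), kind, study.voxel_spacing_mm)


def segment_tumour(tbr2040: ParametricImage, threshold: float = 1.6) -> VoxelMask:
    """Threshold the late TBR image and keep the largest 26-connected component.

    Raises
    ------
    FETNegativeError
        If no voxel reaches the threshold (TBR < 1.6 everywhere): such
        studies carry no delineable tumour and are excluded from analysis.
    """
    if tbr2040.kind != "TBR_20_40":
        raise ValueError("tumour segmentation operates on the TBR_20_40 image")
    above = tbr2040.grid >= threshold
    if not above.any():
        raise FETNegativeError(
            f"no voxel with TBR >= {threshold}: FET-negative study"
        )
    labels, n = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return VoxelMask(labels == keep, role="tumour")


def _late_slope(tac: np.ndarray, schedule: FrameSchedule) -> float:
    """OLS slope of frame activity vs frame mid-time over the late window."""
    mids = schedule.mid_times_min
    lo, hi = LATE_SLOPE_WINDOW_MIN
    sel = (mids >= lo) & (mids < hi)
    if sel.sum() < 2:
        raise ValueError(
            f"late-slope fit needs >= 2 frames with mid-time in [{lo}, {hi}) min, "
            f"got {int(sel.sum())}"
        )
    t = mids[sel]
    y = np.asarray(tac, dtype=float)[sel]
    t_c = t - t.mean()
    return float((t_c @ (y - y.mean())) / (t_c @ t_c))


def classify_voxel_ttp(tac: np.ndarray, schedule: FrameSchedule) -> TTPCategory:
    """Assign a voxel TAC to one of the six time-to-peak categories.

    A strictly positive late slope (OLS over the 15–40 min frames) forces
    category 6.  Otherwise the arg-max frame is sought among frames ending
    after the 2.7-min blood-flush window, ties resolved toward the earliest
    frame, and its mid-time is mapped onto the category bounds.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.shape[0] != len(schedule):
        raise ValueError("TAC length does not match schedule")
    if _late_slope(tac, schedule) > 0:
        return TTP_CATEGORIES[5]
    eligible = schedule.ends_s > BLOOD_FLUSH_CUTOFF_S
    idx_eligible = np.flatnonzero(eligible)
    peak_idx = idx_eligible[int(np.argmax(tac[idx_eligible]))]
    mid = schedule.mid_times_min[peak_idx]
    for cat in TTP_CATEGORIES:
        lo, hi = cat.bounds_min
        if lo <= mid < hi:
            return cat
    # mid-times of a 40-min schedule always fall in [0, 40); guard anyway
    return TTP_CATEGORIES[-1]


def ttp_image(study: DynamicStudy, tumour: VoxelMask, missing: float = np.nan) -> ParametricImage:
    """Voxel-wise TTP classification inside the tumour mask.

    Voxel values are the category midpoints in minutes (2.5, 7.5, 12.5,
    17.5, 25, 35); voxels outside the mask carry ``missing``.
    """
    if tumour.n_voxels == 0:
        raise ValueError("tumour mask is empty")
    if tumour.grid.shape != study.grid_shape:
        raise ValueError(
            f"mask shape {tumour.grid.shape} does not match study grid {study.grid_shape}"
        )
    tacs = study.volume4d[:, tumour.grid].astype(float)  # (frames, voxels)
    schedule = study.schedule
    mids = schedule.mid_times_min

    lo, hi = LATE_SLOPE_WINDOW_MIN
    late = (mids >= lo) & (mids < hi)
    if late.sum() < 2:
        raise ValueError("late-slope fit needs >= 2 frames in the 15-40 min window")
    t_c = mids[late] - mids[late].mean()
    y = tacs[late]
    slope = t_c @ (y - y.mean(axis=0)) / (t_c @ t_c)

    eligible = schedule.ends_s > BLOOD_FLUSH_CUTOFF_S
    idx_eligible = np.flatnonzero(eligible)
    peak_idx = idx_eligible[np.argmax(tacs[idx_eligible], axis=0)]
    peak_mid = mids[peak_idx]

    bounds = np.array([c.bounds_min[0] for c in TTP_CATEGORIES] + [40.0])
    cat = np.searchsorted(bounds, peak_mid, side="right")  # 1..6
    cat = np.clip(cat, 1, 6)
    cat[slope > 0] = 6

    reps = np.array([TTP_REPRESENTATIVE_MIN[k] for k in range(1, 7)])
    grid = np.full(study.grid_shape, missing, dtype=float)
    grid[tumour.grid] = reps[cat - 1]
    return ParametricImage(grid, "TTP", study.voxel_spacing_mm)
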
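"""Synthetic dynamic-PET phantom cohorts.

Real dynamic FET-PET cohorts are not redistributable, so this module builds
desk-scale stand-ins with known ground truth.  Each phantom carries

* a flat-uptake "brain" filling the grid (activity ~= 1), a fixed
  crescent-shaped background VOI in the contralateral half of the grid,
* an ellipsoidal tumour whose voxels follow one of two kinetic archetypes —
  an early peak with subsequent washout (aggressive pattern) or a slowly
  increasing curve (indolent pattern),
* a binary label whose only effect is on the *spatial mixing* of the two
  archetypes inside the tumour: mutant tumours are a salt-and-pepper mixture
  (kinetically heterogeneous), wildtype tumours are nearly pure
  late-increasing (homogeneous).  The ``effect`` parameter scales that
  difference; at ``effect = 0`` the classes are exchangeable.

The continuous voxel kinetic model is a piecewise-linear "tent": linear rise
from ``baseline`` to ``amplitude`` at ``peak_time_min``, then a linear limb
with slope ``washout_slope`` (floored at the baseline when decreasing).
Frame values are exact duration-weighted integrals of that curve — the way a
scanner accumulates counts per frame — so every downstream quantity has a
closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import FrameSchedule, default_frame_schedule
from .parametric import DynamicStudy, VoxelMask, summation_image

__all__ = [
    "KineticParams",
    "CohortSpec",
    "PhantomStudy",
    "simulate_tac",
    "tent_frame_values",
    "generate_phantom",
    "iter_phantom",
]

TBR_FLOOR = 1.6          # every tumour voxel's noise-free late TBR is kept >= this
TBR_MARGIN = 1.05        # multiplicative headroom above the floor
BACKGROUND_ACTIVITY = 1.0


@dataclass(frozen=True)
class KineticParams:
    """Parameters of one voxel's tent-shaped time-activity curve.

    ``washout_slope`` (activity/min) <= 0 gives an early-peak/washout curve;
    > 0 encodes a late-increasing curve whose maximum sits at the end of the
    acquisition.
    """

    amplitude: float
    peak_time_min: float
    washout_slope: float
    baseline: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        # amplitude == baseline is admitted as the degenerate flat curve
        if not (self.amplitude >= self.baseline >= 0 and self.amplitude > 0):
            raise ValueError("require amplitude >= baseline >= 0 and amplitude > 0")
        if not 0 < self.peak_time_min < 40:
            raise ValueError("peak_time_min must lie in (0, 40) minutes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic cohort."""

    n_patients: int = 40
    wildtype_fraction: float = 0.2
    grid_shape: tuple[int, int, int] = (32, 32, 22)
    voxel_spacing_mm: tuple[float, float, float] = (2.03, 2.03, 2.43)
    seed: int = 0
    effect: float = 1.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if not 0 <= self.wildtype_fraction <= 1:
            raise ValueError("wildtype_fraction must be in [0, 1]")
        n_wt = _round_half_up(self.n_patients * self.wildtype_fraction)
        if 0 < self.wildtype_fraction < 1 and not 0 < n_wt < self.n_patients:
            raise ValueError("spec leaves a class empty; adjust n_patients or fraction")


@dataclass
class PhantomStudy:
    """One simulated patient: study, masks, label and planted ground truth."""

    study: DynamicStudy
    tumour: VoxelMask
    background: VoxelMask
    label: int  # 1 = mutant, 0 = wildtype
    truth: dict = field(default_factory=dict)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _tent_cumulative_integral(
    t_min: np.ndarray,
    amplitude: np.ndarray,
    baseline: np.ndarray,
    peak: np.ndarray,
    slope: np.ndarray,
) -> np.ndarray:
    """Integral of the tent curve from 0 to t (minutes), vectorised.

    Broadcasts time (leading axis) against per-voxel parameters.
    """
    t = np.asarray(t_min, dtype=float)[:, None]
    a, b, p, s = (np.atleast_1d(np.asarray(v, dtype=float)) for v in (amplitude, baseline, peak, slope))
    # rising limb on [0, min(t, p)]
    tau1 = np.minimum(t, p)
    out = b * tau1 + (a - b) * tau1**2 / (2 * p)
    # post-peak limb on [p, t]; floored at baseline when decreasing
    tau = np.maximum(t - p, 0.0)
    with np.errstate(divide="ignore"):
        tau_q = np.where(s < 0, (b - a) / np.where(s < 0, s, 1.0), np.inf)
    tau_c = np.minimum(tau, tau_q)
    out = out + a * tau_c + s * tau_c**2 / 2
    out = out + b * np.maximum(tau - tau_q, 0.0)
    return out


def tent_frame_values(
    schedule: FrameSchedule,
    amplitude: np.ndarray,
    baseline: np.ndarray,
    peak_time_min: np.ndarray,
    washout_slope: np.ndarray,
) -> np.ndarray:
    """Noise-free frame activities: exact per-frame means of the tent curve.

    Returns an array of shape ``(n_frames, n_voxels)`` (or ``(n_frames, 1)``
    for scalar parameters).
    """
    starts = schedule.starts_s / 60.0
    ends = schedule.ends_s / 60.0
    upper = _tent_cumulative_integral(ends, amplitude, baseline, peak_time_min, washout_slope)
    lower = _tent_cumulative_integral(starts, amplitude, baseline, peak_time_min, washout_slope)
    durations = (ends - starts)[:, None]
    return (upper - lower) / durations


def simulate_tac(
    params: KineticParams, schedule: FrameSchedule, rng_seed: int
) -> np.ndarray:
    """One frame-activity sequence: tent-curve frame means plus Gaussian noise.

    Noise is zero-mean, i.i.d. per frame; results are clipped at zero.
    """
    clean = tent_frame_values(
        schedule,
        params.amplitude,
        params.baseline,
        params.peak_time_min,
        params.washout_slope,
    )[:, 0]
    if params.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        clean = clean + rng.normal(0.0, params.noise_sd, size=clean.shape)
    return np.clip(clean, 0.0, None)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    centre: np.ndarray,
    semi_axes: np.ndarray,
) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, semi_axes))
    return d2 <= 1.0


def _crescent_background(shape: tuple[int, int, int]) -> np.ndarray:
    """Fixed crescent-shaped VOI in the low-x (contralateral) half of the grid."""
    nx, ny, nz = shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = 0.42 * nx, 0.5 * ny
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    ring = (r >= 0.18 * min(nx, ny)) & (r <= 0.34 * min(nx, ny)) & (x < 0.38 * nx)
    mask = np.zeros(shape, dtype=bool)
    z0, z1 = int(0.3 * nz), int(0.7 * nz) + 1
    mask[:, :, z0:z1] = ring[:, :, None]
    return mask


def _draw_voxel_kinetics(
    rng: np.random.Generator, n_vox: int, mix_fraction: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel tent parameters for a tumour.

    ``mix_fraction`` is the probability that a voxel follows the early-peak/
    washout archetype; the remainder follow the late-increasing archetype.
    """
    early = rng.random(n_vox) < mix_fraction
    amplitude = np.where(
        early, rng.uniform(2.4, 3.2, n_vox), rng.uniform(1.5, 1.9, n_vox)
    )
    baseline = rng.uniform(0.8, 1.2, n_vox)
    peak = np.where(
        early, rng.uniform(4.0, 10.0, n_vox), rng.uniform(2.0, 5.0, n_vox)
    )
    slope = np.where(
        early, rng.uniform(-0.035, -0.015, n_vox), rng.uniform(0.008, 0.025, n_vox)
    )
    # baseline must stay below amplitude
    baseline = np.minimum(baseline, amplitude - 0.2)
    return amplitude, baseline, peak, slope, early


def iter_phantom(spec: CohortSpec, schedule: FrameSchedule | None = None):
    """Yield :class:`PhantomStudy` objects one at a time (memory-friendly)."""
    schedule = schedule or default_frame_schedule()
    ss = np.random.SeedSequence(spec.seed)
    s_labels, s_geom, s_kin, s_noise = ss.spawn(4)

    n_wt = _round_half_up(spec.n_patients * spec.wildtype_fraction)
    labels = np.ones(spec.n_patients, dtype=int)
    labels[:n_wt] = 0
    np.random.default_rng(s_labels).shuffle(labels)

    rng_geom = np.random.default_rng(s_geom)
    rng_kin = np.random.default_rng(s_kin)
    rng_noise = np.random.default_rng(s_noise)

    shape = spec.grid_shape
    background_grid = _crescent_background(shape)

    for i in range(spec.n_patients):
        label = int(labels[i])
        # tumour geometry: jittered ellipsoid in the high-x hemisphere
        semi = rng_geom.uniform([3.6, 3.2, 2.8], [5.0, 4.6, 3.8])
        centre = np.array(
            [
                rng_geom.uniform(0.62 * shape[0], 0.72 * shape[0]),
                rng_geom.uniform(0.40 * shape[1], 0.60 * shape[1]),
                rng_geom.uniform(0.42 * shape[2], 0.58 * shape[2]),
            ]
        )
        if np.any(centre - semi < 0.5) or np.any(centre + semi > np.array(shape) - 1.5):
            raise ValueError("tumour ellipsoid does not fit inside the grid")
        tumour_grid = _ellipsoid_mask(shape, centre, semi)
        n_vox = int(tumour_grid.sum())

        # label-dependent kinetic mixing: mutant ~ 0.5 (heterogeneous),
        # wildtype shifted toward a pure late-increasing tumour by `effect`
        f = 0.5 - 0.45 * spec.effect * (label == 0) + rng_kin.normal(0.0, 0.04)
        f = float(np.clip(f, 0.02, 0.98))
        amplitude, baseline, peak, slope, early = _draw_voxel_kinetics(rng_kin, n_vox, f)

        frames = tent_frame_values(schedule, amplitude, baseline, peak, slope)

        volume = np.full(
            (len(schedule),) + shape, BACKGROUND_ACTIVITY, dtype=np.float32
        )
        volume[:, tumour_grid] = frames

        # rescale the tumour so its noise-free late TBR stays above threshold
        study0 = DynamicStudy(volume, schedule, spec.voxel_spacing_mm)
        late = summation_image(study0, (20.0, 40.0))
        bg_val = BACKGROUND_ACTIVITY
        min_tbr = float(late[tumour_grid].min()) / bg_val
        scale = max(1.0, TBR_FLOOR * TBR_MARGIN / min_tbr)
        if scale > 1.0:
            volume[:, tumour_grid] *= scale

        if spec.noise_sd > 0:
            volume = volume + rng_noise.normal(
                0.0, spec.noise_sd, size=volume.shape
            ).astype(np.float32)
            np.clip(volume, 0.0, None, out=volume)

        yield PhantomStudy(
            study=DynamicStudy(volume, schedule, spec.voxel_spacing_mm),
            tumour=VoxelMask(tumour_grid, role="tumour"),
            background=VoxelMask(background_grid.copy(), role="background"),
            label=label,
            truth={
                "mix_fraction": f,
                "n_early_voxels": int(early.sum()),
                "n_tumour_voxels": n_vox,
                "tbr_scale": scale,
            },
        )


def generate_phantom(spec: CohortSpec, schedule: FrameSchedule | None = None) -> list[PhantomStudy]:
    """Materialise a full cohort (see :func:`iter_phantom`)."""
    return list(iter_phantom(spec, schedule))
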
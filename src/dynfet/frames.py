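"""Dynamic-PET frame schedules.

A dynamic acquisition is a contiguous sequence of time frames.  The default
schedule is the fixed 16-frame, 40-minute protocol of an ECAT HR+ amino-acid
PET study: 7 x 10 s, 3 x 30 s, 1 x 2 min, 3 x 5 min and 2 x 10 min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FrameSchedule", "default_frame_schedule"]


@dataclass(frozen=True)
class FrameSchedule:
    """An ordered, contiguous set of acquisition frames in seconds.

    Parameters
    ----------
    frames
        Tuple of ``(start_s, end_s)`` pairs.  Frames must start at 0, be
        non-overlapping and contiguous (each frame starts where the previous
        one ends).
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("schedule must contain at least one frame")
        if self.frames[0][0] != 0:
            raise ValueError("first frame must start at t=0")
        prev_end = 0.0
        for start, end in self.frames:
            if start != prev_end:
                raise ValueError(
                    f"frames must be contiguous: frame starts at {start}, "
                    f"previous ended at {prev_end}"
                )
            if end <= start:
                raise ValueError(f"frame ({start}, {end}) has non-positive duration")
            prev_end = end

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames], dtype=float)

    @property
    def ends_s(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames], dtype=float)

    @property
    def durations_s(self) -> np.ndarray:
        return self.ends_s - self.starts_s

    @property
    def mid_times_s(self) -> np.ndarray:
        return 0.5 * (self.starts_s + self.ends_s)

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.frames[-1][1])


def default_frame_schedule() -> FrameSchedule:
    """The 16-frame, 2380-s dynamic FET-PET schedule.

    Frame durations: 7 x 10 s, 3 x 30 s, 1 x 120 s, 3 x 300 s, 2 x 600 s.
    """
    durations = [10.0] * 7 + [30.0] * 3 + [120.0] + [300.0] * 3 + [600.0] * 2
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    frames = tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))
    return FrameSchedule(frames)
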
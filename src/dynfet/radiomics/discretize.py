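"""Fixed-bin-width intensity discretisation and the IQR/4 bin-width rule."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["DiscretizationRule", "iqr4_bin_width", "discretize"]


@dataclass(frozen=True)
class DiscretizationRule:
    """Fixed bin width anchored at the masked minimum.

    The bin index of a value ``v`` is ``floor((v - min) / bin_width) + 1``,
    so the minimum always maps to bin 1.
    """

    bin_width: float
    origin: str = "global-min"

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")


def iqr4_bin_width(masked_value_sets: Iterable[Sequence[float]]) -> float:
    """Cohort bin width: mean per-patient interquartile range divided by 4.

    Quartiles use linear interpolation between order statistics.  A cohort
    of constant-valued patients yields 0, which downstream construction of a
    :class:`DiscretizationRule` rejects.
    """
    iqrs = []
    for values in masked_value_sets:
        v = np.asarray(values, dtype=float)
        if v.size < 4:
            raise ValueError("each intensity collection needs >= 4 values")
        q1, q3 = np.percentile(v, [25, 75])
        iqrs.append(q3 - q1)
    if not iqrs:
        raise ValueError("no intensity collections supplied")
    return float(np.mean(iqrs) / 4.0)


def discretize(values: np.ndarray, rule: DiscretizationRule) -> tuple[np.ndarray, int]:
    """Map intensities to integer grey levels; returns ``(levels, Ng)``.

    ``Ng`` is the highest assigned level (levels in between may be empty
    under fixed-bin-width discretisation).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot discretise an empty value set")
    levels = np.floor((v - v.min()) / rule.bin_width).astype(np.int64) + 1
    return levels, int(levels.max())
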
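"""First-order (intensity histogram) features.

All 18 features operate on the raw masked intensities; only Entropy and
Uniformity act on the fixed-bin-width discretised histogram.  Moments use
the population convention (divisor N); Kurtosis is the non-excess variant
(value 3 for a Gaussian).
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizationRule, discretize

__all__ = ["first_order_features", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    values: np.ndarray, rule: DiscretizationRule, voxel_volume_mm3: float = 1.0
) -> dict[str, float]:
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("first-order features need a non-empty mask")

    levels, _ = discretize(v, rule)
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / v.size

    mean = v.mean()
    m2 = np.mean((v - mean) ** 2)
    m3 = np.mean((v - mean) ** 3)
    m4 = np.mean((v - mean) ** 4)
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    robust_mad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0

    energy = float(np.sum(v**2))
    out = {
        "Energy": energy,
        "TotalEnergy": voxel_volume_mm3 * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(v - mean))),
        "RobustMeanAbsoluteDeviation": robust_mad,
        "RootMeanSquared": float(np.sqrt(np.mean(v**2))),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
    return out
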
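"""Intensity (first-order) features: 18 statistics of the in-mask HU values.

Entropy and Uniformity are computed on the fixed-bin-width discretized
histogram (same binning as the texture families); everything else on the
raw intensities.  Moments are population moments; Kurtosis is not
excess-corrected.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["FIRST_ORDER_NAMES", "first_order_features"]

FIRST_ORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
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
    values: np.ndarray,
    mask: np.ndarray,
    voxel_volume: float = 1.0,
    bin_width: float = 25.0,
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(values, dtype=np.float64)[mask]
    if x.size < 2:
        raise ValueError("need at least two in-mask voxels")
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    hist = np.bincount(np.floor((x - x.min()) / bin_width).astype(np.int64))
    p = hist[hist > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if var > 0:
        skew = float(((x - mean) ** 3).mean() / var**1.5)
        kurt = float(((x - mean) ** 4).mean() / var**2)
    else:
        warnings.warn("zero-variance region: skewness/kurtosis degenerate")
        skew, kurt = 0.0, 0.0

    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxel_volume * (x**2).sum()),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": uniformity,
    }
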
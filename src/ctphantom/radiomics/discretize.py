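"""Fixed-bin-width gray-level discretization of a masked ROI."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedRoi", "discretize"]


@dataclass
class DiscretizedRoi:
    """Integer gray levels (1..n_levels in mask, 0 outside) on the ROI grid.

    Bin edges are anchored at the in-mask minimum: level(v) =
    floor((HU(v) - min) / bin_width) + 1, so texture levels are invariant
    to a global intensity shift.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float
    spacing: tuple[float, float, float]
    min_value: float
    degenerate: bool = False

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(
    values: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 25.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DiscretizedRoi:
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(values, dtype=np.float64)
    vmin = float(vals[mask].min())
    levels = np.zeros(mask.shape, dtype=np.int32)
    levels[mask] = np.floor((vals[mask] - vmin) / bin_width).astype(np.int32) + 1
    n_levels = int(levels.max())
    degenerate = n_levels == 1
    if degenerate:
        warnings.warn("constant region: single gray level (degenerate texture)")
    return DiscretizedRoi(
        levels=levels,
        mask=mask,
        n_levels=n_levels,
        bin_width=float(bin_width),
        spacing=tuple(float(s) for s in spacing),
        min_value=vmin,
        degenerate=degenerate,
    )
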
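"""107-feature radiomics extraction: 18 first-order, 14 shape, and 75
texture features (24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) per
lesion measurement.

Texture features are computed on fixed-bin-width discretized intensities
(default 25 HU, anchored at the in-mask minimum) over distance-1 3D
neighborhoods; no resampling or filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ..volume import ImageVolume, LabelMask
from .discretize import DiscretizedRoi, discretize
from .features import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features

__all__ = [
    "ExtractionConfig",
    "FeatureVector",
    "FeatureExtractionError",
    "extract_all",
    "feature_names",
    "GROUP_SIZES",
    "discretize",
    "DiscretizedRoi",
    "first_order_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

GROUP_SIZES = {
    "firstorder": 18,
    "shape": 14,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}


class FeatureExtractionError(RuntimeError):
    """A feature family failed; names the family and the lesion."""


@dataclass(frozen=True)
class ExtractionConfig:
    bin_width: float = 25.0  # HU


@dataclass
class FeatureVector:
    """The named 107-element radiomics vector for one lesion measurement."""

    values: dict[str, float]
    provenance: dict = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def group_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for name in self.values:
            group = name.split("_", 1)[0]
            out[group] = out.get(group, 0) + 1
        return out

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def feature_names() -> tuple[str, ...]:
    """The stable 107-name feature order."""
    names = [f"firstorder_{n}" for n in FIRST_ORDER_NAMES]
    names += [f"shape_{n}" for n in SHAPE_NAMES]
    names += [f"glcm_{n}" for n in GLCM_NAMES]
    names += [f"glrlm_{n}" for n in GLRLM_NAMES]
    names += [f"glszm_{n}" for n in GLSZM_NAMES]
    names += [f"gldm_{n}" for n in GLDM_NAMES]
    names += [f"ngtdm_{n}" for n in NGTDM_NAMES]
    return tuple(names)


def _crop_to_mask(values: np.ndarray, mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return values[sl], mask[sl]


def extract_all(
    volume: ImageVolume | np.ndarray,
    mask: LabelMask | np.ndarray,
    label: int | str | None = None,
    config: ExtractionConfig = ExtractionConfig(),
    provenance: dict | None = None,
) -> FeatureVector:
    """Extract the full 107-feature vector for one lesion.

    ``mask`` may be a boolean array or a :class:`LabelMask` together with
    the lesion's ``label`` (integer value or legend name).
    """
    if isinstance(volume, ImageVolume):
        data = np.asarray(volume.data, dtype=np.float64)
        spacing = volume.spacing
    else:
        data = np.asarray(volume, dtype=np.float64)
        spacing = (1.0, 1.0, 1.0)
    if isinstance(mask, LabelMask):
        spacing = mask.spacing
        if label is None:
            binary = mask.data > 0
        elif isinstance(label, str):
            binary = mask.region(label)
        else:
            binary = mask.data == int(label)
    else:
        binary = np.asarray(mask, dtype=bool)
    if binary.shape != data.shape:
        raise ValueError("volume and mask grids do not match")
    if not binary.any():
        raise ValueError(f"mask is empty for label {label!r}")
    data, binary = _crop_to_mask(data, binary)

    lesion = provenance.get("lesion_id", label) if provenance else label
    voxel_volume = float(np.prod(spacing))
    out: dict[str, float] = {}
    try:
        fo = first_order_features(data, binary, voxel_volume, config.bin_width)
        out.update({f"firstorder_{k}": v for k, v in fo.items()})
    except Exception as exc:
        raise FeatureExtractionError(f"first-order failed for {lesion}: {exc}") from exc
    try:
        sh = shape_features(binary, spacing)
        out.update({f"shape_{k}": v for k, v in sh.items()})
    except Exception as exc:
        raise FeatureExtractionError(f"shape failed for {lesion}: {exc}") from exc

    d = discretize(data, binary, config.bin_width, spacing)
    for family, fn in (
        ("glcm", glcm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("gldm", gldm_features),
        ("ngtdm", ngtdm_features),
    ):
        try:
            out.update({f"{family}_{k}": v for k, v in fn(d).items()})
        except Exception as exc:
            raise FeatureExtractionError(
                f"{family} failed for {lesion}: {exc}"
            ) from exc

    assert len(out) == 107, f"expected 107 features, got {len(out)}"
    return FeatureVector(values=out, provenance=dict(provenance or {}))
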
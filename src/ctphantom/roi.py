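"""ROI placement and first-level image-quality metrics.

Reproduces the manual ROI scheme deterministically: on three non-overlapping
central slices, one 8 mm ROI inside every lesion, one in the lung-parenchyma
background adjacent to each lesion (same angular sector), and one in the
solid-water ring - 13 labeled ROIs per slice across the two study phantoms.
"Homogeneous region" is operationalized as the interior point maximizing
distance to the region boundary; for part-solid lesions the homogeneous
region is the shell (the dominant, non-core component).

From ROI measurements: pooled per-material HU statistics, image noise
(parenchyma ROI SDs), contrast-to-noise ratio CNR_k = (mu_k - mu_BG,k) /
sigma_k, coefficient of variation, and percent differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .materials import GeometryError, PhantomSpec
from .phantom import layout_phantom
from .volume import ImageVolume, LabelMask

__all__ = [
    "RoiSpec",
    "RoiMeasurement",
    "MaterialStats",
    "place_rois",
    "central_slices",
    "measure_roi",
    "pool_material_stats",
    "compute_cnr",
    "coefficient_of_variation",
    "percent_change",
]

ROI_DIAMETER_MM = 8.0
MIN_ROI_DIAMETER_MM = 4.0


@dataclass(frozen=True)
class RoiSpec:
    """A circular single-slice ROI, centered on a voxel center."""

    center_xy: tuple[float, float]  # mm
    slice_index: int
    diameter: float  # mm
    material: str  # lung_parenchyma / water / solid / part_solid / ground_glass
    region_name: str  # label-legend name the ROI sits in
    lesion_id: str | None = None  # lesion this ROI belongs to / is adjacent to
    phantom_id: int | None = None


@dataclass(frozen=True)
class RoiMeasurement:
    roi: RoiSpec
    mean: float
    sd: float
    n_voxels: int
    scanner: str | None = None
    dose: float | None = None
    repetition: int | None = None


@dataclass(frozen=True)
class MaterialStats:
    material: str
    mean: float  # mean of ROI means, pooled over sizes/slices/repetitions
    se: float  # SD of ROI means / sqrt(n)
    n_rois: int
    single_roi: bool = False


def central_slices(
    nz: int, spacing_z: float, offsets_mm: tuple[float, ...] = (-4.0, 0.0, 4.0)
) -> tuple[int, ...]:
    """Three non-overlapping slices around the phantom mid-plane."""
    mid = nz // 2
    idx = []
    for off in offsets_mm:
        k = mid + int(round(off / spacing_z))
        idx.append(min(max(k, 0), nz - 1))
    if len(set(idx)) != len(idx):
        raise ValueError("slice offsets collapse onto overlapping slices")
    return tuple(idx)


def _deepest_point(
    region2d: np.ndarray, spacing: tuple[float, float]
) -> tuple[int, int, float]:
    """Interior voxel maximizing distance to the region boundary (first index
    in C order on ties) and that distance in mm."""
    if not region2d.any():
        raise GeometryError("empty region: cannot place an ROI")
    edt = distance_transform_edt(region2d, sampling=spacing)
    flat = int(np.argmax(edt))
    i, j = np.unravel_index(flat, edt.shape)
    return int(i), int(j), float(edt[i, j])


def _wedge_mask(
    x: np.ndarray, y: np.ndarray, wedge: tuple[float, float]
) -> np.ndarray:
    lo, hi = wedge
    ang = np.arctan2(y[None, :], x[:, None])
    return np.mod(ang - lo, 2 * math.pi) <= (hi - lo) + 1e-12


def _make_roi(
    mask: LabelMask,
    region2d: np.ndarray,
    z: int,
    diameter: float,
    material: str,
    region_name: str,
    lesion_id: str | None,
) -> RoiSpec:
    i, j, depth = _deepest_point(region2d, mask.spacing[:2])
    radius = diameter / 2.0
    if depth < radius:
        if depth < MIN_ROI_DIAMETER_MM / 2.0:
            raise GeometryError(
                f"region {region_name!r} too small for a "
                f"{MIN_ROI_DIAMETER_MM} mm ROI on slice {z}"
            )
        warnings.warn(
            f"shrinking ROI in {region_name!r} on slice {z} to {2 * depth:.1f} mm"
        )
        radius = depth
    cx = mask.origin[0] + mask.spacing[0] * i
    cy = mask.origin[1] + mask.spacing[1] * j
    return RoiSpec(
        center_xy=(cx, cy),
        slice_index=z,
        diameter=2 * radius,
        material=material,
        region_name=region_name,
        lesion_id=lesion_id,
        phantom_id=getattr(getattr(mask.layout, "spec", None), "phantom_id", None),
    )


def place_rois(
    mask: LabelMask,
    spec: PhantomSpec | None = None,
    slices: tuple[int, ...] | None = None,
    diameter: float = ROI_DIAMETER_MM,
    include_water: bool = True,
) -> list[RoiSpec]:
    """Deterministic ROI placement on a phantom's label mask.

    Per slice: one ROI per lesion (in its homogeneous component), one
    parenchyma ROI adjacent to each lesion (deepest parenchyma point within
    the lesion's sector), and optionally one in the water ring.
    """
    layout = mask.layout
    if layout is None and spec is not None:
        layout = layout_phantom(spec)
    if slices is None:
        slices = central_slices(mask.shape[2], mask.spacing[2])
    x = mask.origin[0] + mask.spacing[0] * np.arange(mask.shape[0])
    y = mask.origin[1] + mask.spacing[1] * np.arange(mask.shape[1])
    lesion_specs = {l.lesion_id: l for l in (spec.lesions if spec else ())}
    if not lesion_specs and layout is not None:
        lesion_specs = {l.lesion_id: l for l in layout.spec.lesions}

    rois: list[RoiSpec] = []
    for z in slices:
        lab2d = mask.data[:, :, z]
        comp2d = mask.components[:, :, z] if mask.components is not None else None
        if layout is not None:
            lesion_layouts = layout.lesions
        else:
            lesion_layouts = [
                type("L", (), {"lesion_id": name, "label": lab, "wedge": None})()
                for lab, name in sorted(mask.labels_matching("").items())
                if name not in ("lung_parenchyma", "water")
            ]
        for ll in lesion_layouts:
            les = lesion_specs.get(ll.lesion_id)
            region = lab2d == ll.label
            if comp2d is not None and les is not None and les.lesion_type == "part_solid":
                region = region & (comp2d == 0)  # homogeneous shell
            rois.append(
                _make_roi(
                    mask, region, z, diameter,
                    material=les.lesion_type if les is not None else ll.lesion_id,
                    region_name=ll.lesion_id, lesion_id=ll.lesion_id,
                )
            )
            paren = lab2d == mask.label_for("lung_parenchyma")
            if getattr(ll, "wedge", None) is not None:
                paren = paren & _wedge_mask(x, y, ll.wedge)
            rois.append(
                _make_roi(
                    mask, paren, z, diameter,
                    material="lung_parenchyma",
                    region_name="lung_parenchyma", lesion_id=ll.lesion_id,
                )
            )
        if include_water and "water" in mask.legend.values():
            water = lab2d == mask.label_for("water")
            if water.any():
                rois.append(
                    _make_roi(mask, water, z, diameter, "water", "water", None)
                )
    return rois


def measure_roi(volume: ImageVolume, roi: RoiSpec) -> RoiMeasurement:
    """Mean and sample SD (n-1) over voxels whose centers fall inside the ROI
    disc on its slice."""
    z = roi.slice_index
    if not 0 <= z < volume.shape[2]:
        raise ValueError(f"ROI slice {z} outside the volume")
    x = volume.voxel_centers(0)
    y = volume.voxel_centers(1)
    r = roi.diameter / 2.0
    dx2 = (x - roi.center_xy[0]) ** 2
    dy2 = (y - roi.center_xy[1]) ** 2
    disc = dx2[:, None] + dy2[None, :] <= r**2
    values = volume.data[:, :, z][disc].astype(np.float64)
    if values.size == 0:
        raise ValueError("ROI covers no voxel centers")
    return RoiMeasurement(
        roi=roi,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        n_voxels=int(values.size),
        scanner=volume.scanner,
        dose=volume.dose,
        repetition=volume.repetition,
    )


def pool_material_stats(measurements, material: str) -> MaterialStats:
    """Pool ROI means for one material across sizes, slices and repetitions."""
    means = [m.mean for m in measurements if m.roi.material == material]
    if not means:
        raise ValueError(f"no measurements for material {material!r}")
    arr = np.asarray(means, dtype=float)
    n = arr.size
    se = float(arr.std(ddof=0) / math.sqrt(n)) if n > 1 else 0.0
    return MaterialStats(
        material=material, mean=float(arr.mean()), se=se, n_rois=n, single_roi=n == 1
    )


def compute_cnr(lesion: RoiMeasurement, background: RoiMeasurement) -> float:
    """Signed contrast-to-noise ratio (mu_lesion - mu_background) / sd_lesion.

    The denominator is the lesion ROI's own SD.  Returns NaN (with a warning)
    when that SD is zero.  Reports take the magnitude.
    """
    if lesion.sd == 0:
        warnings.warn("lesion ROI SD is zero: CNR undefined")
        return float("nan")
    return (lesion.mean - background.mean) / lesion.sd


def coefficient_of_variation(values) -> float:
    """|SD / mean| of a set of values (e.g. per-dose material means)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    mean = arr.mean()
    sd = arr.std(ddof=1)
    if abs(mean) < 1e-6 or abs(mean) < 1e-3 * sd:
        warnings.warn("mean near zero: coefficient of variation is unstable")
    with np.errstate(divide="ignore"):
        return float(abs(sd / mean)) if mean != 0 else float("inf")


def percent_change(reference: float, comparison: float, kind: str = "reduction") -> float:
    """Percent reduction (or increase) of ``comparison`` relative to
    ``reference``: 100 * (reference - comparison) / reference for reductions."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    if kind == "reduction":
        return 100.0 * (reference - comparison) / reference
    if kind == "increase":
        return 100.0 * (comparison - reference) / reference
    raise ValueError("kind must be 'reduction' or 'increase'")
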
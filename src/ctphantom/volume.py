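"""In-memory containers for image volumes and label masks, with NIfTI-1 I/O.

Volumes are stored as ``(nx, ny, nz)`` arrays of Hounsfield units with
positive voxel spacing in millimetres.  Files are written RAS+ with the
spacing encoded in the affine, via :mod:`nibabel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "LabelMask", "estimate_integer_shift"]


def _check_grid(data: np.ndarray, spacing: tuple[float, float, float]) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got shape {data.shape}")
    if any(n < 3 for n in data.shape):
        raise ValueError(f"grid dimensions must be >= 3 in each axis, got {data.shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be three positive values, got {spacing}")


@dataclass
class ImageVolume:
    """A 3D HU grid with voxel spacing, origin and acquisition metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scanner: str | None = None
    dose: float | None = None
    repetition: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_grid(self.data, self.spacing)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str | Path) -> Path:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        img.header.set_xyzt_units("mm")
        path = Path(path)
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, **meta) -> "ImageVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
        aff = img.affine
        spacing = tuple(float(x) for x in np.abs(np.diag(aff)[:3]))
        origin = tuple(float(x) for x in aff[:3, 3])
        return cls(data=data, spacing=spacing, origin=origin, **meta)


@dataclass
class LabelMask:
    """Integer label grid aligned to an :class:`ImageVolume`.

    ``legend`` maps label values to region names (lesion ids, materials).
    ``components`` optionally marks sub-lesion structure (1 = dense core of a
    part-solid lesion), used for homogeneous-region ROI placement.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: Mapping[int, str] = field(default_factory=dict)
    components: np.ndarray | None = None
    layout: object | None = None  # PhantomLayout for generated masks

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        _check_grid(self.data, self.spacing)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label mask must be an integer grid")
        if self.components is not None and self.components.shape != self.data.shape:
            raise ValueError("components grid must match the label grid shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def label_for(self, name: str) -> int:
        for lab, n in self.legend.items():
            if n == name:
                return int(lab)
        raise KeyError(f"no label named {name!r} in legend")

    def labels_matching(self, prefix: str) -> dict[int, str]:
        return {int(k): v for k, v in self.legend.items() if v.startswith(prefix)}

    def region(self, name: str) -> np.ndarray:
        return self.data == self.label_for(name)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.int16), self.affine())
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
        if self.components is not None and self.components.any():
            comp = nib.Nifti1Image(
                np.asarray(self.components, dtype=np.int16), self.affine()
            )
            nib.save(comp, str(_components_path(path)))
        return path

    @classmethod
    def from_nifti(
        cls, path: str | Path, legend: Mapping[int, str] | None = None
    ) -> "LabelMask":
        path = Path(path)
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.int16)
        aff = img.affine
        spacing = tuple(float(x) for x in np.abs(np.diag(aff)[:3]))
        origin = tuple(float(x) for x in aff[:3, 3])
        components = None
        cpath = _components_path(path)
        if cpath.exists():
            components = np.asanyarray(nib.load(str(cpath)).dataobj).astype(np.int16)
        if legend is None:
            legend = {int(v): f"label_{int(v)}" for v in np.unique(data) if v != 0}
        return cls(
            data=data,
            spacing=spacing,
            origin=origin,
            legend=dict(legend),
            components=components,
        )


def _components_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + "_components" + suf)
    return path.with_name(name + "_components")


def estimate_integer_shift(
    reference: np.ndarray, moving: np.ndarray, max_shift: int = 20
) -> tuple[int, int, int]:
    """Integer-voxel translation ``s`` with ``np.roll(moving, s)`` aligned
    onto ``reference``.

    Cross-correlation over the ``±max_shift`` search cube via FFT.  Intended
    for imported real scans acquired on a shared table position; generated
    volumes share one frame and need no alignment.
    """
    ref = np.asarray(reference, dtype=np.float64)
    mov = np.asarray(moving, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError("reference and moving volumes must share a grid shape")
    ref = ref - ref.mean()
    mov = mov - mov.mean()
    axes = tuple(range(ref.ndim))
    corr = np.fft.irfftn(
        np.fft.rfftn(ref) * np.conj(np.fft.rfftn(mov)), s=ref.shape, axes=axes
    )
    shifts = []
    for ax, n in enumerate(ref.shape):
        m = min(max_shift, n // 2 - 1)
        shifts.append(np.r_[0 : m + 1, n - m : n])
    sub = corr[np.ix_(*shifts)]
    idx = np.unravel_index(np.argmax(sub), sub.shape)
    out = []
    for ax, i in enumerate(idx):
        raw = shifts[ax][i]
        n = ref.shape[ax]
        out.append(int(raw if raw <= n // 2 else raw - n))
    return tuple(out)
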
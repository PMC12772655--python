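"""Noise-free digital phantom rasterization.

Each phantom is a cylinder of lung-parenchyma-equivalent material holding
ellipsoidal lesions in angular sectors, surrounded by a solid-water ring
and air.  Lesion interiors are rendered so that the mean HU over the lesion
mask equals the lesion's target mean intensity: solid and ground-glass
lesions are uniform at the target; part-solid lesions are a dense core at
the solid material HU inside a shell at the part-solid material HU, with
the core voxel count solved for the target mean.

A smooth, band-passed texture (zero mean over each lesion mask) is added
inside the lesions so truth images are not pathologically flat for texture
analysis; parenchyma and water stay flat so ROI-scale means remain unbiased
estimates of the configured material HU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .materials import (
    AIR_HU,
    ConfigError,
    GeometryError,
    MaterialTable,
    PhantomSpec,
)
from .volume import ImageVolume, LabelMask

__all__ = [
    "TextureParams",
    "LesionLayout",
    "PhantomLayout",
    "layout_phantom",
    "rasterize_phantom",
    "LESION_LABEL_BASE",
    "PARENCHYMA_LABEL",
    "WATER_LABEL",
]

PARENCHYMA_LABEL = 1
WATER_LABEL = 2
LESION_LABEL_BASE = 10

#: Clearance kept between a lesion surface and its sector / ring boundaries.
LESION_MARGIN_MM = 2.0

#: Minimum air gap kept between lesion top/bottom and the phantom faces.
LESION_Z_CLEARANCE_MM = 8.0


@dataclass(frozen=True)
class TextureParams:
    """Smooth background texture: ``amplitude`` HU voxel-scale SD, Gaussian
    correlation ``corr_mm``, with structure smoother than ``highpass_mm``
    removed so 8 mm ROI means stay unbiased."""

    amplitude: float = 20.0
    corr_mm: float = 2.0
    highpass_mm: float = 6.0


@dataclass(frozen=True)
class LesionLayout:
    lesion_id: str
    label: int
    center: tuple[float, float, float]  # mm, phantom axis at (0, 0)
    semi_axes: tuple[float, float, float]  # (a, a, c) mm
    wedge: tuple[float, float]  # sector angular extent, radians


@dataclass(frozen=True)
class PhantomLayout:
    spec: PhantomSpec
    lesions: tuple[LesionLayout, ...]


def _sector_bisectors(n_quarter: int, n_half: int) -> dict[str, list[float]]:
    quarters = [math.radians(a) for a in (45.0, 135.0, 225.0, 315.0)][:n_quarter]
    halves = [math.radians(a) for a in (90.0, 270.0)][:n_half]
    return {"quarter": quarters, "half": halves}


def layout_phantom(spec: PhantomSpec) -> PhantomLayout:
    """Deterministic lesion placement: each lesion centered on the inscribed
    circle of its sector, vertically centered in the phantom."""
    n_q = sum(1 for l in spec.lesions if l.sector == "quarter")
    n_h = sum(1 for l in spec.lesions if l.sector == "half")
    if n_q > 4 or n_h > 2 or (n_q and n_h):
        raise GeometryError("sector plan supports up to 4 quarter or 2 half sectors")
    bisectors = _sector_bisectors(n_q, n_h)
    counters = {"quarter": 0, "half": 0}
    R = spec.diameter / 2.0
    out = []
    for idx, les in enumerate(spec.lesions):
        half_angle = math.pi / 4 if les.sector == "quarter" else math.pi / 2
        s = math.sin(half_angle)
        d = R / (1.0 + s)  # inscribed-circle center along the bisector
        r_in = R - d
        a = les.max_3d_diameter / 2.0
        if a + LESION_MARGIN_MM > r_in:
            raise GeometryError(
                f"lesion {les.lesion_id} (radius {a} mm) does not fit the "
                f"{les.sector} sector of a {spec.diameter} mm phantom"
            )
        c_max = (spec.height - LESION_Z_CLEARANCE_MM) / 2.0
        if c_max <= 0:
            raise GeometryError(f"phantom {spec.phantom_id} is too thin for lesions")
        c = min(a, c_max)
        theta = bisectors[les.sector][counters[les.sector]]
        counters[les.sector] += 1
        center = (d * math.cos(theta), d * math.sin(theta), spec.height / 2.0)
        out.append(
            LesionLayout(
                lesion_id=les.lesion_id,
                label=LESION_LABEL_BASE + idx,
                center=center,
                semi_axes=(a, a, c),
                wedge=(theta - half_angle, theta + half_angle),
            )
        )
    return PhantomLayout(spec=spec, lesions=tuple(out))


def _band_passed_texture(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    params: TextureParams,
    rng: np.random.Generator,
) -> np.ndarray:
    white = rng.standard_normal(shape).astype(np.float32)
    sig_lo = tuple(params.corr_mm / s for s in spacing)
    sig_hi = tuple(params.highpass_mm / s for s in spacing)
    t = gaussian_filter(white, sig_lo, mode="nearest")
    t -= gaussian_filter(t, sig_hi, mode="nearest")
    sd = float(t.std())
    if sd > 0:
        t *= params.amplitude / sd
    return t


def rasterize_phantom(
    spec: PhantomSpec,
    materials: MaterialTable,
    scanner: str,
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0),
    fov_mm: float = 256.0,
    texture: TextureParams | None = TextureParams(),
    seed: int | None = 0,
) -> tuple[ImageVolume, LabelMask]:
    """Rasterize a noise-free phantom volume and its ground-truth label mask.

    Returns a volume whose in-cylinder background is lung parenchyma, each
    lesion an ellipsoid whose mask mean equals its spec mean intensity
    (exact up to one voxel's worth of core quantization), a solid-water
    ring out to ``spec.ring_outer_diameter`` and air outside.
    """
    hu = materials.for_scanner(scanner)
    layout = layout_phantom(spec)

    nxy = int(round(fov_mm / spacing[0]))
    nz = int(round(spec.height / spacing[2]))
    if nxy * spacing[0] < spec.ring_outer_diameter:
        raise ConfigError("field of view smaller than the phantom assembly")
    shape = (nxy, nxy, nz)
    origin = (
        -spacing[0] * (nxy - 1) / 2.0,
        -spacing[1] * (nxy - 1) / 2.0,
        spacing[2] / 2.0,
    )
    x = origin[0] + spacing[0] * np.arange(nxy, dtype=np.float32)
    y = origin[1] + spacing[1] * np.arange(nxy, dtype=np.float32)
    z = origin[2] + spacing[2] * np.arange(nz, dtype=np.float32)
    r2 = (x[:, None] ** 2 + y[None, :] ** 2).astype(np.float32)

    vol = np.full(shape, AIR_HU, dtype=np.float32)
    lab = np.zeros(shape, dtype=np.int16)
    comp = np.zeros(shape, dtype=np.int16)

    in_ring = r2 <= (spec.ring_outer_diameter / 2.0) ** 2
    in_cyl = r2 <= (spec.diameter / 2.0) ** 2
    vol[in_ring] = hu["water"]
    lab[in_ring] = WATER_LABEL
    vol[in_cyl] = hu["lung_parenchyma"]
    lab[in_cyl] = PARENCHYMA_LABEL

    legend = {PARENCHYMA_LABEL: "lung_parenchyma", WATER_LABEL: "water"}
    specs_by_id = {l.lesion_id: l for l in spec.lesions}
    for ll in layout.lesions:
        les = specs_by_id[ll.lesion_id]
        a, _, c = ll.semi_axes
        cx, cy, cz = ll.center
        rho2 = (
            ((x[:, None, None] - cx) / a) ** 2
            + ((y[None, :, None] - cy) / a) ** 2
            + ((z[None, None, :] - cz) / c) ** 2
        )
        inside = rho2 <= 1.0
        if not inside.any():
            raise GeometryError(f"lesion {ll.lesion_id} rasterized to zero voxels")
        lab[inside] = ll.label
        legend[ll.label] = ll.lesion_id
        if les.lesion_type == "part_solid":
            shell_hu, core_hu = hu["part_solid"], hu["solid"]
            frac = (les.mean_intensity - shell_hu) / (core_hu - shell_hu)
            if not 0.0 < frac < 1.0:
                raise ConfigError(
                    f"part-solid target {les.mean_intensity} HU outside the "
                    f"shell/core range [{shell_hu}, {core_hu}]"
                )
            n = int(inside.sum())
            n_core = int(round(frac * n))
            order = np.argsort(rho2[inside], kind="stable")
            vox = np.argwhere(inside)
            core_vox = vox[order[:n_core]]
            vol[inside] = shell_hu
            vol[core_vox[:, 0], core_vox[:, 1], core_vox[:, 2]] = core_hu
            comp[core_vox[:, 0], core_vox[:, 1], core_vox[:, 2]] = 1
        else:
            vol[inside] = les.mean_intensity

    if texture is not None and texture.amplitude > 0 and layout.lesions:
        # Texture only inside lesions: lesion radiomics needs non-degenerate
        # truth texture, while flat parenchyma/water keep ROI-scale means
        # unbiased estimates of the configured material HU (correlated
        # texture does not average out inside an 8 mm disc).
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        t = _band_passed_texture(shape, spacing, texture, rng)
        for ll in layout.lesions:
            region = lab == ll.label
            vol[region] += t[region] - t[region].mean()

    volume = ImageVolume(
        data=vol, spacing=spacing, origin=origin, scanner=scanner, dose=0.0, seed=seed
    )
    mask = LabelMask(
        data=lab,
        spacing=spacing,
        origin=origin,
        legend=legend,
        components=comp if comp.any() else None,
        layout=layout,
    )
    return volume, mask
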
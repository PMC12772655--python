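"""Material tables and lesion/phantom specifications.

The canonical values reproduce a dose-matched two-scanner phantom study:
per-material mean HU for an energy-integrating system (EIDCT) and a
photon-counting prototype (PCCT), and six lung lesions (solid, part-solid,
ground-glass; one small and one large of each) with their maximum 3D
diameters and mean intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

AIR_HU = -1000.0

MATERIALS = ("lung_parenchyma", "ground_glass", "part_solid", "solid", "water")

SCANNERS = ("EIDCT", "PCCT")

LESION_TYPES = ("solid", "part_solid", "ground_glass")

SIZE_CLASSES = ("small", "large")


class ConfigError(ValueError):
    """Invalid material / phantom configuration."""


class GeometryError(ValueError):
    """A lesion cannot be placed inside its sector."""


@dataclass(frozen=True)
class MaterialTable:
    """Per-scanner mean HU for the five study materials.

    The density ordering lung parenchyma < ground-glass < part-solid <
    solid < water must hold for every scanner.
    """

    hu: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for scanner, table in self.hu.items():
            missing = [m for m in MATERIALS if m not in table]
            if missing:
                raise ConfigError(f"{scanner}: missing materials {missing}")
            vals = [table[m] for m in MATERIALS]
            if not all(a < b for a, b in zip(vals, vals[1:])):
                raise ConfigError(
                    f"{scanner}: material HU must increase in the order {MATERIALS}"
                )

    def for_scanner(self, scanner: str) -> dict[str, float]:
        try:
            return dict(self.hu[scanner])
        except KeyError:
            raise ConfigError(f"unknown scanner {scanner!r}") from None

    @property
    def scanners(self) -> tuple[str, ...]:
        return tuple(self.hu)


#: Pooled per-material HU means measured on the two scanners (all doses).
DEFAULT_MATERIALS = MaterialTable(
    {
        "EIDCT": {
            "lung_parenchyma": -873.9,
            "ground_glass": -723.7,
            "part_solid": -660.9,
            "solid": -22.9,
            "water": -2.9,
        },
        "PCCT": {
            "lung_parenchyma": -871.5,
            "ground_glass": -750.1,
            "part_solid": -662.8,
            "solid": -41.8,
            "water": -12.7,
        },
    }
)


@dataclass(frozen=True)
class LesionSpec:
    """One lesion: type, size class, maximum 3D diameter and target mean HU."""

    lesion_id: str
    lesion_type: str
    size_class: str
    max_3d_diameter: float  # mm
    mean_intensity: float  # HU, target mean over the lesion mask
    sector: str  # "quarter" or "half"
    phantom_id: int

    def __post_init__(self) -> None:
        if self.lesion_type not in LESION_TYPES:
            raise ConfigError(f"unknown lesion type {self.lesion_type!r}")
        if self.size_class not in SIZE_CLASSES:
            raise ConfigError(f"unknown size class {self.size_class!r}")
        if self.max_3d_diameter <= 0:
            raise ConfigError("lesion diameter must be positive")
        if self.sector not in ("quarter", "half"):
            raise ConfigError(f"sector must be 'quarter' or 'half', got {self.sector!r}")


CANONICAL_LESIONS: tuple[LesionSpec, ...] = (
    LesionSpec("large_part_solid", "part_solid", "large", 62.8, -614.6, "quarter", 1),
    LesionSpec("small_part_solid", "part_solid", "small", 36.2, -560.9, "quarter", 1),
    LesionSpec("large_solid", "solid", "large", 43.1, -94.8, "quarter", 1),
    LesionSpec("small_solid", "solid", "small", 23.5, -164.8, "quarter", 1),
    LesionSpec("large_ground_glass", "ground_glass", "large", 48.6, -734.6, "half", 2),
    LesionSpec("small_ground_glass", "ground_glass", "small", 22.9, -747.4, "half", 2),
)


@dataclass(frozen=True)
class PhantomSpec:
    """A cylindrical phantom holding lesions in angular sectors.

    ``ring_outer_diameter`` is the outer edge of the surrounding solid-water
    ring (extension ring to 200 mm where the phantom is narrower, plus the
    holder ring the water ROI is placed in).
    """

    phantom_id: int
    diameter: float  # mm
    height: float  # mm
    lesions: tuple[LesionSpec, ...]
    ring_outer_diameter: float = 240.0
    bore_diameter: float = 200.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise ConfigError("phantom dimensions must be positive")
        if self.ring_outer_diameter <= self.bore_diameter:
            raise ConfigError("ring must extend beyond the bore diameter")
        for les in self.lesions:
            if les.phantom_id != self.phantom_id:
                raise ConfigError(
                    f"lesion {les.lesion_id} belongs to phantom {les.phantom_id}"
                )


def canonical_phantoms(
    lesions: tuple[LesionSpec, ...] = CANONICAL_LESIONS,
) -> tuple[PhantomSpec, ...]:
    """The two study phantoms: Ø200×32 mm (four lesions in quarter sectors)
    and Ø150×40 mm (two lesions in half sectors, water extension to 200 mm)."""
    ph1 = tuple(l for l in lesions if l.phantom_id == 1)
    ph2 = tuple(l for l in lesions if l.phantom_id == 2)
    out = []
    if ph1:
        out.append(PhantomSpec(1, 200.0, 32.0, ph1))
    if ph2:
        out.append(PhantomSpec(2, 150.0, 40.0, ph2))
    return tuple(out)


def single_lesion_phantom(lesion: LesionSpec, **kw) -> PhantomSpec:
    """A reduced phantom holding one lesion (toy grids, unit tests)."""
    base = {1: (200.0, 32.0), 2: (150.0, 40.0)}[lesion.phantom_id]
    return PhantomSpec(lesion.phantom_id, base[0], base[1], (lesion,), **kw)


def scaled_lesion(lesion: LesionSpec, **changes) -> LesionSpec:
    return replace(lesion, **changes)
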
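"""Study-grid enumeration and deterministic scan generation.

The default grid mirrors the experimental design: two scanners, five
CTDIvol levels (20.4, 9.8, 4.9, 2.4, 1.6 mGy), three repetitions, two
phantoms holding six lesions in total - 180 lesion-measurement instances.
Every volume is reproducible from the base seed via a per-condition seed
derived from (scanner, dose, repetition, phantom).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .materials import MaterialTable, PhantomSpec, DEFAULT_MATERIALS, canonical_phantoms
from .noise import NoiseModel, default_noise_models, simulate_scan
from .phantom import TextureParams, rasterize_phantom
from .volume import ImageVolume, LabelMask

__all__ = ["StudyGrid", "DOSES_MGY", "condition_seed", "iter_study", "generate_study"]

DOSES_MGY: tuple[float, ...] = (20.4, 9.8, 4.9, 2.4, 1.6)


@dataclass(frozen=True)
class StudyGrid:
    """The cross-product of study conditions plus the base seed."""

    scanners: tuple[str, ...] = ("EIDCT", "PCCT")
    doses: tuple[float, ...] = DOSES_MGY
    repetitions: int = 3
    base_seed: int = 20260101

    def __post_init__(self) -> None:
        if self.repetitions < 1 or not self.scanners or not self.doses:
            raise ValueError("grid must have >= 1 scanner, dose and repetition")

    def n_instances(self, n_lesions: int = 6) -> int:
        return n_lesions * len(self.doses) * len(self.scanners) * self.repetitions

    def conditions(self) -> Iterator[tuple[str, float, int]]:
        for scanner in self.scanners:
            for dose in self.doses:
                for rep in range(self.repetitions):
                    yield scanner, dose, rep


def condition_seed(
    base_seed: int, scanner: str, dose: float, repetition: int, phantom_id: int,
    purpose: str = "scan",
) -> int:
    """Deterministic per-condition seed (< 2^31)."""
    ss = np.random.SeedSequence(
        [
            int(base_seed),
            zlib.crc32(scanner.encode()),
            int(round(dose * 1000)),
            int(repetition),
            int(phantom_id),
            zlib.crc32(purpose.encode()),
        ]
    )
    return int(ss.generate_state(1)[0] >> 1)


@dataclass
class ScanInstance:
    """One simulated acquisition: a phantom at one (scanner, dose, rep)."""

    scanner: str
    dose: float
    repetition: int
    phantom: PhantomSpec
    volume: ImageVolume
    mask: LabelMask
    seed: int


def build_truths(
    phantoms: Sequence[PhantomSpec],
    materials: MaterialTable,
    scanners: Sequence[str],
    base_seed: int,
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0),
    texture: TextureParams | None = TextureParams(),
) -> dict[tuple[str, int], tuple[ImageVolume, LabelMask]]:
    """Noise-free truth volume + mask per (scanner, phantom)."""
    out = {}
    for scanner in scanners:
        for spec in phantoms:
            seed = condition_seed(base_seed, scanner, 0.0, 0, spec.phantom_id, "truth")
            out[(scanner, spec.phantom_id)] = rasterize_phantom(
                spec, materials, scanner, spacing=spacing, texture=texture, seed=seed
            )
    return out


def iter_study(
    grid: StudyGrid,
    phantoms: Sequence[PhantomSpec] | None = None,
    materials: MaterialTable = DEFAULT_MATERIALS,
    models: dict[str, NoiseModel] | None = None,
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0),
    texture: TextureParams | None = TextureParams(),
    truths: dict | None = None,
) -> Iterator[ScanInstance]:
    """Stream simulated scans across the study grid (one volume at a time)."""
    phantoms = list(phantoms) if phantoms is not None else list(canonical_phantoms())
    models = models if models is not None else default_noise_models()
    if truths is None:
        truths = build_truths(
            phantoms, materials, grid.scanners, grid.base_seed, spacing, texture
        )
    for scanner, dose, rep in grid.conditions():
        for spec in phantoms:
            truth, mask = truths[(scanner, spec.phantom_id)]
            seed = condition_seed(grid.base_seed, scanner, dose, rep, spec.phantom_id)
            vol = simulate_scan(
                truth, mask, models[scanner],
                scanner=scanner, dose=dose, repetition=rep, seed=seed,
            )
            yield ScanInstance(scanner, dose, rep, spec, vol, mask, seed)


def mask_legend_path(mask_path: str | Path) -> Path:
    return Path(str(mask_path).replace(".nii.gz", "") + "_legend.json")


def write_mask_legend(mask_path: str | Path, legend) -> None:
    import json

    mask_legend_path(mask_path).write_text(
        json.dumps({int(k): v for k, v in legend.items()})
    )


def _instance_stem(inst: ScanInstance) -> str:
    return (
        f"{inst.scanner}_d{inst.dose:g}mGy_r{inst.repetition}"
        f"_ph{inst.phantom.phantom_id}"
    )


def manifest_rows(inst: ScanInstance, volume_path: str = "", mask_path: str = ""):
    """One manifest row per lesion contained in a scan instance."""
    for les in inst.phantom.lesions:
        yield {
            "lesion_id": les.lesion_id,
            "lesion_type": les.lesion_type,
            "size_class": les.size_class,
            "scanner": inst.scanner,
            "dose_mGy": inst.dose,
            "repetition": inst.repetition,
            "seed": inst.seed,
            "volume_path": volume_path,
            "mask_path": mask_path,
        }


def generate_study(
    grid: StudyGrid,
    phantoms: Sequence[PhantomSpec] | None = None,
    materials: MaterialTable = DEFAULT_MATERIALS,
    models: dict[str, NoiseModel] | None = None,
    out_dir: str | Path = "study",
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0),
    texture: TextureParams | None = TextureParams(),
) -> pd.DataFrame:
    """Write every study volume and mask to ``out_dir`` and return the
    lesion-instance manifest (also written as ``manifest.csv``).

    Re-running with the same grid resumes: volumes already on disk are kept
    (seeds are deterministic, so a partial run plus a resume equals a full
    run).
    """
    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    phantoms = list(phantoms) if phantoms is not None else list(canonical_phantoms())
    rows = []
    mask_written = set()
    for inst in iter_study(grid, phantoms, materials, models, spacing, texture):
        vpath = out_dir / "volumes" / f"{_instance_stem(inst)}.nii.gz"
        mpath = out_dir / "masks" / (
            f"{inst.scanner}_ph{inst.phantom.phantom_id}_mask.nii.gz"
        )
        if not vpath.exists():
            inst.volume.to_nifti(vpath)
        if (inst.scanner, inst.phantom.phantom_id) not in mask_written:
            if not mpath.exists():
                inst.mask.to_nifti(mpath)
            write_mask_legend(mpath, inst.mask.legend)
            mask_written.add((inst.scanner, inst.phantom.phantom_id))
        rows.extend(manifest_rows(inst, str(vpath), str(mpath)))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
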
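"""End-to-end study pipeline: generate -> measure -> radiomics -> cluster ->
stats -> report, driven by a single serializable configuration.

The default configuration reproduces the study design exactly: two scanners,
doses 20.4/9.8/4.9/2.4/1.6 mGy, three repetitions, six lesions in two
phantoms - 180 lesion-measurement instances.  Everything is deterministic
under the base seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    ClusterReport,
    fit_pca,
    nearest_centroid_accuracy,
    project,
    separability,
    within_cluster_distance,
)
from .materials import (
    CANONICAL_LESIONS,
    DEFAULT_MATERIALS,
    MaterialTable,
    canonical_phantoms,
)
from .noise import DEFAULT_NOISE_CALIBRATION, DEFAULT_NOISE_CORR_MM, fit_noise_model
from .phantom import TextureParams
from .radiomics import ExtractionConfig, extract_all, feature_names
from .roi import (
    coefficient_of_variation,
    measure_roi,
    percent_change,
    place_rois,
)
from .stats import one_way_anova, paired_compare
from .study import (
    StudyGrid,
    ScanInstance,
    iter_study,
    manifest_rows,
    write_mask_legend,
)
from .volume import ImageVolume, LabelMask

logger = logging.getLogger("ctphantom")

__all__ = ["StudyConfig", "StudyReport", "run_study", "import_external"]

PROVENANCE_COLS = (
    "lesion_id", "lesion_type", "size_class", "scanner", "dose_mGy", "repetition",
)


@dataclass
class StudyConfig:
    """Source of truth for a full study run; YAML round-trippable."""

    scanners: tuple[str, ...] = ("EIDCT", "PCCT")
    doses: tuple[float, ...] = (20.4, 9.8, 4.9, 2.4, 1.6)
    repetitions: int = 3
    base_seed: int = 20260101
    materials: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MATERIALS.hu.items()}
    )
    noise_calibration: dict = field(
        default_factory=lambda: {
            k: [list(p) for p in v] for k, v in DEFAULT_NOISE_CALIBRATION.items()
        }
    )
    noise_corr_mm: float = DEFAULT_NOISE_CORR_MM
    texture_amplitude: float = 20.0
    texture_corr_mm: float = 2.0
    texture_highpass_mm: float = 6.0
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    bin_width: float = 25.0
    variance_threshold: float = 0.95
    standardize: bool = True
    alpha: float = 0.05
    out_dir: str = "study_out"

    # -- derived objects -------------------------------------------------
    def grid(self) -> StudyGrid:
        return StudyGrid(
            scanners=tuple(self.scanners),
            doses=tuple(self.doses),
            repetitions=self.repetitions,
            base_seed=self.base_seed,
        )

    def material_table(self) -> MaterialTable:
        return MaterialTable({k: dict(v) for k, v in self.materials.items()})

    def noise_models(self) -> dict:
        return {
            sc: fit_noise_model(
                [(p[0], p[1]) for p in cal], corr_mm=self.noise_corr_mm, scanner=sc
            )
            for sc, cal in self.noise_calibration.items()
        }

    def texture(self) -> TextureParams | None:
        if self.texture_amplitude <= 0:
            return None
        return TextureParams(
            self.texture_amplitude, self.texture_corr_mm, self.texture_highpass_mm
        )

    def extraction(self) -> ExtractionConfig:
        return ExtractionConfig(bin_width=self.bin_width)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["scanners"] = list(self.scanners)
        d["doses"] = list(self.doses)
        d["spacing"] = list(self.spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("scanners", "doses", "spacing"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _roi_row(m, phantom_id: int) -> dict:
    return {
        "phantom_id": phantom_id,
        "scanner": m.scanner,
        "dose_mGy": m.dose,
        "repetition": m.repetition,
        "material": m.roi.material,
        "region_name": m.roi.region_name,
        "lesion_id": m.roi.lesion_id,
        "slice_index": m.roi.slice_index,
        "center_x_mm": m.roi.center_xy[0],
        "center_y_mm": m.roi.center_xy[1],
        "diameter_mm": m.roi.diameter,
        "mean": m.mean,
        "sd": m.sd,
        "n_voxels": m.n_voxels,
    }


def measure_scan(inst: ScanInstance, rois) -> list[dict]:
    return [
        _roi_row(measure_roi(inst.volume, roi), inst.phantom.phantom_id)
        for roi in rois
    ]


def extract_scan_features(inst: ScanInstance, config: ExtractionConfig) -> list[dict]:
    rows = []
    for les in inst.phantom.lesions:
        fv = extract_all(
            inst.volume,
            inst.mask,
            label=les.lesion_id,
            config=config,
            provenance={
                "lesion_id": les.lesion_id,
                "lesion_type": les.lesion_type,
                "size_class": les.size_class,
                "scanner": inst.scanner,
                "dose_mGy": inst.dose,
                "repetition": inst.repetition,
            },
        )
        rows.append({**fv.provenance, **fv.values})
    return rows


def cnr_table(roi_df: pd.DataFrame) -> pd.DataFrame:
    """Per-(scanner, dose, repetition, lesion, slice) signed CNR, computed
    from each lesion ROI and its adjacent parenchyma ROI."""
    keys = ["scanner", "dose_mGy", "repetition", "phantom_id", "lesion_id",
            "slice_index"]
    lesions = roi_df[(roi_df["lesion_id"].notna())
                     & (roi_df["material"] != "lung_parenchyma")]
    background = roi_df[(roi_df["lesion_id"].notna())
                        & (roi_df["material"] == "lung_parenchyma")]
    merged = lesions.merge(
        background[keys + ["mean"]].rename(columns={"mean": "bg_mean"}),
        on=keys, validate="one_to_one",
    )
    with np.errstate(divide="ignore"):
        merged["cnr"] = (merged["mean"] - merged["bg_mean"]) / merged["sd"]
    merged.loc[merged["sd"] == 0, "cnr"] = np.nan
    out = merged.rename(columns={"material": "lesion_type"})
    return out[keys + ["lesion_type", "cnr"]]


def material_stats_table(roi_df: pd.DataFrame, instances=None) -> pd.DataFrame:
    rows = []
    for (scanner, material), g in roi_df.groupby(["scanner", "material"]):
        arr = g["mean"].to_numpy(dtype=float)
        n = arr.size
        rows.append({
            "scanner": scanner,
            "material": material,
            "mean": arr.mean(),
            "se": arr.std(ddof=0) / np.sqrt(n) if n > 1 else 0.0,
            "n_rois": n,
        })
    return pd.DataFrame(rows)


def noise_summary_table(roi_df: pd.DataFrame) -> pd.DataFrame:
    paren = roi_df[roi_df["material"] == "lung_parenchyma"]
    rows = []
    for (scanner, dose), g in paren.groupby(["scanner", "dose_mGy"]):
        rows.append({
            "scanner": scanner,
            "dose_mGy": dose,
            "noise_mean": g["sd"].mean(),
            "noise_sd": g["sd"].std(ddof=1),
            "n_rois": len(g),
        })
    return pd.DataFrame(rows).sort_values(["scanner", "dose_mGy"]).reset_index(drop=True)


def noise_comparison_table(
    noise_df: pd.DataFrame, reference: str = "EIDCT", comparison: str = "PCCT"
) -> pd.DataFrame:
    piv = noise_df.pivot(index="dose_mGy", columns="scanner", values="noise_mean")
    rows = []
    for dose, row in piv.iterrows():
        if reference in row and comparison in row:
            rows.append({
                "dose_mGy": dose,
                f"{reference}_noise": row[reference],
                f"{comparison}_noise": row[comparison],
                "reduction_pct": percent_change(row[reference], row[comparison]),
            })
    return pd.DataFrame(rows)


def cnr_summary_table(cnr_df: pd.DataFrame) -> pd.DataFrame:
    d = cnr_df.assign(cnr_abs=cnr_df["cnr"].abs())
    out = (
        d.groupby(["scanner", "dose_mGy", "lesion_type"])["cnr_abs"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "cnr_mean", "std": "cnr_sd", "count": "n"})
    )
    return out


def cnr_comparison_table(
    cnr_df: pd.DataFrame, reference: str = "EIDCT", comparison: str = "PCCT"
) -> pd.DataFrame:
    """Percent CNR increase considering all six lesions: per-lesion mean |CNR|
    across repetitions and slices, averaged over lesions, then the percent
    change of the two scanner means."""
    d = cnr_df.assign(cnr_abs=cnr_df["cnr"].abs())
    per_lesion = (
        d.groupby(["scanner", "dose_mGy", "lesion_id"])["cnr_abs"].mean().reset_index()
    )
    pooled = per_lesion.groupby(["scanner", "dose_mGy"])["cnr_abs"].mean().unstack(0)
    rows = []
    for dose, row in pooled.iterrows():
        if reference in row and comparison in row:
            rows.append({
                "dose_mGy": dose,
                f"{reference}_cnr": row[reference],
                f"{comparison}_cnr": row[comparison],
                "increase_pct": percent_change(row[reference], row[comparison],
                                               kind="increase"),
            })
    return pd.DataFrame(rows)


def cov_table(roi_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (scanner, material), g in roi_df.groupby(["scanner", "material"]):
        dose_means = g.groupby("dose_mGy")["mean"].mean()
        if len(dose_means) < 2:
            continue
        rows.append({
            "scanner": scanner,
            "material": material,
            "cov": coefficient_of_variation(dose_means.to_numpy()),
        })
    return pd.DataFrame(rows)


def cluster_from_features(
    features_df: pd.DataFrame,
    variance_threshold: float = 0.95,
    standardize: bool = True,
) -> tuple[ClusterReport, pd.DataFrame]:
    feat_cols = [c for c in features_df.columns if c not in PROVENANCE_COLS]
    space = fit_pca(
        features_df[feat_cols],
        variance_threshold=variance_threshold,
        standardize=standardize,
    )
    pts = project(features_df[list(space.feature_names)], space)
    labels = features_df["lesion_type"].to_numpy()
    scanners = features_df["scanner"].to_numpy()
    within = {}
    sep = {}
    for sc in pd.unique(scanners):
        sel = scanners == sc
        within[sc] = within_cluster_distance(pts[sel], labels[sel])
        sep[sc] = separability(pts[sel], labels[sel])
    report = ClusterReport(
        n_components=space.n_retained,
        explained_variance_ratio=tuple(float(x) for x in
                                       space.explained_variance_ratio),
        within={sc: {t: v for t, v in d.items()} for sc, d in within.items()},
        separability={sc: float(v) for sc, v in sep.items()},
    )
    points = pd.DataFrame(
        pts, columns=[f"PC{i + 1}" for i in range(pts.shape[1])]
    )
    for col in PROVENANCE_COLS:
        if col in features_df:
            points[col] = features_df[col].to_numpy()
    points["nearest_centroid_accuracy"] = nearest_centroid_accuracy(pts, labels)
    return report, points


def stats_table(
    roi_df: pd.DataFrame, cnr_df: pd.DataFrame, alpha: float = 0.05,
    reference: str = "EIDCT", comparison: str = "PCCT",
) -> pd.DataFrame:
    """The study's significance tests: per-dose paired scanner comparisons of
    noise and CNR (gated t / signed-rank), and per-scanner cross-dose ANOVA
    of material HU."""
    results = []
    pair_keys = ["phantom_id", "lesion_id", "slice_index", "repetition"]
    scanners = set(roi_df["scanner"].unique())
    paren = roi_df[roi_df["material"] == "lung_parenchyma"]
    if {reference, comparison} <= scanners:
        for dose, g in paren.groupby("dose_mGy"):
            piv = g.pivot_table(index=pair_keys, columns="scanner", values="sd")
            piv = piv.dropna()
            if len(piv) >= 4:
                r = paired_compare(
                    piv[reference], piv[comparison],
                    comparison=f"noise_{reference}_vs_{comparison}@{dose:g}mGy",
                    alpha=alpha,
                )
                results.append((r, "noise", dose, None))
        d = cnr_df.assign(cnr_abs=cnr_df["cnr"].abs())
        for (dose, ltype), g in d.groupby(["dose_mGy", "lesion_type"]):
            piv = g.pivot_table(index=pair_keys, columns="scanner",
                                values="cnr_abs").dropna()
            if len(piv) >= 4:
                r = paired_compare(
                    piv[reference], piv[comparison],
                    comparison=f"cnr_{ltype}_{reference}_vs_{comparison}@{dose:g}mGy",
                    alpha=alpha,
                )
                results.append((r, f"cnr_{ltype}", dose, None))
    for (scanner, material), g in roi_df.groupby(["scanner", "material"]):
        groups = [
            grp["mean"].to_numpy() for _, grp in g.groupby("dose_mGy")
            if len(grp) >= 2
        ]
        if len(groups) >= 3:
            r = one_way_anova(
                groups, comparison=f"hu_across_doses_{scanner}_{material}",
                alpha=alpha,
            )
            results.append((r, f"hu_{material}", None, scanner))
    rows = []
    for r, metric, dose, scanner in results:
        rows.append({
            "comparison": r.comparison,
            "metric": metric,
            "dose_mGy": dose,
            "scanner": scanner,
            "test": r.test_name,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "normality_p": r.normality_p,
            "significant": r.significant,
        })
    return pd.DataFrame(rows)


@dataclass
class StudyReport:
    """All study artifacts plus provenance; regenerable bit-identically."""

    config: StudyConfig
    manifest: pd.DataFrame
    roi_measurements: pd.DataFrame
    material_stats: pd.DataFrame
    noise_summary: pd.DataFrame
    noise_comparison: pd.DataFrame
    cnr: pd.DataFrame
    cnr_summary: pd.DataFrame
    cnr_comparison: pd.DataFrame
    cov: pd.DataFrame
    features: pd.DataFrame | None = None
    cluster_report: ClusterReport | None = None
    pca_points: pd.DataFrame | None = None
    stats: pd.DataFrame | None = None

    def provenance(self) -> dict:
        return {
            "config_hash": self.config.content_hash(),
            "base_seed": self.config.base_seed,
            "version": __version__,
        }

    def summary_text(self) -> str:
        lines = [
            f"ctphantom study report (seed {self.config.base_seed}, "
            f"config {self.config.content_hash()})",
            "",
            "Pooled material HU (mean +/- SE, n ROIs):",
        ]
        for _, r in self.material_stats.iterrows():
            lines.append(
                f"  {r.scanner:6s} {r.material:16s} {r['mean']:9.1f} "
                f"+/- {r.se:5.1f}  (n={int(r.n_rois)})"
            )
        lines.append("")
        lines.append("Parenchyma noise by dose (mean +/- SD):")
        for _, r in self.noise_summary.iterrows():
            lines.append(
                f"  {r.scanner:6s} {r.dose_mGy:5.1f} mGy  "
                f"{r.noise_mean:6.1f} +/- {r.noise_sd:5.1f}"
            )
        if len(self.noise_comparison):
            lines.append("")
            lines.append("Noise reduction PCCT vs EIDCT by dose:")
            for _, r in self.noise_comparison.iterrows():
                lines.append(f"  {r.dose_mGy:5.1f} mGy  {r.reduction_pct:5.1f}%")
        if self.cluster_report is not None:
            cr = self.cluster_report
            lines.append("")
            lines.append(
                f"PCA: {cr.n_components} components at "
                f"{self.config.variance_threshold:.0%} variance"
            )
            for sc, d in cr.within.items():
                for t, (m, s) in d.items():
                    lines.append(f"  within-cluster {sc:6s} {t:13s} "
                                 f"{m:5.2f} +/- {s:4.2f}")
            for sc, v in cr.separability.items():
                lines.append(f"  separability   {sc:6s} {v:5.2f}")
        return "\n".join(lines)

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.save(out / "config.yaml")
        self.manifest.to_csv(out / "manifest.csv", index=False)
        self.roi_measurements.round(6).to_csv(
            out / "roi_measurements.csv", index=False
        )
        self.material_stats.round(6).to_csv(out / "material_stats.csv", index=False)
        self.noise_summary.round(6).to_csv(out / "noise.csv", index=False)
        self.noise_comparison.round(6).to_csv(
            out / "noise_comparison.csv", index=False
        )
        self.cnr.round(6).to_csv(out / "cnr.csv", index=False)
        self.cnr_summary.round(6).to_csv(out / "cnr_summary.csv", index=False)
        self.cnr_comparison.round(6).to_csv(out / "cnr_comparison.csv", index=False)
        self.cov.round(6).to_csv(out / "cov.csv", index=False)
        if self.features is not None:
            self.features.to_csv(out / "features.csv", index=False)
        if self.cluster_report is not None:
            payload = self.cluster_report.to_dict() | {"provenance": self.provenance()}
            (out / "cluster_report.json").write_text(json.dumps(payload, indent=2))
        if self.pca_points is not None:
            self.pca_points.round(8).to_csv(out / "pca_points.csv", index=False)
        if self.stats is not None:
            self.stats.to_csv(out / "stats.csv", index=False)
        (out / "summary.txt").write_text(self.summary_text() + "\n")
        return out


def run_study(
    config: StudyConfig | None = None,
    with_radiomics: bool = True,
    with_stats: bool = True,
    write_volumes: bool = False,
    out_dir=None,
) -> StudyReport:
    """Execute the full pipeline over the configured study grid.

    Scans are streamed one at a time (generate, measure, extract, discard),
    so memory stays at a single volume.  With ``write_volumes`` the NIfTI
    artifacts are also written under ``out_dir``.
    """
    config = config or StudyConfig()
    grid = config.grid()
    phantoms = canonical_phantoms(
        tuple(l for l in CANONICAL_LESIONS)
    )
    materials = config.material_table()
    models = config.noise_models()

    roi_cache: dict[tuple[str, int], list] = {}
    roi_rows: list[dict] = []
    feat_rows: list[dict] = []
    man_rows: list[dict] = []
    vol_dir = None
    if write_volumes:
        vol_dir = Path(out_dir or config.out_dir)
        (vol_dir / "volumes").mkdir(parents=True, exist_ok=True)
        (vol_dir / "masks").mkdir(parents=True, exist_ok=True)
    masks_written = set()

    n_scans = 0
    for inst in iter_study(
        grid, phantoms, materials, models,
        spacing=config.spacing, texture=config.texture(),
    ):
        key = (inst.scanner, inst.phantom.phantom_id)
        if key not in roi_cache:
            roi_cache[key] = place_rois(
                inst.mask, inst.phantom,
                include_water=inst.phantom.phantom_id == 1,
            )
        roi_rows.extend(measure_scan(inst, roi_cache[key]))
        if with_radiomics:
            feat_rows.extend(extract_scan_features(inst, config.extraction()))
        vpath, mpath = "", ""
        if vol_dir is not None:
            stem = (f"{inst.scanner}_d{inst.dose:g}mGy_r{inst.repetition}"
                    f"_ph{inst.phantom.phantom_id}")
            vpath = str(vol_dir / "volumes" / f"{stem}.nii.gz")
            inst.volume.to_nifti(vpath)
            mpath = str(
                vol_dir / "masks"
                / f"{inst.scanner}_ph{inst.phantom.phantom_id}_mask.nii.gz"
            )
            if key not in masks_written:
                inst.mask.to_nifti(mpath)
                write_mask_legend(mpath, inst.mask.legend)
                masks_written.add(key)
        man_rows.extend(manifest_rows(inst, vpath, mpath))
        n_scans += 1
        logger.info("scan %d: %s %.1f mGy rep %d phantom %d",
                    n_scans, inst.scanner, inst.dose, inst.repetition,
                    inst.phantom.phantom_id)

    roi_df = pd.DataFrame(roi_rows)
    cnr_df = cnr_table(roi_df)
    report = StudyReport(
        config=config,
        manifest=pd.DataFrame(man_rows),
        roi_measurements=roi_df,
        material_stats=material_stats_table(roi_df),
        noise_summary=noise_summary_table(roi_df),
        noise_comparison=noise_comparison_table(noise_summary_table(roi_df)),
        cnr=cnr_df,
        cnr_summary=cnr_summary_table(cnr_df),
        cnr_comparison=cnr_comparison_table(cnr_df),
        cov=cov_table(roi_df),
    )
    if with_radiomics:
        features_df = pd.DataFrame(feat_rows)
        report.features = features_df
        report.cluster_report, report.pca_points = cluster_from_features(
            features_df, config.variance_threshold, config.standardize
        )
    if with_stats:
        report.stats = stats_table(roi_df, cnr_df, alpha=config.alpha)
    if out_dir is not None:
        report.save(out_dir)
    return report


def import_external(volumes, masks, labels) -> pd.DataFrame:
    """Build a study manifest from existing NIfTI volume/mask pairs.

    ``volumes`` and ``masks`` are equal-length path lists; ``labels`` is a
    list of per-pair metadata dicts with at least scanner, dose_mGy,
    repetition, and a ``lesions`` mapping of lesion_id -> {lesion_type,
    size_class}.  Volume/mask grids must agree in shape and spacing.
    """
    if not (len(volumes) == len(masks) == len(labels)):
        raise ValueError("volumes, masks and labels must have equal length")
    rows = []
    for vpath, mpath, meta in zip(volumes, masks, labels):
        if not Path(mpath).exists():
            raise FileNotFoundError(f"missing mask for volume {vpath}: {mpath}")
        vol = ImageVolume.from_nifti(vpath)
        mask = LabelMask.from_nifti(mpath)
        if vol.shape != mask.shape:
            raise ValueError(f"{vpath}: volume/mask shape mismatch")
        if any(abs(a - b) > 1e-6 for a, b in zip(vol.spacing, mask.spacing)):
            raise ValueError(f"{vpath}: volume/mask spacing mismatch")
        for lesion_id, info in meta.get("lesions", {}).items():
            rows.append({
                "lesion_id": lesion_id,
                "lesion_type": info.get("lesion_type", "unknown"),
                "size_class": info.get("size_class", "unknown"),
                "scanner": meta.get("scanner", "unknown"),
                "dose_mGy": meta.get("dose_mGy", float("nan")),
                "repetition": meta.get("repetition", 0),
                "seed": meta.get("seed", -1),
                "volume_path": str(vpath),
                "mask_path": str(mpath),
            })
    return pd.DataFrame(rows)
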
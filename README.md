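# ctphantom

Digital lung-phantom CT simulation and quantitative evaluation for
comparing a photon-counting CT (PCCT) against a conventional
energy-integrating CT (EIDCT) in low-dose lung-cancer-screening
conditions.

Low-dose screening CT lives or dies on image noise: ground-glass and
part-solid lung nodules sit barely above the parenchyma background, and
radiomics-based characterization needs features that stay stable across
dose and repetition.  Physical evaluations of new detectors use printed
patient-specific phantoms scanned on both systems; the images behind such
studies are rarely shareable.  `ctphantom` rebuilds that evaluation as a
reproducible computational pipeline for imaging physicists and radiomics
researchers: a calibrated digital-phantom generator stands in for the
scanner pair, and every analysis stage — ROI statistics, noise, CNR,
radiomics, cluster analysis, significance testing — runs identically on
simulated or imported (NIfTI) scans.

## The model in brief

* **Phantoms.** Two cylinders (Ø200 × 32 mm with four lesions, Ø150 × 40 mm
  with two) holding six ellipsoidal lesions — small/large solid,
  part-solid, ground-glass — rendered so each lesion's mask-mean HU equals
  its specified mean intensity; part-solid lesions are a dense core inside
  a homogeneous shell with the core fraction solved for the target mean.
* **Noise.** Per scanner, σ²(D) = a/D + b calibrated to five per-dose
  parenchyma noise means over 1.6–20.4 mGy; simulated scans add a
  correlated Gaussian field rescaled so noise *measured in 8 mm ROIs*
  equals σ(D).
* **Reading.** 13 deterministic 8 mm ROIs per slice on three central
  slices; pooled per-material HU (μ ± SE), noise σ_HU,lung, CNR_k =
  (μ_k − μ_BG,k)/σ_k, coefficients of variation, percent differences.
* **Radiomics.** 107 features per lesion instance (18 first-order, 14
  shape, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM), IBSI-style
  formulas, 25 HU fixed-bin discretization, implemented from scratch and
  verified against exhaustive brute-force enumeration in the tests.
* **Clustering.** z-scored features → PCA retaining 95% variance →
  within-cluster distance (feature consistency) and separability
  (between-centroid over within-cluster distance) per scanner.
* **Statistics.** Paired scanner comparisons gated by a Monte-Carlo
  Lilliefors normality test (paired t vs Wilcoxon signed-rank), one-way
  ANOVA for HU across doses, all at the 5% level.

The default configuration is the full study design: 6 lesions × 5 doses ×
2 scanners × 3 repetitions = 180 lesion-measurement instances, fully
deterministic under one base seed.  See `docs/methods.md` for the model
details and design rationale.

## Worked example

```bash
python examples/02_noise_model.py
```

```
EIDCT: a =    30036 HU^2*mGy, b =    962 HU^2, worst calibration residual 4.5%
PCCT: a =    21345 HU^2*mGy, b =   1183 HU^2, worst calibration residual 3.1%

Noise vs dose (anchored at the calibration doses):
    1.6 mGy: EIDCT  134.4 HU, PCCT  116.9 HU, reduction 13.0%
    2.4 mGy: EIDCT  117.2 HU, PCCT  103.5 HU, reduction 11.7%
    4.9 mGy: EIDCT   88.2 HU, PCCT   76.8 HU, reduction 12.9%
    9.8 mGy: EIDCT   65.9 HU, PCCT   57.9 HU, reduction 12.1%
   20.4 mGy: EIDCT   47.2 HU, PCCT   45.8 HU, reduction  3.0%
```

The quantum term `a` dominates at low dose, where the photon-counting
system's smaller electronic floor buys a 13% noise reduction; at 20.4 mGy
the two systems nearly converge (3%).  The other examples build a phantom
and verify lesion rendering (`01`), simulate a 1.6 mGy scan and read noise
and CNR from it (`03`), extract a 107-feature vector (`04`), embed a
reduced study in PC space (`05`), and run the complete study (`06`).

The same pipeline is scriptable from the shell:

```bash
ctphantom all --outdir study_out --seed 1        # everything, with NIfTI output
ctphantom generate ... / measure / radiomics / cluster / stats / report
```

## Layout

```
src/ctphantom/
  materials.py   material tables, lesion and phantom specifications
  phantom.py     rasterization of truth volumes and label masks
  noise.py       sigma^2(D) = a/D + b calibration, scan simulation
  study.py       study grid, seeding, NIfTI generation with manifest
  roi.py         ROI placement/measurement, pooled HU, noise, CNR, CoV
  radiomics/     discretization, first-order, shape, texture families
  cluster.py     PCA space, within-cluster distance, separability
  stats.py       Lilliefors-gated paired tests, ANOVA
  pipeline.py    StudyConfig / run_study / StudyReport, external import
  cli.py         thin click CLI over the pipeline stages
```
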
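# Methods

`ctphantom` simulates, in the image domain, a dose-matched comparison of a
photon-counting CT (PCCT) and an energy-integrating CT (EIDCT) on
patient-derived-style lung phantoms, and evaluates the simulated study with
the standard physics reading: HU accuracy, parenchyma noise,
contrast-to-noise ratio (CNR), radiomics, PCA cluster statistics, and
normality-gated significance tests.  This note records the model, its
parameters, and the design choices made where the design was genuinely
open.

## Digital phantoms

Two cylindrical phantoms are rasterized on the scanner's reconstruction
grid (512 x 512 at 0.5 mm in-plane, 1.0 mm slices by default):

* Phantom 1, Ø 200 x 32 mm: large/small part-solid and large/small solid
  lesions, one per quarter sector.
* Phantom 2, Ø 150 x 40 mm: large/small ground-glass lesions, one per half
  sector, with a water-equivalent extension ring to 200 mm.

Both sit inside a solid-water holder ring (modeled 200-240 mm) so the
water ROI of the reading scheme exists; air (-1000 HU) fills the rest of
the 256 mm field of view.  Each lesion is an ellipsoid whose in-plane
diameter equals its specified maximum 3D diameter (36.2/62.8 mm
part-solid, 23.5/43.1 mm solid, 22.9/48.6 mm ground-glass); the polar
semi-axis is capped so an 8 mm parenchyma gap remains above and below.
Lesion centers sit on the inscribed circle of their sector, which keeps at
least 2 mm of parenchyma margin or raises a geometry error.

Material HU come from a per-scanner table (defaults are the pooled
measured means of the two systems: lung parenchyma -873.9/-871.5,
ground-glass -723.7/-750.1, part-solid -660.9/-662.8, solid -22.9/-41.8,
water -2.9/-12.7 HU for EIDCT/PCCT).  Solid and ground-glass lesions are
rendered uniformly at their specified mean intensity (-164.8/-94.8 and
-747.4/-734.6 HU).  A part-solid lesion is a concentric dense core at the
table's *solid* HU inside a shell at the table's *part-solid* HU, with the
core voxel count solved so the mask mean equals the lesion's specified
mean (-560.9/-614.6 HU).  Rendering the shell at the part-solid material
value (rather than at ground-glass HU) reflects what an ROI in the
lesion's homogeneous region reads on the real systems, and is what
preserves the observed CNR ordering solid > part-solid > ground-glass;
the core fraction comes out near 16% (small) and 8% (large) of lesion
volume.  Because core membership is decided per voxel, every lesion's
mask-mean HU matches its specification to well under 1 HU.

A band-passed Gaussian texture (20 HU voxel SD, 2 mm correlation, scales
above 6 mm removed, re-centered to zero mean over each lesion mask) is
added **inside lesions only**.  Its purpose is to keep truth-image texture
features away from the degenerate single-gray-level case.  It is not
applied to parenchyma or water: correlated texture does not average out
inside an 8 mm disc (we measured 6-12 HU of fixed per-location disc-mean
offsets for any band-pass that leaves visible texture), and with only 18
fixed parenchyma ROI locations per scanner such offsets would bias the
pooled parenchyma HU by several HU.  Flat parenchyma keeps the pooled-HU
reading an unbiased estimate of the configured material value and makes
the noise calibration exact.  This is the main idealization relative to
printed physical phantoms, whose infill pattern does texture the
background; consequences: parenchyma ROI SD measures noise alone, and
truth-image (zero-dose) parenchyma is exactly uniform.

## Noise model and scan simulation

Noise follows sigma^2(D) = a/D + b (quantum term plus electronic floor).
The model is calibrated per scanner to five printed per-dose parenchyma
noise means (EIDCT 134.4/117.2/88.2/65.9/47.2 HU and PCCT
116.9/103.5/76.8/57.9/45.8 HU at 1.6/2.4/4.9/9.8/20.4 mGy).  The fit
minimizes the worst-case relative deviation across the calibration points
(an ordinary least-squares fit on sigma^2 leaves a 14% error at 20.4 mGy
because the two-parameter form underfits the curve's tail; the minimax fit
keeps every point within 5%).  `sigma(D)` returns the calibration value
exactly at a calibration dose and the fitted curve elsewhere: the
simulator's contract is to *reproduce the measured noise at the measured
doses*, with the parametric form supplying interpolation and the
physical reading (a > 0, b > 0, PCCT's advantage growing toward low dose).

A simulated scan is `truth + noise field`, where the field is white
Gaussian noise smoothed with a 0.6 mm Gaussian kernel and rescaled.  Two
calibration details matter:

* **ROI-scale rescaling.** The sample SD inside an 8 mm disc of a
  correlated field sits a few percent below the voxel-scale SD (fewer
  effective degrees of freedom).  The field is therefore rescaled against
  its own mean disc-SD, measured on 128 seeded discs sampled inside the
  parenchyma, so that noise *as the ROI pipeline measures it* hits the
  target.
* **Texture compensation.** The target for the added field is
  sqrt(sigma(D)^2 - s_truth^2), where s_truth is the truth volume's own
  parenchyma disc-scale SD, so the *output's* measured SD equals
  sigma(D).  (With the default flat parenchyma s_truth is ~0; the term
  matters when a textured background is configured.)

The 0.6 mm correlation length was chosen so the simulated inter-ROI
scatter of measured noise (~13-15% of the mean) matches the scatter the
calibration data report (roughly 15-20%); a 1 mm kernel produces ~27%,
visibly too wide.  No autocorrelation measurements exist to constrain the
kernel shape itself; Gaussian is a modeling choice, and sinogram-domain
physics (beam hardening, scatter, spectral response) is out of scope.

Determinism: every stochastic step derives its generator from the study's
base seed hashed with (scanner, dose, repetition, phantom, purpose)
through `numpy` `SeedSequence`, so any volume can be regenerated in
isolation and the full study is bit-reproducible.

## The study grid

The default grid is 2 scanners x 5 doses (20.4, 9.8, 4.9, 2.4, 1.6 mGy) x
3 repetitions over the 6 lesions = 180 lesion-measurement instances.
Truth volumes (one per scanner x phantom) are reused across doses and
repetitions, as in a repeated physical scan of one object.

## ROI reading

Thirteen 8 mm ROIs per slice on three non-overlapping central slices
(mid-plane and ±4 mm): one inside each of the six lesions, one in the
parenchyma adjacent to each lesion (constrained to the lesion's sector),
and one in the water ring (placed on the phantom-1 scan, so the pair of
phantoms carries exactly 13 per slice).  "Manual placement in homogeneous
regions" is operationalized deterministically as the interior point
maximizing the 2D distance to the region boundary (ties broken by grid
order); for part-solid lesions the homogeneous region is the shell.  A
region too shallow for an 8 mm disc shrinks the ROI with a warning, never
below 4 mm.  ROI voxels are those whose centers fall inside the disc on
the single slice; mean uses all voxels, SD uses n-1.

From the per-ROI means and SDs: pooled per-material statistics (mean of
ROI means; SE = population SD of ROI means / sqrt(n)), image noise (SD of
parenchyma ROIs), CNR_k = (mu_k - mu_BG,k)/sigma_k with the lesion ROI's
own SD in the denominator (signed; reports take magnitudes), coefficient
of variation |SD/mean| of per-dose pooled means, and percent differences
100*(ref - comp)/ref.  The cross-scanner CNR increase "over all six
lesions" is computed as mean of per-lesion mean |CNR|, then the percent
change of the scanner means; the alternative (percent change per lesion,
then averaged) is available by composing the table functions directly.

## Radiomics

107 features per lesion instance: 18 first-order, 14 shape, 24 GLCM, 16
GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM, following the harmonized (IBSI-style)
formula conventions in common use.  Intensities are discretized with a
fixed 25 HU bin width anchored at the in-mask minimum (a global HU shift
leaves texture levels unchanged); gray levels in formulas are 1-based bin
labels.  Texture matrices use distance-1 neighborhoods: the 13 unique 3D
offsets for GLCM (symmetrized) and GLRLM, 26-connectivity for GLSZM
zones, GLDM dependence (|level difference| <= 0; dependence size = count
+ 1 including the center) and NGTDM neighborhood averages.  Directional
families compute features per direction and average.  Shape features
triangulate the 0.5 iso-surface of the mask after one voxel of Gaussian
smoothing — meshing the raw binary mask overestimates surface area by
~8% (staircase facets), while the smoothed mesh recovers an analytic
sphere's area and volume to ~1% — and axis lengths are 4*sqrt(lambda) of
the physical-coordinate second-moment eigenvalues.  No resampling,
filtering, or 2D modes.  Degenerate inputs take defined limits (GLCM
maximum probability 1 and zero entropies at a single gray level; NGTDM
coarseness capped at 1e6; single-voxel masks use voxel-based shape
fallbacks) and warn.

Every matrix builder is checked in the test suite against exhaustive
pure-Python enumeration on random small grids, and the scalar statistics
against independent brute-force recomputation.

## Cluster analysis

Features are z-score standardized (without standardization the 95%
variance rule is dominated by energy-like features spanning orders of
magnitude; a flag disables it), PCA is fitted jointly on both scanners'
180 instances, and the smallest component count reaching 95% cumulative
variance is retained (6-7 on default runs).  Component signs follow a
deterministic convention (largest-magnitude loading positive).  In the
retained space, with lesion-type clusters (sizes, doses, repetitions
pooled): within-cluster distance is the mean (± SD) Euclidean distance to
the cluster centroid, computed per scanner on that scanner's points in the
joint space; separability is the mean of the three pairwise centroid
distances divided by the mean within-cluster distance, centroid pairs
equally weighted and no whitening of retained components.  Separability is
invariant to rotation, translation and uniform scaling of the cloud.

## Statistics

Two-group comparisons are paired by (ROI location, slice, repetition)
across scanners at matched dose.  The paired differences pass through a
Lilliefors gate at alpha = 0.05: the Kolmogorov-Smirnov statistic against
a normal with estimated mean/SD, with the p-value from a seeded
Monte-Carlo null table (10,000 sorted-normal resamples per sample size,
cached; the statistic is location-scale free so one table per n is exact).
Normal-looking differences get a two-tailed paired t-test; otherwise the
two-sided Wilcoxon signed-rank (exact for n <= 25, normal approximation
with continuity correction above; zero differences dropped).  All-zero
differences return p = 1 by convention; constant nonzero differences
(zero-variance t) route to an exact sign test.  Three-or-more group
comparisons (HU across doses) use one-way ANOVA.  Everything is decided at
the 5% level with no multiplicity correction.  The unpaired Mann-Whitney U
is available as an explicit alternative entry point.

## Synthetic data: what it does and does not emulate

The generator reproduces the study's *design and calibration*: grid
geometry, lesion sizes and mean intensities, per-material HU, per-dose
noise magnitude and its inter-ROI scatter, repetition structure, and
ground-truth masks in place of manual segmentation.  It does not emulate
anatomical background structure (vessels, bronchi), reconstruction-kernel
correlation structure, beam hardening or scatter artifacts, partial-volume
blur at lesion boundaries (edges are sharp), segmentation variability, or
detector-specific spectral effects.  Tests passing on this study therefore
validate the *pipeline* — calibration closure, metric definitions,
deterministic reproduction of the published worked-example arithmetic and
directional findings — not the claim that real-scanner radiomics values
would be numerically reproduced.  Absolute texture-feature values and
separability magnitudes in particular depend on texture/noise structure
the real systems do not share with the simulator.

## Problem sizes and numerical choices

Default runs use the full 512 x 512 in-plane grid and the complete
180-instance design; the library streams one volume at a time, so peak
memory stays near a single 512 x 512 x 40 float32 volume and a full run
(generation, ROI reading, radiomics, clustering, statistics) completes in
a few minutes on one CPU.  The test suite runs the same full design once
per session and reuses it across checks.  Tolerances asserted in tests
reflect sampling variability at the design's own size (e.g. noise
recovery within 5% over 54 ROIs, pooled HU within 3 HU over 270 ROIs).
Ties in ROI placement and PCA signs are broken deterministically; all
stochastic steps are seeded.

## Known limitations

* Image-domain noise injection cannot represent dose-dependent changes in
  noise *correlation* (only magnitude); NPS/MTF analysis is explicitly out
  of scope.
* The part-solid core/shell construction is one of many morphologies
  consistent with a printed mean intensity; radiomics values for
  part-solid lesions depend on it.
* With one lesion per size/type, lesion-level variance estimates pool
  across sizes exactly as the original design does — six objects, not a
  population sample.
* The Lilliefors Monte-Carlo null uses 10,000 resamples; p-values carry
  ~0.2% resolution near the 5% threshold.
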
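# Methods

## Scope and design

`floodscore` analyses per-plot rasters: each breeding plot is one
region of interest with a 5-band reflectance stack, a thermal raster in
°C, and (for synthetic data) ground-truth canopy masks on both sensor
grids. Orthomosaic stitching, GPS/EXIF handling and interactive ROI
cropping are out of scope; the plot raster is the unit of analysis.
Image rows run along the planted row (the "length" direction), columns
across it; indices are 0-based with the origin at top left.

## Synthetic field generator

The generator emulates a flooded soybean nursery of `n_plots = 724`
single-row plots scored 1–5 (FIS). Class composition uses fixed counts —
largest-remainder rounding of the proportions
`(0.18, 0.27, 0.27, 0.18, 0.10)` — with a seeded permutation assigning
scores to plots. A scored field has one definite injury histogram;
fixed counts reproduce that design exactly for every seed, so
field-level recovery checks are not confounded by class-composition
sampling noise.

**Canopy geometry.** Each canopy is a superellipse (exponent 2.5,
length:width aspect 3.6) in physical coordinates, with a per-plot
4-harmonic Fourier perturbation of the outline (relative s.d. 0.04) so
that boundaries are irregular and mixed pixels appear on downsampling.
Defining the outline in metres makes the multispectral and thermal
grids see the same plant despite their different ground sampling
distances (GSDs). The occupied area fraction of the plot ROI decreases
with injury: 0.58 / 0.50 / 0.42 / 0.33 / 0.22 for FIS 1–5, with a
multiplicative per-plot jitter (s.d. 7%).

**Radiometry.** Canopy pixels carry an NDVI value
n = n_FIS + plot effect (s.d. 0.02) + pixel noise (s.d. 0.04), from
which red and NIR reflectance are set exactly as
R = (1 − n)s/2, NIR = (1 + n)s/2 with band sum s = 0.50; blue, green
and red-edge are fixed means (0.05 / 0.16 / 0.26) plus noise
(s.d. 0.012). The FIS→NDVI map is linear,
n_FIS = 0.51 − 0.055·(FIS − 2.75), centred so the class mixture under
the default proportions has a grand mean of exactly 0.51 at 20 m.
Background pixels are soil (82%), shadow (10%) and dark plant residue
(8%): the soil spectrum is brown with NDVI ≈ 0.10 and multiplicative
brightness jitter; shadow is soil scaled by 0.15; residue is a dark
brown spectrum. These three sub-classes are what give the stepwise
segmentation distinct jobs per step.

**Thermal.** Canopy pixel temperature is
T_FIS + plot effect (s.d. 0.5 °C) + pixel noise (s.d. 0.7 °C) with the
linear map T_FIS = 39.0 + 1.1·(FIS − 2.75) °C, mixture-centred on
39.0 °C; in-plot background is 49.4 °C (plot s.d. 0.6, pixel s.d.
1.0 °C). Separate pure bare-soil sample regions average 52.3 °C. The
~10 °C canopy–background gap against sub-1 °C noise is what makes the
two-cluster K-means segmentation essentially exact at 20 m.

**Flight height.** A 50 or 80 m scene is derived from the 20 m scene by

1. exact area-average downsampling by the GSD ratio (multispectral
   13.2 → 34.7 → 55.6 mm/px; thermal 23.4 → 68.0 → 108.8 mm/px),
   implemented via the integral image — the integral of a
   piecewise-constant raster is piecewise bilinear, so linear
   interpolation at fractional box corners gives the exact footprint
   mean;
2. a Gaussian thermal point-spread blur (σ = 1.3 output pixels),
   modelling the low optical MTF of a microbolometer: once a canopy is
   only a few pixels wide, hot background bleeds into its interior;
3. thermal attenuation T_obs = τ·T + (1 − τ)·T_ambient with ambient
   33.4 °C and τ(20/50/80) = 1.0 / 0.9259 / 0.7989. The τ values are
   solved, not physical: they place apparent bare-soil temperature at
   52.3 / 50.9 / 48.5 °C. The PSF width is likewise calibrated so the
   extracted canopy temperature *rises* with height (≈39.0 → 40.4 →
   40.7 °C) while soil falls — the observed, seemingly contradictory
   height pattern that a resolution-plus-attenuation model must
   reproduce: mixing folds hot soil into the cool cluster faster than
   attenuation cools it.

Truth masks are downsampled by strict majority vote (area fraction
> 0.5; an exact tie counts as background).

**Raw captures.** The forward model per band b is
DN = round(clip(R · I_b · g_b · x_b · 65535, 0, 65535)) with scene
illumination I, sensor gain g and exposure x (all positive; defaults
chosen so I·g·x ≤ 1 and clipping never fires on in-range reflectance).
The vignette is flat: no spatial profile is modelled, so calibration is
a single per-band scale. The calibration-reflectance-panel capture is
rendered with the same model from known panel reflectances
(0.48–0.52). An optional `corner_light_drop` flag renders a trailing
fraction of plots under a global exposure drop, emulating a sudden
light change over one field corner; it is off by default.

## Radiometric calibration

`dn_to_radiance` inverts the sensor part of the forward model:
radiance = DN/(g·x·65535), in model units. The *unified-factor* method
averages the panel radiance over a central 50% crop, forms
factor_b = known reflectance / panel radiance, and multiplies; on model
data this recovers reflectance to within the two propagated
quantization steps (pixel DN and panel DN), and it is exposure-
invariant as long as each capture carries its own panel. The *max-min*
method is DN/65535: monotone, scale-free, not exposure-invariant — its
role is robustness when auto-exposure already compensates global light
changes, at the price of absolute calibration. Out-of-range results are
clipped to [0, 1] with a logged count.

## Segmentation

The multispectral procedure removes background in four ordered steps,
each a box in a colour space; a pixel inside a box is removed, so the
mask can only shrink:

1. YCbCr box on the (red, NIR, red-edge) false-colour composite — the
   soil bulk. Vegetation has NIR ≫ red, pushing Cr far below soil's.
2. YCbCr box on the (red, green, blue) true-colour composite — residual
   soil near the canopy.
3. HSV box (V ≤ 0.10) — dark pixels: shadow and residue.
4. 8-connected components smaller than 1% of the image are removed as
   noise (strict `<`: a component of exactly the threshold size
   survives).

The interactive freehand thresholds such a workflow normally relies on
are not reproducible, so the shipped boxes are fixed numbers tuned once
on a frozen fixture field (default configuration, seed 0) and never
revisited: reproducibility is preferred over fidelity to unrecorded
values. On noise-free scenes the mask equals the generator truth
exactly; at default noise the mask-vs-truth Jaccard exceeds 0.95 on
well over 95% of plots. CIE Lab conversion is provided to complete the
colour-space menu but unused by the default procedure.

Thermal masks come from 1-D K-means (k = 2, k-means++ with fixed seed,
≤ 300 iterations, tolerance 1e-6) on temperature values only — not
pixel coordinates — with the canopy taken as the cluster with the lower
mean, making the output invariant to label permutation. A constant
raster is an error (no canopy/background separation exists).

## Features

Per plot and height: canopy temperature = arithmetic mean of thermal
values under the thermal mask; NDVI = (NIR − R)/(NIR + R) per pixel
(undefined where NIR + R = 0 and excluded), averaged under the
multispectral mask; area = true-pixel count; length/width = number of
occupied image rows/columns of the mask. "Occupied extent" is used
rather than crop-box dimensions because hand-drawn crop boxes are not
recoverable; the two conventions coincide on tightly cropped plots.
Features stay in pixel units per sensor grid (no cross-sensor
resampling); a px→cm helper exists but the classifier does not use it.
Plots with an empty mask are flagged invalid and excluded from
modelling, as dead or poorly germinated plots would be.

## Group statistics

One-way ANOVA (F = MSB/MSW with (k−1, N−k) df) with the convention
F = 0, p = 1 when all observations are identical; Tukey HSD adjusted
p-values from the studentized range; compact letter display via the
insert–absorb algorithm, ordering groups by descending mean (ties by
label) so the highest mean always carries "a". α defaults to 0.05.
Height comparisons treat the three heights as independent groups, not
paired samples.

## Network training

Architecture 5–10–1: tanh hidden layer, linear output, 71 parameters.
Inputs are scaled per feature from the training min/max to [−1, 1]
(constant features map to 0); targets are the scores 1–5 as reals, so
training is least-squares regression and the continuous output is
binned afterwards — the categorization table exists precisely to
discretize a continuous prediction, and the raw output supports ranked
selection of tolerant plots (ceil(fraction·n) lowest outputs, ties by
plot id).

Levenberg–Marquardt: per epoch, the analytic Jacobian J of the outputs
w.r.t. all 71 parameters is built and (JᵀJ + μI)Δ = Jᵀr is solved
(Cholesky; μ escalation on numerical failure). A step that lowers the
training MSE is accepted and μ ← 0.1μ; otherwise μ ← 10μ and the epoch
retries, stopping when μ > 1e10. Defaults: 1000 epochs maximum,
performance goal 0, gradient-norm floor 1e-7, μ₀ = 1e-3, and early
stopping after 6 consecutive epochs without validation improvement,
restoring the best-validation weights. Initial weights are uniform in
[−0.5, 0.5] from the run seed — a deliberate simplification over
Nguyen–Widrow initialisation; LM converges in tens of epochs here
either way. Data are split 90/10 train/test (test size = floor(0.10·n),
so 724 → 72) with a validation carve-out of floor(0.10 · remaining)
taken from the training partition; the split, initialisation and
training are deterministic given the seed.

Binning: [0,1.5)→1, unit bins to [4.5,∞)→5; negative raw outputs
(possible from a linear neuron) clip to level 1, the only consistent
extension of a table that starts at 0. Accuracy is percent correct on
the test set; confusion tables are 5×5 predicted×observed counts.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis
relies on — class-ordered temperature/NDVI/area, cool canopy vs hot
soil, height-driven resolution loss, exposure effects — but not real
field data: no within-canopy texture or gaps, no row overlap between
neighbouring plots, no soil moisture gradients, no wind-driven thermal
drift, no genotype or replicate structure, and class-conditional
distributions are cleaner than visual scoring noise would make them.
Synthetic test accuracy (~97% at 20 m) therefore demonstrates that the
pipeline is correct and that the feature set separates ordered injury
classes under realistic degradation; it is not a claim about accuracy
on a real nursery. Likewise the NDVI height decline here (≈0.51 → 0.50
→ 0.49) is milder than a real mission would show, since illumination
drift and inter-image exposure variation are off by default.

## Numerical choices and degenerate inputs

- Area downsampling is exact (integral image), not interpolation-based;
  grand means are preserved to machine precision.
- Majority-vote ties (fraction exactly 0.5) go to background.
- Segmentation uses 8-connectivity; the 1% area rule removes with
  strict `<`.
- K-means requires ≥ 2 distinct values; empty masks propagate as
  invalid records rather than NaN contagion.
- Reflectance is stored float32, thermal float32; comparisons in tests
  allow for that precision.
- Seeds everywhere derive from `numpy.random.SeedSequence([seed, tag])`
  so stages are independently reproducible.

## Problem sizes in the test suite

Unit and property tests run on toy rasters and 15–60-plot fields;
field-level recovery and classification checks use the full default
724-plot field at 20 m, and the height-degradation ordering check runs
the default field at all three heights over five seeds. The whole suite
completes in about two minutes on one CPU; the acceptance script in
under one.

## Known limitations

- The radiance scale is a model unit, not W/m²/nm/sr; absolute
  radiometry is out of scope, only the algebraic structure of
  panel-based calibration is preserved (flat vignette, no dark current).
- Threshold boxes are tuned to the synthetic colour distributions;
  real imagery would need re-tuning (the `ThresholdSet` is a plain
  dataclass and the CLI accepts a YAML override).
- The attenuation/PSF constants are calibrated to reproduce observed
  height patterns, not derived from atmospheric physics.
- Per-height models are trained independently; no transfer across
  heights is attempted.
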
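# Methods

`peritomorph` implements an automated quantitative histomorphometry pipeline
for the peritoneal membrane — microvessel density and morphometry on
dual-stained (CD31 / podoplanin) sections, submesothelial layer structure,
mast-cell counting, mesothelial integrity, and LMS age-reference centile
curves — together with a synthetic tissue generator that provides ground
truth for closed-loop validation.  This note records the model assumptions,
the parameters that matter, and the design choices made where the design was
genuinely open.

## The synthetic tissue model

Real inputs to this kind of analysis are whole-slide scans of stained
sections.  No public specimen set exists for the healthy peritoneum, so the
generator emulates sections whose *statistics* match the published cohort:

* **Geometry.** The mesothelial surface lies along the top image row; depth
  is vertical distance in μm (0-based, row-major pixels).  The canvas holds
  a ~4 μm mesothelial band, the submesothelial zone, and a band of
  lower-boundary tissue (fat/muscle/fascia, 40 μm by default).  The image
  width is chosen so that the canvas area equals the requested analyzed
  area (default 1.44 mm², the published median analyzed area per section).
* **Pixel scale** defaults to 0.25 μm/px, matching a 40× whole-slide scan.
  This is deliberate: endothelial walls are 1–2 μm (4–8 px), so the default
  reproduces the discretization error a real scan would carry.
* **Vessels** are a Poisson point process: counts are Poisson(density ×
  area) per class (blood, lymphatic), horizontal positions uniform, depths
  drawn from a three-component normal mixture — the three submesothelial
  vessel layers, medians 36/96/192 μm with IQR-scale dispersions 20/65/133
  μm — truncated to the submesothelium.  Published dispersions are reported
  as median/IQR only; they are converted to normal-equivalent sigmas by
  σ = IQR/1.349.  Cross-sections are annuli: outer radius from a truncated
  normal (mean 4.5 μm, sd 0.8 μm, floor 2.5 μm), wall thickness lognormal
  around the group median (median-preserving jitter, σ_log = 0.15).  A
  configurable fraction (default 0.10; not reported in reference cohorts)
  is *collapsed*: rendered as filled discs without a lumen.  Overlapping
  placements are re-sampled up to 100 times so objects stay separable; the
  segmenter's merge handling is tested separately with constructed inputs.
* **Vessel depth floor.** Depths are truncated below at 20 μm + radius so
  no cross-section intrudes into the mesothelial zone.  This mirrors the
  anatomy (the shallowest vessel layer sits ~36 μm deep) and keeps the
  podoplanin surface-mask from clipping lymphatic vessels.
* **Stain channels.** CD31 marks every vessel; podoplanin marks lymphatic
  vessels plus the mesothelial band; tryptase marks mast cells (discs of
  radius 2.5 μm at 12.9 cells/mm² by default).  Positive objects are drawn
  at intensity 0.8 on a 0.1 background with additive Gaussian noise
  (sd 0.05), clipped to [0, 1].  The structural channel is a noise-free
  label map (mesothelium / submesothelium / lower boundary).
* **Mesothelial integrity.** One contiguous denuded stretch of the surface
  is removed at a random position with total length `denuded_fraction` ×
  width (default 0.21, the published denuded proportion).
* **Submesothelial boundary.** The lower boundary undulates sinusoidally
  with relative amplitude 0.08 (random phase and 1–3 cycles), around the
  group's true thickness; the sinusoid has zero median, so the
  median-of-transects measurement is unbiased.
* **Cohorts.** The default seven-group design (ages <1 to 60 years, sizes
  14/10/15/15/18/21/14) carries the published group medians for densities,
  wall thickness and thickness.  Submesothelial thickness is only published
  for three groups (230/402/173 μm); intermediate groups are monotone
  interpolations.  Per-patient parameters get median-preserving lognormal
  variation scaled from the published IQRs, and each patient's layer depths
  are coupled to their submesothelial thickness (proportional scaling with
  lognormal noise, σ_log = 0.5, calibrated by simulation so that the
  depth-thickness Spearman correlation lands in the published 0.57–0.60
  band).

What the generator does **not** emulate: color chemistry (no DAB/HE
rendering or color deconvolution; one channel per stain), tissue folds,
scanner artifacts, vessel shapes other than circular cross-sections, or
object-level correspondence between the "adjacent" CD31 and podoplanin
sections.  Consequently, passing tests demonstrate that the measurement
definitions and the pipeline plumbing are correct and unbiased under the
stated noise model — not that segmentation would survive real staining
variability.

## Measurement definitions

* **Pixel classification**: intensity binning into negative/weak/medium/
  strong with strictly increasing per-stain thresholds (defaults 0.3/0.5/
  0.7, calibrated to the generator's intensity model and exposed in
  configuration).  **Positivity** = positive pixels / all analyzed pixels;
  the denominator is the analyzed tissue region, not the whole canvas.
* **Vessel detection**: 8-connected positive components ≥ 12 μm²
  (the smallest reported capillary medians are ~48 μm²); the lumen is
  recovered by hole-filling, with holes below 4 px² treated as no distinct
  lumen (collapsed).  Rings containing several distinct lumina are split by
  one round of watershed on the distance transform, seeded from the lumina;
  merges without distinct lumina stay single and are logged.  Components
  touching the image border are counted for density but excluded from shape
  metrics.  On podoplanin sections a 15 μm surface margin is masked first,
  removing the mesothelial band the stain also marks.
* **Morphometry**: vessel area = endothelial + lumen area (exact on label
  masks); endothelial thickness = endothelial area / mean ring length,
  which reduces to r_out − r_in for a perfect annulus; perimeters use the
  Crofton estimator (4 directions) because naive pixel-edge counting
  overestimates circle perimeters by ~27% and weighted step counting still
  carries a few percent bias at these radii.  Endothelial surface per
  volume = Σ endoluminal perimeter / analyzed area; the section thickness
  cancels algebraically and never enters numerically.  Relative endothelial
  area includes collapsed vessels (they are endothelium without a lumen);
  per-sample summaries are medians over non-collapsed, non-border records.
* **Dual-stain differencing**: per sample, total = CD31 count, lymphatic =
  podoplanin count, blood = max(total − lymphatic, 0), with clamping
  logged.  No object-level registration between adjacent sections is
  assumed; CD31 shape metrics are reported under the blood class since
  blood capillaries dominate that channel.
* **Submesothelial thickness**: median of ≥ 5 (default 7) evenly spaced
  perpendicular transects with 5% lateral margins.
* **Layer clustering**: see below.
* **Cohort statistics**: Shapiro–Wilk per group at α = 0.05 decides ANOVA
  vs Kruskal–Wallis (graphical normality checks have no computational
  analogue, so the test decides alone, logged per group); chi-square with
  Fisher's exact fallback for 2×2 tables with low expected counts; Pearson
  vs Spearman chosen from marginal normality.  No multiple-testing
  correction is applied, matching the reporting convention the pipeline
  reproduces.

## Depth clustering: why a constrained mixture

Within one sample the three vessel layers are visually distinct, but their
*pooled* depth distribution across a cohort overlaps heavily: the printed
between-sample dispersions (IQR 65 and 133 μm for the deeper layers) exceed
the distances between layers.  Prototyping showed that every hard-partition
estimator — k-medians with nearest-median assignment, the optimal 1-D
L1/L2 partitions, and MAP assignment from a free-weight Gaussian mixture —
places the middle-layer median near 125 μm when the true component median
is 96 μm, because the wide third component bleeds into the middle segment.
An equal-weight-constrained Gaussian EM (quantile initialization,
deterministic) keeps the components identifiable and recovers the middle
component median nearly unbiased (≈ +3%).  The constraint encodes the
generator's (and the anatomy's) roughly equal layer populations.  The
default therefore reports component medians from the constrained mixture;
`method="kmedians"` retains the hard partitioner, which is exact on
well-separated depths, and `method="gmm"` frees the weights.  Vessels whose
maximum posterior falls below 0.5 are still assigned (every vessel belongs
to exactly one layer) but their fraction is reported as `unassigned_fraction`.

A single 300-depth draw from the published mixture carries ~9% intrinsic
standard error on the middle-layer estimate (the overlap limits the Fisher
information), so the layer-recovery experiment pools 25 independent draws
and reports the median — analogous to the >100 samples pooled in a real
cohort — reducing Monte Carlo error to ~3%.

## LMS reference curves

L(t), M(t), S(t) are modeled on t = log(age + 0.25 y) — the offset gives
infancy, where the curves move fastest, the resolution it needs — as
orthogonal-polynomial smooths with the conventional degrees-of-freedom
defaults L:2, M:4, S:3 (configurable).  Coefficients maximize the
Box–Cox–Cole–Green likelihood via L-BFGS-B, started from both L = 1 and
L = 0 (the better optimum wins); M and S are parameterized on the log scale
to stay positive.  The z-score uses the log branch for |L| < 1e-7, which
keeps the transform continuous in L at 0 to well below 1e-6.  Centile
tables report the 3rd/10th/25th/50th/75th/90th/97th centiles.  Known-truth
simulations validate the fit (median recovery, z-score calibration by KS,
centile coverage); note that the Box–Cox power is weakly identified at
realistic sample sizes (SE ≈ 0.4 at n = 500, CV 0.2), which is a property
of the method, not of this implementation.

## Numerical choices and degenerate inputs

* Rasterization includes a pixel when its center lies inside the annulus;
  mask area converges to π(r_out² − r_in²) as the pixel scale shrinks
  (≤ ~1% error at 0.25 μm/px for default radii).  Sub-pixel objects emit a
  degenerate-mask warning.
* Sections too small to hold one vessel warn and return an empty truth.
* Identical groups in a comparison yield a NaN test statistic upstream;
  this carries no evidence against the null and is reported as p = 1.
* Fewer depths than layers reduces k with a warning; all-equal depths give
  a degenerate single layer.
* All randomness flows through `numpy.random.Generator` seeded per run;
  cohort patients use spawned `SeedSequence` children, so outputs are
  byte-identical across reruns of the same seed and insensitive to the
  number of channels requested.

## Problem sizes of the validation experiments

The recovery experiments mirror the corresponding study designs: 14 samples
of 1.44 mm² at 0.25 μm/px for the infant density and relative-area
experiments, ≥ 200 rendered rings for wall thickness, 15 structural
sections for thickness transects, 30 tryptase sections for mast cells, and
10 sections of 0.5 mm² for the high-density omental regime (the smaller
area still yields > 200 vessels per section at 434/mm²).  Unit tests use
0.01–0.5 mm² sections, which hold enough vessels to exercise every code
path while keeping the suite fast.

## Known limitations

* Blood/lymphatic classification is count-level only; per-object class is
  unknowable without registration, exactly as in the slide-based workflow.
* The generator's vessel-size distribution is calibrated only so that
  median per-vessel metrics are plausible; published tables are internally
  inconsistent about per-vessel areas vs aggregate endothelial percentages
  (median area × density ≈ 1.2% vs a printed 5.8% for infants), so the
  relative-area experiment calibrates the generator to the aggregate
  percentage directly rather than asserting a reconciliation.
* Omental sections are ordinary sections with their own parameter regime;
  arteriolar (EVG tunica-media) morphometry is out of scope.
* Nerve fibers accompany the vessel layers in real tissue but are not
  segmented; mesothelial protein-expression panels beyond the integrity
  measure are out of scope.
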
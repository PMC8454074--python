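# Methods

This note documents the models behind `bbbarray`, the parameter choices
that matter, what the synthetic generator does and does not emulate, and
the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Forward transport model

The expected tracer level in the organoid core under a condition is

* excluded tracers (FITC-dextrans, non-targeting IgG, species-mismatched
  shuttle): `I = B`, the autofluorescence baseline;
* paracellular tracers (free FITC; any tracer when no endothelial cells
  are present): `I = B + L`, a constant leak amplitude;
* receptor-targeted shuttles: `I(t, dose) = B + α · dose · (1 − e^{−kt})`,
  one-phase association in time, linear in dose.

The one-phase association form is the package's modelling choice for
receptor-mediated accumulation: it is the standard saturating first-order
kinetic, it is identifiable from the six sampling times used in the assays,
and its plateau timing (`t95 = ln 20 / k ≈ 60 min` at the default
`k = 0.05 /min`) matches the observed behaviour of shuttle accumulation.
Dose response is linear (no receptor-saturation term): within the dose
ranges screened, the assays are operated in the linear regime.

Default intensity scale: `B = 10 AU`; `α = 1 AU/nM`, so a 100 nM reference
dose contributes 100 AU at plateau; leak amplitude 60 AU for free FITC and
80 AU for barrier-free (no-BEC) organoids; per-organoid multiplicative
variability with relative SD 0.1. These four numbers define the study
conditions used throughout the tests; they are amplitudes on an arbitrary
fluorescence scale and only their ratios matter.

## Synthetic image generator

**Geometry.** Organoids are oblate spheroids: mounting flattens them
axially by a factor 0.5 (the magnitude is a convention; only the presence
of flattening matters for the depth geometry). Diameters follow a normal
distribution with mean 235 µm and SD 25 µm truncated at ±3 SD — chosen so
simulated experiments land inside the 220–250 µm mean band and the
23–27 µm intra-experiment SD band expected of microwell arrays. The
endothelial layer is a 6 µm shell (a single squamous cell layer);
everything inside it is the interior where transported tracer distributes.

**Brightfield arrays.** Microwells (600 µm cavities) sit on a 700 µm
pitch; organoids are dark disks at half the background level with a thin
bright halo, anti-aliased over ~1.5 px, on a background with a gentle
illumination gradient and per-well vignetting. Pixel size 2 µm (a 4×
objective scale).

**Confocal stacks.** Three channels: nuclei (diffuse cytoplasmic haze over
the cross-section plus ~1000 nuclear blobs), endothelial marker (the
shell; empty for no-BEC controls) and tracer (exterior ≈ 0, rim signal in
the shell, core signal at the forward-model level). Structures above the
imaged depth are not rendered — a confocal stack samples only the bottom
~36 µm of the flattened organoid, which fully contains the 25–28.5 µm core
window. Optics: isotropic Gaussian blur of 1 µm in xy with a 2× wider z
kernel. Noise: Poisson shot noise with configurable gain plus Gaussian read
noise, simulated exactly where expected counts are below 25 and by the
variance-matched normal approximation above (the standard mixed
Poisson–Gaussian scheme). Default voxel size is 1.6 µm in xy with a 1 µm
z-step on a 36×224×224 grid, which holds the largest organoid the
morphology model can produce; finer samplings are configuration options.

**Puncta.** Receptor-mediated core signal is split 50/50 between a diffuse
component and point-like puncta (endosomal appearance), at a default
density of 0.05 puncta/µm³ (~100 vesicles per cell) with per-spot amplitude
normalized so the *volume* mean of the interior equals the forward-model
level exactly.

**Per-organoid variability.** One multiplicative factor per organoid
(relative SD 0.1) scales the whole tracer field — autofluorescence,
surface binding and transported signal all vary organoid-to-organoid —
matching the measurement-level simulator used for kinetics
(`value = I · (1 + 0.1 Z)`).

**What the generator does not emulate.** Vendor PSFs, spectral bleed,
depth-dependent attenuation, cell-scale biology (individual astrocytes or
pericytes), organoid shape irregularity, and mounting artefacts. Passing
tests therefore demonstrate the *analysis* chain is correct and calibrated
on images with realistic geometry and noise — not that segmentation is
robust to every real-world artefact.

## Measurement chain conventions

* **Depth reference:** the core window is measured from the detected
  *bottom* slice (lowest slice whose foreground area exceeds 10% of the
  per-slice maximum, global Otsu on the smoothed reference channel). The
  endothelial channel is preferred for bottom finding, with automatic
  fallback to nuclei (no-BEC controls).
* **Segmentation channel:** the nuclei MIP — present in every experiment
  including no-BEC controls.
* **Core ROI:** distance-transform erosion, choosing the distance level
  whose kept-area fraction is closest to the target (0.75); concentric and
  shape-following by construction. The achieved fraction is always
  reported; masks that cannot realize the target within ±5 points are
  rejected. An alternative (scaled-contour shrinking) would give a
  non-concentric ROI for irregular masks and is not implemented.
* **No background subtraction:** core means are raw; background is
  assessed via non-treated control organoids in the same statistical
  comparison.
* **MIP bias:** the maximum-intensity projection of noisy or punctate
  voxels is upward-biased (a max over fluctuating samples). This is a
  property of the projection itself, shared with the physical assay; it
  shifts all conditions of an experiment coherently and cancels in group
  comparisons. Truth-recovery tests therefore validate the absolute scale
  on noise-free diffuse renders (accurate to <1%), while noisy punctate
  renders are validated through the group-decision patterns.
* **Coordinates:** 0-based pixels, half-open ROI intervals, z index 0 at
  the coverslip-proximal slice.

## Brightfield segmentation recipe

Median smooth (3 px) → divide by a large-kernel Gaussian illumination
estimate (σ = 400 µm, computed on a decimated copy) → Otsu threshold on
the inverted normalized image → fill holes → connected components →
per-object QC: equivalent diameter within [50, 450] µm, circularity
(4πA/P², Crofton perimeter) ≥ 0.6, not border-touching. QC-flagged objects
are excluded from statistics but reported. Division-based normalization
makes detection invariant to additive and multiplicative illumination
changes; the threshold sits at the half-depth of the disk edge, making the
area-equivalent diameter unbiased to <1% over 100–400 µm (verified against
simulator truth).

Size-homogeneity conventions: SD is the sample SD (n−1); the
cross-experiment reproducibility metric is
`100 · (max experiment mean − min experiment mean) / mean of experiment
means`, an explicit convention for "diameter varied by X%" statements.

## Fitting

One-phase association is fitted by bounded least squares on per-organoid
points (not per-time means): initialization B₀ = smallest per-time mean,
A₀ = range of per-time means, k₀ = 1/median(t); k bounded to
(10⁻⁵, 10] /min with three fixed multistart perturbations of k₀. Parameter
covariance is `s² (JᵀJ)⁻¹`. Constant responses raise "amplitude
unidentifiable"; a rate pinned at its bound is reported as a failure, not
an estimate. Dose–response lines are ordinary least squares; with exactly
two points the line interpolates with zero residual degrees of freedom and
no confidence band exists.

Confidence bands are **pointwise** delta-method bands: variance
`g(x) Σ g(x)ᵀ` with `g` the parameter gradient of the curve, half-width a
two-sided t-quantile at the residual degrees of freedom. They are not
simultaneous bands; simulated coverage at a fixed time is ~95% (verified
at 400 replicates).

## Statistics

* **ANOVA + Dunnett:** omnibus one-way F; per-comparison adjusted p from
  the many-to-one multivariate-t max-|t| distribution (seeded evaluation,
  reproducible). Verified in the tests against an independent 10⁶-draw
  Monte-Carlo max-|t| oracle (agreement < 0.005) and against the pooled
  two-sample t-test in the single-comparison case.
* **Friedman:** within-block average ranks,
  `χ²_F = [12/(nk(k+1)) ΣR_j² − 3n(k+1)] / C` with tie correction
  `C = 1 − Σ(t³−t)/(nk(k²−1))`; fully tied blocks give the degenerate
  statistic 0 with p = 1. Blocking unit: the independent experiment, using
  per-experiment condition means — organoids are not paired across
  conditions, so per-organoid blocking is not defined; this convention is
  a documented choice, not an inference about how any particular dataset
  was analysed. The χ² null is asymptotic in the number of blocks and
  conservative for very few blocks (simulated type-I ≈ 0.02 at 4 blocks
  vs ≈ 0.047 at 30 blocks, nominal 0.05); calibration tests therefore run
  at 30 blocks.
* **Kruskal–Wallis + Dunn:** tie-corrected H with χ² reference; Dunn
  pairwise z with tie-corrected rank variance and Bonferroni adjustment
  (configurable). Dunn's z is asymptotic: at n = 8 per group it deviates
  from an exact permutation null by a few percent in the high-p region.
* **Boxplots:** percentiles by linear interpolation between order
  statistics (numpy's "linear" convention), fixed and documented.

## Pipeline scales and runtime choices

Simulated assays default to the reference designs: permeability — 6
conditions × 50 organoids over 4 experiments; transcytosis — 4 constructs
× 60 organoids over 3 experiments; knockout — 4 lines × 2 tracers × 50
organoids over 3 experiments; size QC — 3 experiments × ≥300 organoids.
Construct, permeability and knockout measurements run every organoid
through the full image chain (render → bottom → window → MIP → segment →
ROI → measure). Time-course and dose–response fits consume
measurement-level simulations of per-organoid core means: the fitted
quantity *is* the measured core mean, so rendering each kinetic organoid
adds runtime without adding information; the construct comparison in the
same assay still exercises the imaging chain. A shared per-experiment
factor (relative SD 0.05) emulates day-to-day staining/illumination drift.

All randomness flows from `numpy.random.SeedSequence` children of a single
seed: identical configuration + seed reproduces byte-identical images and
CSV outputs. Output writes are atomic and refuse to overwrite without
`force`.

## Known limitations

* Absolute transport quantification is out of scope: readouts are relative
  fluorescence, and permeability coefficients cannot be derived from them.
* Merged/overlapping organoids are QC-rejected (circularity), not split.
* The generator's rim/leak amplitudes are plausible conventions; only the
  orderings they induce (shuttle ≫ baseline, leak > baseline) are
  load-bearing in the tests.
* Mechanistic multi-compartment transcytosis/efflux models are not fitted;
  the association model is a phenomenological summary.
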
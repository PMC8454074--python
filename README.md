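# bbbarray

Quantitative imaging and statistics for blood–brain-barrier (BBB) organoid
array assays.

BBB organoids are self-assembled spheroids of astrocytes (core), pericytes
(mid-layer) and brain endothelial cells (surface shell) grown by the
hundreds in hydrogel microwell arrays. They are used to screen which
antibodies cross the human BBB: a tracer is added to the medium, organoids
are fixed and imaged by confocal microscopy, and the fluorescence that
reached the organoid *core* — behind the endothelial barrier — is the
transport readout. `bbbarray` implements the complete analysis workflow for
these assays, plus a seeded synthetic-image generator so every stage can be
developed and validated without microscope data.

## What it computes

* **Size morphometry** (`bbbarray.arraymorph`) — segments organoids in
  stitched brightfield array images and reports per-experiment diameter
  statistics (mean, sample SD, CV) and cross-experiment reproducibility.
  Diameters are area-equivalent: `d = 2 sqrt(A/π)`.
* **Core-intensity quantification** (`bbbarray.corequant`) — the confocal
  measurement chain: find the organoid bottom, select the core window
  (default 25 µm above the bottom, 3.5 µm deep), maximum-intensity project,
  segment the cross-section, shrink the mask concentrically (distance
  transform) to 75% of its area, and measure the mean tracer intensity in
  that core ROI. Line profiles across organoids are included.
* **Transport kinetics** (`bbbarray.transport_fit`) — one-phase association
  fits `I(t) = B + A(1 − e^{−kt})` on per-organoid points, linear
  dose–response fits, pointwise 95% confidence bands (delta method,
  t-quantile), and steady-state timing `t_f = ln(1/(1−f))/k`.
* **Group statistics** (`bbbarray.groupstats`) — boxplot summaries (median,
  IQR, 5th/95th percentiles), one-way ANOVA + Dunnett's many-to-one test,
  the Friedman test for experiment-blocked designs, and Kruskal–Wallis +
  Dunn with tie correction. Decisions use adjusted p < 0.05.
* **Synthetic assays** (`bbbarray.simdata`) — a forward transport model
  (excluded tracers stay at baseline; paracellular tracers add a leak term;
  receptor-targeted shuttles accumulate with association kinetics) rendered
  into brightfield arrays and 3-channel confocal stacks with ground-truth
  tables; fully deterministic given a seed.
* **End-to-end assays** (`bbbarray.pipeline`, CLI `bbbarray`) — size QC,
  dextran permeability, transcytosis (constructs, time course, dose
  response) and endothelial knockout comparisons, with provenance.

## Worked example

`examples/04_transcytosis_kinetics.py` simulates per-organoid core
intensities of a transferrin-receptor shuttle (100 nM; 50 organoids at each
of 15, 30, 60, 120, 240, 360 min; 10% relative noise) and fits the
association model:

```
baseline  B =   4.11 AU
amplitude A = 104.61 AU
rate      k = 0.0523 /min
I(   30 min) =   87.0 AU, 95% band [  84.7,   89.2]
I(   60 min) =  104.2 AU, 95% band [ 102.7,  105.7]
I(  240 min) =  108.7 AU, 95% band [ 107.3,  110.2]
time to 95% of plateau: 57.2 min
```

The generator used B = 10 AU, A = 100 AU, k = 0.05/min, so the true
steady-state time is ln(20)/0.05 ≈ 59.9 min; the fit recovers the rate and
the plateau from noisy data and brackets the curve with a pointwise 95%
band. The other examples cover brightfield morphometry, single-stack core
quantification, the permeability assay and the statistics layer — each
prints what it computed and what the numbers mean.

A thin CLI wraps the same functions:

```bash
bbbarray simulate --kind brightfield --out demo --seed 1
bbbarray measure-array --image demo/array.tif --pixel-size 2.0 --out demo/morph
bbbarray run --config assay.yaml --out results/
```

## Layout

```
src/bbbarray/     library (simdata, arraymorph, corequant, transport_fit,
                  groupstats, pipeline, cli)
examples/         one narrative script per capability
tests/            pytest suite, including the acceptance checks
docs/methods.md   models, assumptions, parameter choices, limitations
```
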
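# Methods

## Scope and design

`synquant` implements the image-quantification side of a compartment-
targeting experiment: given multi-channel fluorescence images of synapses
(STED for the protein of interest and PSD-95, confocal for synapsin) or of
somata (NeuN, EGFP nucleus, HA), it measures where and how much of the
protein of interest is present, and compares conditions with nonparametric
statistics.  Raw experimental images are typically not public, so the
package ships a synthetic generator whose scenes carry exact ground truth;
all tests and the acceptance script run against it.

## Synthetic scenes

A synapse is parameterized by a center, an elongation-axis angle θ ∈ [0, π),
and three structures placed along the perpendicular (trans-synaptic) axis:

- **PSD bar** — a sharp rectangle, default 400 × 80 nm, amplitude 100 a.u.,
  centered at the synapse center.  Side view requires length > thickness.
- **channel band** — a 300 × 60 nm rectangle parallel to the PSD at a
  signed perpendicular offset (negative = presynaptic).  In the *targeted*
  regime offsets are drawn Normal(−50 nm, 15 nm) — tens of nanometers on
  the presynaptic side — and amplitudes Normal(80, 10) a.u.; *reduced*
  uses Normal(20, 5); *absent* sets the amplitude to 0.  These regimes are
  generator conventions for "localizes / partially localizes / not
  detected at the active zone", not claims about any particular dataset;
  no quantitative offset or amplitude distributions are published for this
  preparation, so the defaults are chosen once as plausible for an
  active-zone protein and exposed in the config.
- **vesicle cloud** — an isotropic Gaussian (sd 200 nm, amplitude 120)
  centered 250 nm presynaptic of the PSD.

Rendering is analytic: a sharp box convolved with an isotropic Gaussian PSF
separates into a product of erf differences along the box axes, and a
Gaussian cloud convolves into a wider Gaussian with its integral preserved.
Each channel is `background + photon_scale · Σ structures ⊗ PSF`, evaluated
only within ±5σ bounding windows, then Poisson-sampled per pixel if noise
is requested.  The noiseless render is therefore the exact expectation of
the noisy one (verified by a 1000-render calibration test).  Structure
edge softness defaults to 0 so a point-like emitter reproduces the
configured PSF FWHM exactly.

Optics defaults mirror a gated-STED synapse acquisition: 58.14 × 58.14 μm²
fields at 4096 × 4096 px (pixel 14.194 nm), PSF FWHM 60 nm for STED
channels and 250 nm confocal, background 2 counts, photon scale 1 (so peak
SNR at a targeted band is ≈ √82 ≈ 9).  Soma fields use 90.2 nm pixels with
disk-shaped NeuN somata (radius ~8 μm), nucleus disks (~45–55% of the soma
radius), and a cytoplasmic HA annulus.

Seeding: one scene seed; synapse *i* draws from
`SeedSequence((seed, tag, i))`, so extending a scene never perturbs
existing synapses; the Poisson streams use a separate tag per channel.

### What the generator does not emulate

3-D structure and optical sectioning, photobleaching, chromatic offsets
between channels, detector gating, antibody labeling stochasticity,
structured (non-uniform) background, and touching/overlapping synapses.
Passing tests therefore demonstrate that the *measurement pipeline* is
correct and well-calibrated on images matching its geometric assumptions —
not that any biological conclusion holds for real tissue.

## Profile analysis

- **Detection** (automated surrogate for manual side-view selection): Otsu
  on PSD-95, 8-connected components, second-moment principal axis; keep
  components with elongation (√ eigenvalue ratio, with a 1/12-px
  regularization) ≥ 2.0 whose pixels come within 150 nm of the Otsu
  synapsin mask.  The elongation cutoff for manual selection is not
  quantified anywhere, so 2.0 is a declared default; an annotation-driven
  mode accepts externally curated side-view lists instead.
- **Extraction**: grid step = pixel size along both rectangle axes,
  bilinear interpolation, mean (not max) across the 200 nm width —
  matching standard line-profile tooling; whether real analyses average or
  maximize across the width is not stated, so the choice is documented
  here.  A rectangle leaving the image excludes the synapse (logged).
- **Sign convention**: the profile is flipped so the side with more
  synapsin signal is negative (presynaptic).
- **Smoothing**: 5-px centered rolling average applied to the PSD-95
  channel only (the channel of interest stays raw).  At the profile ends
  the window clips to the available samples — no padding, so no invented
  data; `[5,0,0,0,0]` smooths to `5/3` at the first position.
- **Alignment**: each profile is shifted by whole grid steps so its
  smoothed PSD-95 argmax sits at 0 (ties → smallest position); positions
  covered by fewer than half the synapses (configurable) are dropped from
  the group mean; SEM uses ddof=1 and is 0 where n=1.
- **Peak read-out**: maximum within ±window/2 (default 200 nm window) of
  the aligned grid; ties → nearest zero, then the presynaptic side.  The
  offset-recovery benchmarks open the window to 400 nm so a 150 nm true
  offset is inside the searched range.

With 14.194 nm pixels the alignment and read-out are each quantized to
half a pixel, so noiseless recovery is accurate to ≤ 1 px; under default
Poisson noise the median absolute error over ≥ 100 synapses is ~4 nm
(bounded at 30 nm in the acceptance check).

## ROI and soma quantification

Otsu's threshold is computed per image on the synapsin channel over a
256-bin histogram spanning [min, max]; pixels strictly above threshold are
foreground (constant images are rejected).  Components use 8-connectivity
by default ("contiguous" is ambiguous; the choice is exposed because it
changes counts).  The area floor is inclusive: a component of exactly
0.05 μm² is retained, giving a 249-px minimum at 14.194 nm.  ROI and soma
means are taken on raw intensities — no background subtraction — and image
summaries are unweighted means over ROI means.  Soma donuts are
soma ∖ (soma ∩ nucleus); polygons rasterize by the even-odd rule at pixel
centers (pixel center = integer index × pixel size, consistent with the
renderer and the profile sampler); an empty donut is a degenerate-ROI
error.

## Statistics

- Kruskal–Wallis (tie-corrected, χ² with k−1 df; H=0, p=1 when all values
  are identical) with Dunn's post-hoc z on pooled mean ranks,
  tie-corrected pooled variance, vs-reference or all-pairs.  The
  multiplicity rule defaults to Bonferroni-type `min(1, m·p)` — the exact
  correction used inside commercial "Dunn's multiple comparisons" is not
  specified, so the rule is a named, swappable choice.
- Friedman (within-block ranks, tie-corrected) with Dunn's z =
  ΔR̄ / √(k(k+1)/6n) for the within-subject series.
- Wilcoxon matched-pairs signed rank: zeros dropped, average ranks; exact
  two-sided p (2·min tail, capped at 1) by rank-sum convolution for
  n ≤ 12, tie-corrected normal approximation with continuity correction
  above.
- Two-way repeated-measures design with genotype between subjects and drug
  stage within: a mixed ANOVA (pingouin) with Dunnett's comparisons of
  each group vs the control on per-subject means (scipy).  The design must
  be complete and balanced; nothing is imputed.
- `GroupData` carries the unit of analysis (synapse / image / cell);
  concatenating mixed units into one test is an error by construction.

A simulated 3-group null (n = 18/group, 2000 replicates) keeps the
Kruskal–Wallis type-I error rate within [0.04, 0.06] at α = 0.05.

## Pipeline

`run_experiment` validates its config up front (unknown keys are named in
the error), derives all randomness from one seed, stamps every CSV with a
SHA-256 config hash, and optionally replaces condition labels with opaque
codes until the statistics stage (blinding; the key file decodes them).
Two runs with the same config produce byte-identical CSVs.

## Problem sizes

Tests and the acceptance script keep the acquisition-scale pixel size (14.194 nm)
but render 256–1024 px sub-fields with 1–30 synapses per condition and
reuse single-synapse tiles for the recovery benchmarks — plenty for the
quantization- and noise-limited behaviors under test, while the whole
suite runs in well under a minute of rendering time.  Full 4096² fields
are supported and remain the `OpticsSpec` default.

## Known limitations

Automated side-view detection is a convenience surrogate; on crowded real
images it will merge touching PSDs (no watershed splitting) and its
elongation/adjacency thresholds would need tuning.  Alignment is quantized
to the pixel grid (no sub-pixel peak interpolation), which is appropriate
for read-outs reported per ~14 nm pixel but limits accuracy below half a
pixel.  The intensity scale is arbitrary units throughout; no cross-repeat
normalization is attempted (real experiments hold imaging settings fixed
within a repeat instead).
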
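# Methods

This note documents the generative model behind the synthetic cohort, the
network and its training protocol, the statistical battery, the numerical
choices, and what passing tests on phantoms do and do not establish about
real data.

## Phantom generative model

Each subject has chronological age `a` drawn per group (uniform on
[18, 55] by default; a truncated normal with mean 30, SD 9 is available),
sex and scanner drawn with equal proportions, and an *effective brain age*

```
eff = a + Δ_g(a) + η,
Δ_g(a) = β₀ + β₁·a + β₂·max(0, a − knot)      (Δ_HC ≡ 0, knot = 40 y)
η ~ N(0, σ_g²), truncated at ±2.5 σ_g
```

The default patient profile is β₀ = +22.07, β₁ = −0.51, β₂ = −0.1 — an
early-adulthood elevation that declines with age and steepens past the
knot; per-group overrides are supported (the recovery study plants
BD (22.07, −0.51, −0.1) and SZ (23.87, −0.48, −0.1)). The offset is
continuous in age at the knot by construction.

`η` is subject-level biological heterogeneity. Its defaults
(σ_HC = 0, σ_BD = 9.6, σ_SZ = 7.9 years) are derived from the reported
Brain-PAD spreads in single-site BD/SZ cohorts of this size: patient SDs of
~10.2 and ~8.7 years against ~3.5 in controls, where the control spread is
fully accounted for by prediction error (MAE ≈ 3), leaving
√(10.2² − 3.5²) ≈ 9.6 and √(8.7² − 3.5²) ≈ 7.9 years of genuine spread.
Without this term the phantom would imply a patient population as
homogeneous as controls, and the heterogeneity battery (variance tests,
dispersion profiles, quantile regression) would have nothing real to
detect.

The rendered volume is a three-compartment concentric sphere: a bright
shell (intensity 1.0) of thickness `t(eff)`, a mid-intensity interior
(0.5), and a dark central "ventricle" (0.15) of radius `v(eff)`, inside an
outer radius scaled by sex (F 0.96, M 1.04 — a realistic head-size
difference). At the 64-voxel reference grid,

```
t(eff) = 8.0 − 0.9 · (eff − 18)/10        voxels  (thinning)
v(eff) = 4.0 + 1.2 · (eff − 18)/10        voxels  (expansion)
```

both scaled linearly with grid size. Compartment boundaries are rendered
with a one-voxel linear ramp so radii vary sub-voxel-continuously with
age; with zero noise the planted radii are recoverable from the rendered
geometry to ~0.05 voxel (tested). Scanner enters as a multiplicative gain
(1.0 / 1.1) applied after additive Gaussian voxel noise (SD 0.1), so the
between-scanner voxelwise ratio is exact; the background outside the head
mask is exactly zero. Rendering is deterministic given (record, config,
seed), with per-subject seeds derived stably from the cohort seed.

What the phantom does **not** emulate: cortical folding, bias fields,
motion artifacts, registration error, multi-contrast content, or any
spatially specific disease anatomy. Passing recovery tests shows the
pipeline recovers what was planted under its own assumptions — not that
the network would achieve comparable accuracy on real MRI.

## Preprocessing

Volumes are trilinearly resampled (corner-aligned `map_coordinates`,
order 1) to the model grid, clipped at the 1st/99th percentile of each
volume (linear interpolation between order statistics), then z-scored
within volume to mean 0, SD 1 — in that order. Per-volume clip bounds are
used for patients as well as controls. Age targets are standardized with a
scaler fitted on the training partition only (population-SD convention,
divide by n); validation, test and patient subjects reuse it unchanged.
Note that per-volume z-scoring removes the global scanner gain exactly;
the scanner covariate is still modelled (FiLM) for generality.

## Network and training

The reference architecture is five conv blocks (channels 16→256, 3×3×3
kernels, same padding) at a 128³ grid with a 512-unit head; the package
default is the desk-scale reduction — three blocks (8, 16, 32) at 32³
with a 64-unit head — chosen so a full study runs in minutes on one CPU.
Each block is conv → batch norm → FiLM → ReLU → 2×2×2 max pool:

- **Sex-stratified batch normalization** keeps one running-statistics set
  per sex level (shared affine); each item is normalized with its own
  sex's statistics, and inference with an unseen sex level is an error.
- **FiLM** conditions on scanner via a learned per-level, per-channel
  (γ, β) lookup, injected after normalization and before activation in
  every block.

Training minimizes Huber loss (δ = 1 in scaled-age units) with AdamW
(weight decay 1e-5, decay on conv/dense weights only), global
gradient-norm clipping at 1.0, batch size 32, augmentation of training
volumes only (random affine: ±5° rotation, ±5% translation, ±10% scale;
left-right flip with p = 0.5), validation-loss early stopping
(patience 15) and plateau learning-rate halving (patience 5). The
reference learning rate is 1e-4; the desk-scale default is 1e-3, which
the reduced architecture needs to converge within its epoch budget. The
scaled protocol used by the recovery study is 50 epochs, early-stop
patience 12.

Because only two-to-three batches fit in an epoch at these cohort sizes,
exponential-moving-average batch-norm statistics are noisy; after every
epoch the running statistics are replaced by the exact population
statistics of the training set at the current weights (one stat-collection
pass, standard batch-norm recalibration). This stabilizes both model
selection and inference. The engine (im2col convolution, analytic
backprop, optimizer) is written in numpy/float32; training is reproducible
bit-for-bit given the seed on fixed hardware.

## Brain-PAD, bias correction

Brain-PAD = predicted − chronological age, positive meaning
older-appearing. R² is reported as 1 − SSres/SStot against the identity
prediction, with the squared-correlation convention emitted alongside
(`r2_corr`), since the two differ once predictions are biased.

Brain-age models regress toward the training mean, so HC-based age-bias
correction precedes trajectory analyses. Two methods are provided:

- `residual` — fit PAD ~ α + β·age on HC, subtract the fitted line from
  everyone (the classic residualization).
- `rescale` — fit predicted age ~ α + β·age on HC and invert that
  calibration, `pred' = (pred − α)/β`. This additionally undoes the
  multiplicative attenuation that residualization provably leaves in
  held-out-group offsets (a planted offset Δ appears as β·Δ after
  residual correction but as Δ after rescaling).

The pipeline default is `rescale` because the recovery analyses compare
estimated offsets against planted values on the years scale; `residual`
is retained for parity with common practice.

## Trajectory and heterogeneity battery

All models run on the bias-corrected PAD table with HC as reference level
and sex/scanner covariates (dropped automatically when single-level):

- **Interaction**: OLS `pad ~ age × group + sex + scanner`, reporting
  patient intercept/slope contrasts versus HC and the direct BD−SZ slope
  contrast (Wald χ²).
- **Piecewise**: basis (age, max(0, age − 40)) interacted with group;
  continuous at the knot; per-group pre/post-knot slopes and the knot-term
  ("extra slope") estimates with SEs. With no knot effect it reproduces
  the interaction model's slopes exactly (tested).
- **Spline**: natural cubic spline on age (df 4 by default — enough
  curvature for one bend on a 37-year range without overfitting n ≈ 60
  groups), interacted with group; omnibus group test via nested-model F.
- **LOESS**: tricube-weighted local *linear* fits, span 0.75 default, no
  robustness iterations (so the value at any point equals the direct
  weighted-least-squares fit there, which the tests verify); explicitly
  visualization-grade, excluded from inference.
- **Quantile regression**: check-loss minimization on the age × group
  design per τ; per-group age slopes reported.
- **Brown-Forsythe**: one-way ANOVA on absolute deviations from group
  medians (W on k−1, N−k df), computed globally over ages by default.
- **Dispersion / ribbon summaries**: per-group linear age-detrend then
  per-10-year-bin residual SD; per-5-year-bin median/IQR/10–90% bands.
  Bins under 5 subjects are flagged as suppressed.
- **Sensitivity suite**: (a) refit on a trimmed age window (default
  20–50); (b) inverse-probability weighting — weights are the binned
  (5-year) pooled-to-group age-density ratio, normalized to mean 1,
  feeding a WLS refit; this construction directly targets uneven age
  sampling across groups; (c) leave-one-out influence on the interaction
  slopes, flagging |Δβ| > 2/√n × SE (DFBETA-style cut, configurable);
  (d) robust refit by Huber M-estimation with the standard tuning
  constant 1.345. Conventional (non-robust) OLS standard errors are used
  throughout; heteroskedasticity-consistent errors were considered and
  left out to keep a single SE convention across the battery.

## Attribution

Grad-CAM for a regression output: channel weights are the spatial mean of
∂(prediction)/∂(activation) at the chosen block (default: penultimate
block, matching the fourth-of-five convention at full scale), the map is
the rectified weighted channel sum, trilinearly upsampled to the input
grid and normalized per subject by its maximum (alternatives: sum-to-one,
none). Maps are invariant to constant shifts of the model output (tested).

Real-data parcellations would come from an atlas in input-grid space; for
the phantom, a geometric stand-in region set is generated from the
reference geometry — angular shell sectors for frontal / occipital /
parietal / temporal / motor / sensory / cerebellar "lobes" and a
peri-ventricular band for "limbic" — declared in config rather than
hard-coded. Regional means are correlated with Brain-PAD per group and
pooled, plainly and partially (residualizing both variables on age, sex
and scanner; t-based two-sided p with df reduced by the number of
covariates), with Benjamini-Hochberg FDR applied within each family of
regional tests.

## Orchestration and determinism

A single `PipelineConfig` (YAML-serializable, hash-stamped) drives
generate → split → train → predict → attribute → analyze. Every stage
derives its seed as `blake2(global_seed, stage_name) mod 2³¹`, so stages
can be rerun independently and deleting any cached stage output
reproduces it identically. Healthy-control-only training is structural:
the trainer receives only HC rows, and an explicit training list
containing a patient id is rejected before training. Checkpoints are
parameter arrays plus a JSON sidecar (architecture, scaler, covariate
levels, best epoch).

## Problem sizes

The shipped study sizes are chosen so everything runs on one CPU: the
end-to-end recovery study uses a 32³ grid, channels (8, 16, 32), 120 HC
(72/24/24) and 60 BD / 60 SZ (≈ 5 minutes); unit tests use 16³ grids and
cohorts of 8–32 subjects (the full suite runs in ≈ 5 minutes). All sizes,
grids and channel widths are configurable up to the full-scale reference.

## Known limitations

- The phantom's age signal is globally geometric; regional attribution on
  phantoms can only validate mechanics (localization of planted saliency,
  normalization, statistics), not anatomical claims.
- Quantile regression at extreme τ on small groups can hit the interior-
  point iteration cap; estimates are still returned and flagged by the
  underlying solver warning.
- The CNN engine is CPU-bound numpy; 128³ five-block training is out of
  its intended envelope.
- Cross-sectional Brain-PAD conflates cohort and aging effects; nothing
  here addresses survivor bias or longitudinal inference.
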
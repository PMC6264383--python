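# Methods

This note documents the models implemented in `gradnf`, the defaults they
ship with, and the choices made where the underlying experimental
procedure left the design open.

## Experimental skeleton

All designs live on a TR = 1.55 s grid with 0-based volume indexing; block
onsets in seconds are `onset_volume × TR` with no slice-timing offset,
which is the natural convention for ROI-mean series. A neurofeedback (NF)
run tiles 5 rest and 4 task blocks of 20 volumes (180 volumes, 279 s);
task blocks carry *low*/*high* target labels, two of each per run. A
localizer run tiles 5 rest and 4 task blocks of 16 volumes (144 volumes).
A `padding_volumes` option can append extra trailing rest volumes for
protocols whose acquisition ran longer than the stimulus structure; the
default is 0 and nothing downstream depends on it.

Counterbalancing: region order (which of SMA/M1 is trained first)
alternates across consecutive subjects. Within a subject, each region's
five runs draw level orders from the six permutations of
{low, low, high, high} such that low-first and high-first runs differ in
count by at most one; the draw is a seeded permutation scheme, so any
cohort is reproducible from its seed. Level-order counterbalancing is not
cosmetic here: the NF analysis model has no drift regressor (see below),
so a linear scanner drift loads onto the level contrast of any single
block order, and it is the counterbalancing across runs that cancels this
loading in per-subject aggregates. The type-I-error simulation in the
test suite demonstrates exactly this mechanism.

## Synthetic data generator

Per region and run the raw ROI-mean signal is

```
y(v) = B · (1 + Σ_levels psc_true/100 · x_level(v)) + m·v + ε(v)
```

where `B` is the baseline signal (default 1000 arbitrary raw units),
`x_level` is the level boxcar convolved with a double-gamma HRF and scaled
to unit plateau, `m` a linear drift (default 0.05 raw units/volume ≈ 0.9%
over a run), and `ε` stationary AR(1) Gaussian noise (default marginal SD
6 raw units, lag-1 autocorrelation ρ = 0.3). The HRF is the canonical
double-gamma (peak 6 s, undershoot 16 s, ratio 1/6) sampled on the TR
grid; block regressors are rescaled by the kernel sum so a sustained
block plateaus at exactly 1, which makes a GLM amplitude directly
readable in the boxcar's units and gives closed-form oracles for
noiseless tests.

Default effect structure (the study conditions the generator emulates):
SMA responds positively with *low* = 0.300 and *high* = 0.387 PSC (a
0.087 high-minus-low difference), M1 responds at −0.150 PSC at both
levels, and the localizer elicits 1.48% (M1) and 1.10% (SMA). The
generative model carries **no feedback-condition effect**: a region
responds identically whether it drives the display or not, mirroring the
null interaction the emulated study observed. Between-subject variation
is a shared per-region offset (SD 0.25 PSC; also applied to the localizer
PSC) plus an independent per-cell offset (SD 0.08 PSC, so the level
difference has between-subject SD ≈ 0.11, giving group effect sizes
d ≈ 0.7–0.8 at n = 17).

Physiological traces are generated at TR resolution as a subject-typical
mean (40 mmHg end-tidal CO2, 65 bpm heart rate) plus a slow AR(1)
fluctuation (ρ = 0.9; SD 1.5 mmHg / 3 bpm) plus `coupling × task boxcar`.
Default couplings are small and negative (−0.1 mmHg, −0.3 bpm) with
between-subject SD equal to the coupling magnitude, chosen so the group
Fisher-z statistics land in the small-negative regime the emulated study
reported. Real physiological recordings have cardiorespiratory structure
(respiratory cycles, HRV spectra) that this generator does not attempt;
the traces exist to exercise the correlation/FDR analysis path, and
passing tests show the analysis machinery is correct, not that real
physiology behaves this way.

What the generator does **not** model: voxelwise noise and spatial
smoothing (everything is an ROI mean by construction), motion artifacts,
nonlinear drift, display latency, or any feedback-dependent behavioural
adaptation — simulated "participants" hit their target amplitudes by
construction, so the pipeline tests recovery of known effects, not
learning.

## Online feedback computation

At every TR of a task block:

- `val` = mean of the last three acquired ROI raw values. At a block's
  first two volumes this window straddles the rest/task boundary, which is
  the causal behaviour of the original online system (default,
  `window="causal"`); a `window="block"` option restarts the average at
  block onset instead.
- `baseline` = median of the last 10 volumes of the preceding rest block,
  updated at each rest→task transition.
- `PSC_NF = (val − baseline) · 100 / baseline`, displayed as
  `PSC_NF / (0.10 · PSC_LOC)` thermometer segments, rounded to the nearest
  integer (half away from zero; a floor convention is selectable) and
  clamped to [0, 15]. The rounding convention is a choice — the original
  system documents only the clamping. Target levels sit at 5 (low) and 10
  (high) segments.

Rest volumes emit no segments (the thermometer stays empty). PSC_LOC, the
calibration constant, is defined here as the localizer GLM task amplitude
as a percentage of the intercept; the original online implementation's
formula is unpublished, and this definition makes online and offline
calibration coincide exactly on noiseless data.

## Offline GLM

NF-run model: intercept, an HRF-convolved task regressor spanning all
four task blocks, a parametric level regressor (+½ on high, −½ on low, on
the same convolved support — so its coefficient equals the high-minus-low
amplitude difference), and one indicator per task block covering the 10
pre-onset volumes, matching the online baseline window. No drift term,
matching the analysis it replicates. One pre-onset indicator *per task
block* (rather than one shared regressor) was chosen because the online
baseline is re-estimated per block; the alternative changes little on
simulated data. Localizer model: intercept, task, mean-centred linear
drift.

Fitting is two-pass prewhitening: OLS, estimate the residual lag-1
autocorrelation, Prais–Winsten-transform data and design (first row
scaled by √(1−ρ²)), re-fit. Because OLS residuals are a projection of the
noise, their raw lag-1 autocorrelation is biased toward zero (about −0.06
at ρ = 0.4 for this design); the estimate is de-biased by inverting the
exact mapping E[r₁ | ρ] computed from the residual projection operator on
a ρ grid (cached per design matrix). Degenerate designs (e.g. a
parametric regressor proportional to the task regressor when all blocks
share a level) are rejected with the offending columns named.

Level-wise PSC: `100 · (β_task ± ½β_level) / (β_intercept + mean(β_pre))`.
On noiseless simulated runs this recovers `psc_true` exactly and agrees
with the online plateau PSC within 5%.

Event-related averages are expressed as percent change from each block's
own 10-volume pre-onset baseline and averaged across blocks; group error
bands use the Cousineau subject-centering correction with Morey's
m/(m−1) factor, a standard within-subject error definition.

## Group statistics

Per subject, PSC values are aggregated as the **median across runs** for
each region × condition × level cell. The 2×2 within-subject ANOVA tests
each effect against its own subject-by-effect interaction term (for
2-level factors each F equals the square of the corresponding paired t,
an identity the tests verify to machine precision). Effect sizes are
partial omega-squared, ω²ₚ = (F−1)/(F+(df_den+1)/df_num), clamped at 0 —
the variant consistent with the published effect sizes this package
emulates. Paired/one-sample t-tests report Cohen's d = t/√n.

The informed Bayesian t-test places a half-normal prior (scale σ,
truncated to the hypothesized direction) on the standardized effect δ and
integrates the noncentral-t likelihood over it:

```
BF = ∫₀^∞ nct(t; n−1, δ√n) · 2φ(δ; 0, σ) dδ / t(t; n−1)
```

evaluated by adaptive quadrature split at the likelihood peak (relative
tolerance 1e−9; a brute-force Riemann sum on a fine grid agrees within
1e−4). Prior scales derive from group localizer PSC values: 75% of the M1
PSC for M1 deactivation tests, 50% of the SMA PSC for the level contrast
(the spacing between the two target levels). BF → 1 as σ → 0 and is
monotone in t for a directed positive test.

Physiological analysis: each trace is demeaned (its physiological mean
carries no task information and would otherwise leak an onset ramp into
the correlation), convolved with the same HRF, and correlated with the
task predictor; r values are Fisher-z-transformed, averaged across runs
per subject, and tested against zero with one-sample t-tests —
two-sided by default, since the directions here are exploratory — with
Benjamini–Hochberg FDR across the kind × region tests. Constant traces
yield an undefined r and are excluded with a warning. Both FDR and
Bonferroni correctors are available.

## Problem sizes and determinism

The shipped defaults are the full study geometry (17 subjects, 5 NF runs
per region, 180-volume runs); a complete simulate-analyse-report cycle
takes a few seconds. Monte-Carlo checks in the test suite use 200
replicates for estimator bias, 500 for the autocorrelation estimate, and
1000 null cohorts (two counterbalanced runs per subject) for the
type-I-error calibration of the level test. Every stochastic stage
receives an explicit seed; a cohort seed fans out to per-subject
`SeedSequence` children, so any subject's data can be regenerated
independently, and pipeline runs write a provenance manifest (config,
hash, versions).

## Known limitations

- ROI-mean simulation only; no voxel level, no spatial operations.
- The AR(1) noise model matches the prewhitening model by construction;
  real BOLD noise has longer-memory structure the two-pass AR(1) only
  approximates.
- The generator's effect structure is stationary across runs (no learning
  curve), so the run-trend ANOVA is exercised under the null by default.
- Omega-squared conventions differ across software; only the partial-ω²
  variant implemented here is reported.
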
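# Methods

This note documents the models, numerical choices and design decisions
behind `tauflow`, in the spirit of a package methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Kinetic model

The simplified reference tissue model (SRTM) describes a target region's
time–activity curve (TAC) through the reference region's curve:

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·[C_R ⊗ e^(−k2a t)](t),
    k2a = k2/(1 + BP_ND),  DVR = BP_ND + 1.

Assumptions: both regions are effectively one-tissue compartments, share
the nondisplaceable distribution volume, and the reference region is
devoid of specific binding. R1 (unitless) is the target/reference
delivery ratio and proxies relative cerebral blood flow; k2 (1/min) is
target efflux; BP_ND (unitless) is specific binding.

### Numerics: closed-form convolution

Measured TACs are treated as piecewise-linear in time — frame values
attached to frame midpoints, zero at injection, constant after the last
midpoint. For such curves the convolution with an exponential kernel
satisfies y′ = f − k·y and is integrated exactly segment by segment;
values at arbitrary times and *exact frame averages* follow from
∫y = (∫f − Δy)/k. The forward model, the basis functions and the fit
therefore contain no discretisation error and no FFT edge effects. The
frame average of the R1·C_R term is exactly R1 times the measured frame
values, which keeps the forward model and the fit design matrix
consistent. (A `fine_dt` grid survives only where the continuous plasma
curve is sampled; halving it changes reference frame values at the 1e-6
relative level.)

## Parameter estimation (receptor parametric mapping)

The nonlinear k2a is discretised on a log-spaced grid (default 64 points
over [0.006, 0.6] min⁻¹, spanning plausible flortaucipir kinetics); for
each grid point the two linear coefficients of
C_T ≈ θ1·C_R + θ2·B(k2a) are solved in closed form and the point with
minimal weighted residual sum of squares is selected, then mapped to
R1 = θ1, k2 = θ2 + R1·k2a, BP_ND = k2/k2a − 1. Two refinements:

* **Continuous polish.** Pure grid selection quantises k2a (±3.8% at 64
  points), leaving ~1% parameter error. A bounded search over log k2a
  between the two neighbouring grid points removes it; noiseless round
  trips then recover parameters to machine-level accuracy.
* **Errors-in-variables correction (optional).** Both design columns are
  linear functions of the measured reference frames, so when the
  reference is itself noisy, ordinary least squares attenuates R1 (about
  −2% at 5% frame noise) by an amount that depends on the binding level
  — which biases longitudinal R1 ratios. When the per-frame reference
  noise SD is available (it is, inside the simulation framework), its
  second moments are subtracted from the normal equations, removing the
  attenuation without inflating variance.

Fit weights default to uniform, with frame-duration weights available;
under the proportional noise model below, duration weights are
inverse-variance and the cohort pipeline uses them. Negative fitted
BP_ND values are reported as-is (with a warning at DVR conversion) —
clamping would bias cohort means. Fits landing on the grid boundary are
flagged, never dropped.

SUVr over a window is the duration-weighted mean target/reference ratio;
frames partially covering the window contribute by overlap length, so
the value does not depend on frame-boundary placement.

## Simulation framework

* **Plasma input**: linear rise to a peak at 1 min, then tri-exponential
  decay (rates 2.5, 0.28, 0.009 min⁻¹). Only the shape matters — every
  downstream quantity is a ratio.
* **Reference region**: one-tissue, C_R = K1′·[C_p ⊗ e^(−k2′t)], with
  k2′ = 0.05 min⁻¹.
* **Binding conditions**: BP_ND = 0.05 (almost no binding), 0.25, 0.6,
  1.2 (high AD-like load). Each condition carries the relative delivery
  of the cortical territory it typically occupies (entorhinal ≈ 0.71 for
  the no-binding case, limbic ≈ 0.84, neocortical ≈ 0.90); k2 = R1·k2′.
  A single common R1 for all conditions is available as an option but is
  not physiological: with R1 = 0.9 everywhere, a +30% flow change drives
  the no-binding target's efflux past the reference's and flips the
  late-window SUVr bias negative, which contradicts the observed
  behaviour these simulations are built to emulate.
* **Flow scenarios**: delivery and efflux scale jointly by (1+δ),
  δ ∈ {−0.3 … +0.3} by default, leaving true DVR exactly invariant;
  scope is regional (target-only) by default, optionally global.
* **Noise**: independent Gaussian per frame with
  SD_i = COV·C(t_i)·√(Δt̄/Δt_i) — the count-statistics scaling that makes
  short early frames noisier. COV 0.05% approximates noiseless data;
  COV 5% is realistic ROI-level noise. Noise applies to target and
  reference independently; negative values are flagged, never clipped.
* **Schedule**: continuous 130-min dynamic framing (6×10 s, 2×30 s,
  3×60 s, 2×150 s, 2×300 s, then 5-min frames).

### Calibration of the two free constants

The plasma terminal clearance (0.009 min⁻¹) was fixed once so that the
simulated baseline SUVr(80–100) at two anchor settings — (BP_ND 0.045,
R1 0.836) and (BP_ND 0.284, R1 0.904), the low- and high-binding
cortical operating points of the cohort — reproduces the SUVr-over-DVR
overestimation seen in observed cortical flortaucipir data (simulated
1.094 and 1.375 against observed 1.102 and 1.382). All other constants
are generic physiological choices; everything is exposed in the run
configuration.

## Synthetic longitudinal cohort

The generator emulates a two-timepoint, two-group observational study:
38 subjective-cognitive-decline subjects and 24 AD patients, three
Braak-stage composite regions, ~2.1/2.2 ± 0.3 y between scans. Per
subject and region it draws true baseline DVR and R1 and subject-level
percentage changes from normal distributions whose means and SDs are
transcribed from the published cohort (packaged in
`tauflow/data/default_cohort.yaml`). Regions within a subject share a
Gaussian random effect (intra-subject correlation 0.7, configurable):
Braak regions are biologically coupled, and pooled-region statistics
(Pearson, Bland–Altman) are sensitive to that coupling; the true
covariance is not published, so pooled-correlation magnitudes should be
read as demonstrations, not calibrated predictions.

Truncations (baseline and follow-up DVR ≥ 1, baseline R1 ≥ 0.3,
interval ≥ 0.5 y) use rejection resampling of whole per-subject region
vectors, preserving both the distribution shape near the bound and the
intra-subject correlation. Truncation shifts the *baseline* means
upward (intentionally — DVR below 1 is unphysical) but moves the
percentage-change means by well under half a point, which the test suite
verifies.

SUVr is never sampled: each subject-visit is realised as noisy TACs and
SUVr is computed from them, so the SUVr-vs-DVR gap and its flow
sensitivity emerge mechanically from the kinetics. Truth columns travel
with fitted columns in every results table for audit; truth records are
never mutated.

What the generator does **not** emulate: off-target binding (a known
flortaucipir limitation), partial-volume effects, scanner PSF, decay and
deadtime, dual-time-window gaps (sampling is continuous), attrition, and
amyloid-status substructure. Passing tests therefore show that the
quantification chain is faithful under the stated kinetic and noise
model — not that it would survive every artefact of real data.

## Statistics

Percentage change is (follow-up/baseline − 1)·100; annualised change
divides by the scan interval in years. Paired t tests and Pearson
correlations are two-sided; no multiple-testing correction is applied by
default (regional P values are reported raw; a Bonferroni helper
exists). Bland–Altman differences are quantitative minus
semiquantitative (DVR − SUVr changes), with limits of agreement at
±1.96 SD. Sample sizes for a paired t test come from the noncentral t
distribution (df = n−1, noncentrality dz·√n), scanning n upward until
the requested power is met; the effect is specified as (expected %
change, SD of % change), the way longitudinal PET effects are quoted,
and dz is derived internally. Callers who want trial-duration scaling
(e.g. 18-month changes) apply `annualized_change` first.

## Problem sizes used by the checks

The acceptance script averages 40 independent cohorts (the per-subject
SD of R1 percentage change is ≈ 7 pp, so 40×24 subjects put the Monte
Carlo error of that grand mean near 0.25 pp); bias grids use 200
replicates per cell for noise comparisons and 20 for near-noiseless
structure checks; the null-calibration check uses 500 replicate
mini-cohorts. These sizes were chosen so every Monte Carlo margin is a
small fraction of the corresponding scientific tolerance.

## Known limitations

* The RPM implementation is region-level; voxelwise parametric imaging
  (and its noise regularisation trade-offs) is out of scope, as are
  plasma-input models (2TCM, Logan) and SRTM2.
* The errors-in-variables correction needs the reference noise SD; on
  real data it would have to be estimated from reconstruction statistics.
* The plasma model and binding-condition constants are plausible, not
  fitted to individual subjects; conclusions should rest on the relative
  behaviour of SUVr vs DVR, which is robust to those choices, not on
  absolute uptake values.
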
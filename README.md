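# tauflow

Reference-tissue kinetic modelling and flow-bias simulation for
longitudinal tau-PET quantification.

## The problem

Longitudinal flortaucipir (tau) PET studies can quantify tracer binding
two ways. A dynamic scan supports the simplified reference tissue model
(SRTM), which expresses the target-region time–activity curve C_T(t) in
terms of a reference-region curve C_R(t) through three parameters —
relative delivery R1 (a proxy for relative cerebral blood flow), target
efflux k2, and binding potential BP_ND:

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a) · [C_R ⊗ e^(−k2a·t)](t),
    k2a = k2 / (1 + BP_ND),    DVR = BP_ND + 1.

A static late scan yields only the standardized uptake value ratio
SUVr = C_T/C_R averaged over a window such as 80–100 min. SUVr is
convenient but is not a pure binding measure: it is biased relative to
the true DVR, and the bias moves when cerebral blood flow changes —
a real concern for disease progression and drug trials. DVR from kinetic
modelling is, by construction, insensitive to proportional flow changes.

`tauflow` implements the full chain needed to study this quantitatively:

* **`tauflow.kinetics`** — SRTM forward model, basis-function parameter
  estimation (receptor parametric mapping: a log-spaced k2a grid, closed
  form weighted least squares per grid point, WRSS selection plus a
  continuous polish step, optional errors-in-variables correction for a
  noisy reference), and windowed SUVr. Exponential convolutions of the
  piecewise-linear TACs are evaluated in closed form — no quadrature.
* **`tauflow.simulate`** — plasma input, one-tissue reference region,
  named tau-binding conditions, flow scenarios (R1 and k2 scaled jointly,
  leaving true DVR fixed), and proportional Gaussian frame noise.
* **`tauflow.bias`** — grids of percentage bias of SUVr and fitted DVR
  against true DVR across binding level, flow change, scan window and
  noise level.
* **`tauflow.cohort`** — a synthetic two-timepoint cohort generator
  (two groups: subjective cognitive decline n=38 and AD n=24; three
  Braak-stage composite regions) whose truth distributions are
  parameterised from a published longitudinal flortaucipir cohort, plus
  the end-to-end pipeline: simulate noisy TACs per subject-visit, fit,
  compute percentage changes, paired tests, Pearson and Bland–Altman
  agreement.
* **`tauflow.stats`** — percentage change, annualisation, paired t,
  Pearson, Bland–Altman, and paired-t sample-size curves via the
  noncentral t distribution.

## Worked example

Simulate a noisy dynamic scan for a medium-binding AD-like region
(true R1 = 0.84, k2 = 0.042 /min, BP_ND = 0.6, 5% frame noise) and
quantify it:

```sh
$ tauflow simulate --condition AD_medium --cov 0.05 --seed 7 --out example.csv
$ tauflow fit --tac example.csv --window 80 100
region,R1,k2_per_min,BPND,DVR,SUVr_80_100,wrss,boundary_flag
example,0.8359...,0.03518...,0.5854...,1.5854...,1.7149...,6.595...,False
```

The fit recovers R1 ≈ 0.836 and DVR ≈ 1.585 (truth 0.84 and 1.6) from a
single noisy realisation, while the 80–100 min SUVr of the same data is
1.715 — a ~7% overestimate of the true DVR, which is the systematic
SUVr-vs-DVR gap the simulation framework studies.

Sample sizes for a future paired study (per arm, α=0.05, power 0.80):

```sh
$ tauflow sample-size --effect 1:4:1 --sd 4
expected_pct_change  sd_pct_change  alpha  power  n_required
1.0                  4.0            0.05   0.8    128
2.0                  4.0            0.05   0.8    34
3.0                  4.0            0.05   0.8    16
4.0                  4.0            0.05   0.8    10
```

In Python, the cohort pipeline is one call:

```python
from tauflow.cohort import run_cohort_pipeline
run = run_cohort_pipeline(seed=1, cov=0.05)
print(run.stats)       # group x region x parameter: %change, paired t
print(run.agreement)   # per group: Pearson r, Bland-Altman bias / LoA
```

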
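# Methods

This note records the statistical model, the estimation machinery, the
design decisions behind the simulation and cohort generators, and the known
limitations.

## 1. Model

Let `y_ijs` be the response (e.g. retinal thickness, µm) of patient
`i = 1..n`, eye `j` (one or two per patient), sector `s` on a fixed lattice
of `k ≤ 9` named locations. The model is

```
y_ijs = x_ijs' beta + b_i + u_ij + e_ijs,
b_i  ~ N(0, sigma_b^2),   u_ij ~ N(0, sigma_u^2),
(e_ij1, …, e_ijk)' ~ N(0, sigma_s^2 * Lambda C(gamma) Lambda),
```

with all random terms mutually independent and patients independent of each
other. `C(gamma)` is the sector correlation matrix generated by a kernel on
the inter-sector distance (or adjacency lag), and
`Lambda = diag(lambda_g)` carries one residual-scale ratio per level of an
optional grouping factor, the reference level fixed at `lambda = 1` for
identifiability. The marginal covariance is block-diagonal over patients;
within a patient,

```
H_i = sigma_b^2 J + blockdiag_j( sigma_u^2 J_j + sigma_s^2 Lambda_j C_j Lambda_j ),
```

where `J` is the all-ones matrix and `C_j` is the principal submatrix of
`C` for the sectors actually observed in eye `j` (missing sectors simply
drop rows; no imputation).

### Correlation kernels

For distance `d ≥ 0` in millimetres (or integer lag `delta`), with rate
`gamma > 0`:

| family | correlation |
|---|---|
| independence | `1{d = 0}` |
| exponential | `exp(-gamma d)` |
| gaussian | `exp(-gamma d^2)` |
| spherical | `1 - 1.5 gamma d + 0.5 (gamma d)^3` for `d < 1/gamma`, else 0 |
| ar_lag | `gamma^delta`, `gamma ∈ (0, 1)`, `delta` = adjacency lag |

`gamma` is a *rate*: larger means faster decay. Exponential and Gaussian
kernels are positive definite on any planar point set; spherical is valid in
the plane; the lag kernel operates on a fixed integer lattice. The matrix
builder verifies positive semi-definiteness numerically and rejects
violations rather than silently repairing them.

### Sector geometry

The default lattice is the nine-sector macular grid: a central subfield at
the origin and two rings of four sectors (superior / temporal / inferior /
nasal), with centroids placed at the ring mid-radii — 1.0 mm for the inner
ring, 2.25 mm for the outer ring. Distances are Euclidean between centroids
and are identical for left and right eyes (laterality only mirrors the
x-coordinates). Custom lattices can be supplied as coordinate tables.

## 2. Estimation

Write `theta` for the variance parameters and `H(theta)` for the marginal
covariance. Fixed effects are profiled out by GLS:

```
beta_hat(theta) = (X' H^-1 X)^-1 X' H^-1 y,
Cov(beta_hat)   = (X' H^-1 X)^-1.
```

The ML objective is the profiled Gaussian log-likelihood (including the
`-N/2 log 2π` constant); the REML objective subtracts
`½ log |X' H^-1 X|` and adjusts the constant, satisfying the identity
`l_R(theta) = l(beta_hat, theta) - ½ log|X' H^-1 X| + (p/2) log 2π`, which
the test suite checks on every nontrivial model.

### Parameterisation and optimisation

The objective is maximised over an unconstrained transform: `log` of each
SD, `log gamma` (or `logit gamma` for the AR kernel) and `log lambda_g` per
non-reference group. L-BFGS-B with finite-difference gradients runs from a
moment-based starting point (OLS residual variance split across components;
`gamma_0 = log 2 / median distance`, i.e. correlation ½ at the median
distance) plus jittered restarts. Wide box bounds on the transformed scale
keep the linear algebra away from overflow; an estimate is flagged as a
*boundary* estimate if it lands on a bound or if a random-effect SD
collapses below 10⁻³ of the residual SD (a variance component estimated at
zero — the usual caveats about boundary inference then apply, and the
likelihood-ratio test notes that the naive chi-square reference is
conservative there).

### Blocked linear algebra

`H` is block-diagonal over patients, and most patients share the same block
pattern (same observed sectors, eye count and weight groups). Patients are
bucketed by block signature and each bucket is processed as one batched
Cholesky factorisation + triangular solve, accumulating `log|H|`,
`X'H⁻¹X`, `X'H⁻¹y` and `y'H⁻¹y`. This makes a 200-patient fit take a few
hundredths of a second and a 500-patient two-eye heteroscedastic fit about a
second, which is what makes the Monte-Carlo study cheap.

### Inference

* Wald tests on single coefficients use the normal reference; joint tests
  use chi-square with one df per coefficient, with an F variant whose
  denominator df follows a between-within count at the eye level.
* Likelihood-ratio tests require a common objective; REML comparisons are
  refused unless the fixed-effects design is identical.
* `AIC = -2l + 2p`, `BIC = -2l + p log(n_eff)` with
  `p = dim(beta) + dim(theta)` and `n_eff = N` (ML) or `N - p_fixed`
  (REML). A `paper_variant` switch doubles the BIC penalty to
  `2p log(n_eff)`, matching a variant sometimes printed in the applied
  literature; the default follows the standard definition.
* Top-down selection: fit the saturated fixed effects, choose the random
  structure by REML AIC/BIC, then the correlation family, then reduce the
  fixed effects under ML, and refit the winner by REML. Every candidate fit
  is recorded in an audit trail.
* BLUPs of `b_i` and `u_ij` are the usual conditional means
  `sigma^2 Z' H^-1 (y - X beta_hat)` per component.

## 3. Monte-Carlo study design

Three scenarios share one truth and differ only in the residual
correlation: none, exponential rate 0.5, exponential rate 0.1 (rate 0.1
over millimetre distances ⇒ neighbour correlation ≈ 0.90, a strong
misspecification stress for the non-spatial analysis).

Per replication: `n = 200` patients, one eye each, an exact 70/30 split of
no-maculopathy (M0) vs maculopathy (M1); a patient-level risk factor drawn
truncated-normal(54, 15²) on [20, 86]; intercept 280 µm, risk slope −0.3,
diagnosis effect +6.1 µm; fixed sector offsets (inner ring thicker) and a
+2 µm inner-ring thickening in M1 (the "shape effect", so the joint
interaction test has nonzero power); a patient random intercept with SD
1.5 µm and residual SD 10 µm.

The patient-intercept SD deserves a note. With a shared intercept of SD
`sigma_b` across an eye's nine sectors, the non-spatial OLS analysis of a
*patient-level* covariate is miscalibrated even in the uncorrelated-residual
scenario, with coverage collapsing as `sigma_b / sigma_s` grows. The study
is designed so that Scenario 1 is a calibration baseline — both analyses
near nominal coverage — and coverage degradation is attributable to the
*spatial* correlation added in Scenarios 2–3. That requires
`sigma_b` small relative to `sigma_s`; 1.5 vs 10 achieves baseline
non-spatial coverage ≈ 95–96% while keeping a genuine two-level structure.
With a large `sigma_b` (comparable to clinical cohorts) the non-spatial
baseline coverage drops to ≈ 70% already in Scenario 1 and the scenario
comparison no longer isolates the spatial effect.

Each replication is analysed by the spatial model (REML, exponential
kernel, patient intercept) and by OLS on the *identical* design matrix
(statsmodels). Reported per approach: mean estimate, mean model SE,
Monte-Carlo SD, 95%-CI coverage (`±1.96 SE`), and the power of the joint
Wald chi-square test of all sector-by-diagnosis interactions at
`alpha = 0.05`. Replications whose spatial fit fails are dropped and
counted; the run aborts if more than 5% fail (in practice none do).
Replication `r` uses seed `base_seed + r`, so any replication can be
regenerated in isolation.

## 4. Synthetic clinical cohort generator

`generate_clinical` emulates a clinic-style OCT cohort: 500 patients by
default (75 healthy, 260 diabetic without maculopathy, 165 with
maculopathy), each contributing two eyes with probability 0.835, nine
sectors per eye, with optional completely-at-random sector missingness that
never empties an eye.

Defaults are chosen to be representative of clinical OCT cohorts: per-group
sector mean profiles with central subfield ≈ 283–293 µm and the inner ring
thickest; an age slope of −0.1984 µm/year centred at 54 years with ages
truncated-normal(54, 15²) on [20, 86]; patient SD 18.34 µm, eye-within-
patient SD 1.45 µm, residual SD 23.8 µm with group scale ratios
0.4588 (healthy) / 0.5369 (M0) / 1 (M1, reference); exponential spatial
rate 1.4487 per mm. The generator draws exactly the model of §1, so
two-level heteroscedastic spatial fits on its output are a parameter-
recovery oracle for the whole estimation path.

A caveat on `sigma_u` (eye SD): at 1.45 µm against a 23.8 µm residual SD,
the eye variance is a small fraction of the total, and its sampling SD at
500 patients is of the same order as the parameter itself, so its relative
recovery error across seeds is routinely tens of percent. The acceptance
check of component recovery at the standard seed passes, but users should
not expect tight `sigma_u` estimates at these cohort sizes; this is a
property of the information content of the design, not of the optimiser.

## 5. Numerical and software choices

* Established libraries do the standard work: scipy for optimisation and
  distributions, numpy (batched) linear algebra, pandas I/O, statsmodels as
  the OLS comparator in the study and as an independent mixed-model oracle
  in the tests (`MixedLM` reproduces our one- and two-level non-spatial
  REML fits to 4 and 3 significant figures respectively).
* The likelihood evaluator rejects non-positive-definite assemblies
  (raising, rather than regularising) — the optimiser treats those points
  as infeasible.
* All generators take explicit seeds and are deterministic given the seed;
  the CLI surfaces the seed in every report.
* Problem sizes used in validation: unit tests up to 500 patients / ~8,000
  rows (seconds); acceptance Monte-Carlo 3 × 200 replications of 1,800-row
  fits plus a type-I calibration run (minutes on one CPU).

## 6. Limitations

* Residual correlation is assumed stationary and isotropic in centroid
  distance; sector-pair-specific correlation is not modelled.
* Model-based (not sandwich) standard errors; no small-sample df correction
  beyond the between-within F option.
* No boundary-corrected (mixture chi-square) LRT p-values; boundary cases
  are flagged instead.
* Eye-level variance is weakly identified in realistic regimes (§4).
* The formula syntax in the CLI is deliberately restricted to the terms the
  model supports (`covariate`, `sector`, `covariate:sector`,
  `covariate*sector`).
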
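# slme — spatial linear mixed effects models for sector-lattice profiles

`slme` fits linear mixed effects models to retinal-thickness measurements
laid out on the nine-sector ETDRS macular grid — or any small, fixed lattice
of named locations. It combines

* **nested random effects** — a random intercept per patient and, optionally,
  per eye within patient — with
* **a spatially correlated residual** across the sectors of one eye, using
  exponential, Gaussian, spherical or adjacency-lag (AR-style) correlation
  functions of inter-sector distance, and
* **group-specific residual scales** (heteroscedasticity by diagnosis group).

Ignoring the spatial correlation does not just lose efficiency: it biases the
standard errors of covariate effects, so confidence intervals under- or
over-cover and hypothesis tests are miscalibrated. The package includes a
Monte-Carlo study harness that quantifies exactly this, comparing the spatial
model against an ordinary (non-spatial) regression on identical data.

## The model

For patient *i*, eye *j*, sector *s*:

```
y_ijs = x_ijs' beta + b_i + u_ij + e_ijs
b_i   ~ N(0, sd_patient^2)         patient intercept
u_ij  ~ N(0, sd_eye^2)             eye-within-patient intercept
e_ij. ~ N(0, sd_resid^2 L C L)     spatially correlated residual vector
```

`C` is a 9×9 correlation matrix built from a parametric kernel on the
inter-sector distances (millimetres between sector centroids on the ETDRS
grid), and `L` is a diagonal matrix of per-group scale ratios (reference
group fixed at 1). All parameters are estimated jointly by maximum
likelihood or REML; fixed effects come from generalized least squares at the
estimated covariance, with model-based standard errors.

## Worked example

Generate a small synthetic clinic-style cohort (50 patients, up to two eyes
each, three diagnosis groups) and fit a two-level spatial model:

```python
from slme import (ClinicalSimConfig, CorrelationSpec, SlmeSpec,
                  fit, generate_clinical, wald_test)

data = generate_clinical(
    ClinicalSimConfig(n_healthy=10, n_m0=25, n_m1=15, seed=3))

spec = SlmeSpec(
    patient_effects=("age",),
    eye_effects=("group",),
    sector_effects=True,
    random_levels=("patient", "eye"),
    correlation=CorrelationSpec("exponential", 1.0),  # initial rate, per mm
)
f = fit(data, spec, method="REML", seed=0)

print(f.coef_table().head(6).to_string(float_format=lambda v: f"{v:.4f}"))
print("sd_patient =", round(f.theta.sd_patient, 3))
print("sd_eye     =", round(f.theta.sd_eye, 3))
print("sd_resid   =", round(f.theta.sd_resid, 3))
print("gamma      =", round(f.theta.gamma, 3))
print("REML loglik =", round(f.loglik, 2), " AIC =", round(f.aic, 2))
print(wald_test(f, "group[M1]"))
```

Output:

```
                estimate      se       z  p_value
Intercept       304.7453 13.2272 23.0393   0.0000
age              -0.2734  0.2196 -1.2452   0.2131
group[M1]         0.1873  7.0043  0.0267   0.9787
group[healthy]  -12.1680  7.9971 -1.5216   0.1281
sector[SI]       57.6119  2.1104 27.2991   0.0000
sector[TI]       44.6406  2.1104 21.1527   0.0000
sd_patient = 20.43
sd_eye     = 2.405
sd_resid   = 16.371
gamma      = 1.411
REML loglik = -3481.76  AIC = 6995.52
TestResult(wald: stat=0.02674, df=1, p=0.9787)
```

The estimated exponential rate (1.41 per mm) says residual correlation
between neighbouring sectors ~1 mm apart is about `exp(-1.41) ≈ 0.24` after
accounting for the shared patient and eye intercepts.

## Command-line interface

```bash
slme make-fixtures --preset small --seed 3 --out cohort.csv
slme fit --data cohort.csv \
     --fixed "thickness ~ age + group + sector" \
     --random patient/eye --correlation exponential --out fit.json
slme select --data cohort.csv \
     --fixed "thickness ~ age + group + sector"      # top-down selection
slme simulate --scenario 2 --reps 200 --seed 11 --out results/
```

`fit` writes a JSON report (estimates, SEs, variance components,
likelihoods, convergence diagnostics); `select` runs top-down selection of
the random structure, then the correlation family, then the fixed effects,
with a full audit trail; `simulate` runs one Monte-Carlo scenario and writes
its summary tables.

## The simulation study

Three scenarios share one truth (200 patients, one eye each, a 70/30
diagnosis split, a continuous risk factor with slope −0.3, a diagnosis main
effect of 6.1 µm, sector effects and a sector-by-diagnosis interaction) and
differ only in the residual correlation: none, exponential with rate 0.5
(moderate) and rate 0.1 (strong). Each replication is analysed by the
spatial model (REML) and by OLS on the identical design. The study tabulates
mean estimates, mean model SEs, Monte-Carlo SDs and 95%-CI coverage for the
two headline coefficients, plus the power of the joint "shape effect" test
(all sector-by-diagnosis interactions).

Expected pattern: both approaches stay unbiased, but the non-spatial model's
coverage for the patient-level coefficient collapses as the ignored
correlation strengthens, while the spatial model stays near the nominal 95%,
and the spatial shape-effect test is markedly more powerful.

## Package layout

| module | contents |
|---|---|
| `slme.grid` | ETDRS sector geometry, centroid distances, adjacency lags |
| `slme.kernels` | correlation functions and correlation-matrix builder |
| `slme.data` | long-format dataset container and schema validation |
| `slme.model` | model specification, design matrices, covariance assembly |
| `slme.likelihood` | blocked ML/REML likelihoods and GLS summaries |
| `slme.fitting` | optimisation, fitted-model object, BLUPs |
| `slme.inference` | Wald/F/LRT tests, information criteria, top-down selection |
| `slme.simulate` | Monte-Carlo study generator, runner and tables |
| `slme.clinical` | synthetic two-eye clinic-style cohort generator |
| `slme.cli` | `slme` command-line interface |

See `docs/methods.md` for the statistical and numerical details.
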
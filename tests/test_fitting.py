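"""Fitting engine: recovery, limits, boundaries, determinism, and agreement
with an independent mixed-model implementation (statsmodels MixedLM)."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from slme import (
    ClinicalSimConfig,
    SlmeSpec,
    fit,
    generate_clinical,
    predict_blups,
    scenario_config,
    simulate_dataset,
)
from slme.kernels import CorrelationSpec

from conftest import make_long


def _one_level_data(n_patients=80, seed=10, sd_b=6.0, sd_e=4.0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        b = rng.normal(0, sd_b)
        age = rng.uniform(30, 80)
        for i, s in enumerate(
                ("CS", "SI", "TI", "II", "NI", "SO", "TO", "IO", "NO")):
            y = 280 - 0.2 * age + 2.0 * i + b + rng.normal(0, sd_e)
            rows.append((f"P{p:03d}", "OD", s, y, {"age": age}))
    return make_long(rows)


def test_ols_limit_without_random_effects(grid):
    data = _one_level_data(25, seed=11, sd_b=0.0)
    spec = SlmeSpec(patient_effects=("age",), random_levels=())
    f = fit(data, spec, grid, method="ML", n_starts=1)
    from slme.model import build_design
    d = build_design(data, spec, grid)
    beta_ols, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
    rss = float(((d.y - d.X @ beta_ols) ** 2).sum())
    assert np.allclose(f.beta.to_numpy(), beta_ols, rtol=1e-5)
    assert f.theta.sd_resid**2 == pytest.approx(rss / d.n_obs, rel=1e-3)


def test_agrees_with_statsmodels_mixedlm(grid):
    # non-spatial, equal-weight, one-level random intercept: an independent
    # implementation must reproduce the REML fixed effects and SDs
    data = _one_level_data(60, seed=12)
    spec = SlmeSpec(patient_effects=("age",), random_levels=("patient",))
    f = fit(data, spec, grid, n_starts=1)
    md = smf.mixedlm("thickness ~ age + C(sector, Treatment('CS'))",
                     data.df, groups=data.df["patient_id"])
    mf = md.fit(reml=True, method="lbfgs")
    assert f.beta["Intercept"] == pytest.approx(mf.params["Intercept"],
                                                rel=1e-4)
    assert f.beta["age"] == pytest.approx(mf.params["age"], rel=1e-4)
    sd_b_sm = np.sqrt(float(mf.cov_re.iloc[0, 0]))
    sd_e_sm = np.sqrt(float(mf.scale))
    assert f.theta.sd_patient == pytest.approx(sd_b_sm, rel=1e-4)
    assert f.theta.sd_resid == pytest.approx(sd_e_sm, rel=1e-4)
    assert f.se["age"] == pytest.approx(float(mf.bse["age"]), rel=1e-3)


def test_nested_two_level_agrees_with_mixedlm(grid):
    cfg = ClinicalSimConfig(
        n_healthy=0, n_m0=40, n_m1=30, two_eye_prob=1.0,
        sd_patient=12.0, sd_eye=6.0, sd_resid=8.0, gamma_e=1.0,
        weight_ratios={"M0": 1.0, "M1": 1.0}, seed=13)
    data = generate_clinical(cfg)
    # independence residuals in BOTH fits (the generator's spatial
    # correlation is just part of the noise here)
    spec = SlmeSpec(patient_effects=("age",), eye_effects=("group",),
                    sector_effects=True,
                    random_levels=("patient", "eye"))
    f = fit(data, spec, grid, n_starts=2)
    df = data.df.copy()
    df["pe"] = df["patient_id"] + "/" + df["eye_id"]
    md = smf.mixedlm(
        "thickness ~ age + group + C(sector, Treatment('CS'))", df,
        groups=df["patient_id"], re_formula="1",
        vc_formula={"eye": "0 + C(pe)"})
    mf = md.fit(reml=True, method="lbfgs")
    assert f.beta["age"] == pytest.approx(mf.params["age"], rel=1e-3)
    assert f.beta["group[M1]"] == pytest.approx(mf.params["group[T.M1]"],
                                                rel=1e-3)
    sd_b_sm = np.sqrt(float(mf.cov_re.iloc[0, 0]))
    assert f.theta.sd_patient == pytest.approx(sd_b_sm, rel=1e-2)


def test_parameter_recovery_one_level_spatial(grid):
    # moderately large single draw: estimates land near the truth
    cfg = scenario_config(2, n_reps=1, base_seed=3).replace(
        n_patients=400, sd_random_intercept=5.0, sd_resid=10.0)
    data = simulate_dataset(cfg, 12345)
    spec = SlmeSpec(
        patient_effects=("risk_factor",), eye_effects=("group",),
        sector_effects=True, sector_by_eye=("group",),
        random_levels=("patient",),
        correlation=CorrelationSpec("exponential", 0.5))
    f = fit(data, spec, grid, n_starts=2)
    assert f.converged
    assert f.theta.sd_resid == pytest.approx(10.0, rel=0.10)
    assert f.theta.gamma == pytest.approx(0.5, rel=0.40)
    assert f.theta.sd_patient == pytest.approx(5.0, rel=0.50)
    assert f.beta["risk_factor"] == pytest.approx(-0.3, abs=0.08)


def test_zero_eye_variance_hits_boundary(grid):
    cfg = ClinicalSimConfig(
        n_healthy=0, n_m0=40, n_m1=30, two_eye_prob=1.0,
        sd_patient=10.0, sd_eye=0.0, sd_resid=6.0, gamma_e=1.0,
        weight_ratios={"M0": 1.0, "M1": 1.0}, seed=14)
    data = generate_clinical(cfg)
    spec = SlmeSpec(eye_effects=("group",), sector_effects=False,
                    random_levels=("patient", "eye"))
    f = fit(data, spec, grid, n_starts=1)
    assert f.theta.sd_eye < 0.05 * f.theta.sd_resid
    assert "log_sd_eye" in f.boundary_params


def test_fit_is_deterministic_given_seed(grid):
    data = _one_level_data(20, seed=15)
    spec = SlmeSpec(patient_effects=("age",), random_levels=("patient",),
                    correlation=CorrelationSpec("exponential", 0.5))
    f1 = fit(data, spec, grid, n_starts=3, seed=42)
    f2 = fit(data, spec, grid, n_starts=3, seed=42)
    assert np.array_equal(f1.beta.to_numpy(), f2.beta.to_numpy())
    assert f1.theta == f2.theta


def test_requires_two_patients(grid):
    data = make_long([("P1", "OD", "CS", 280.0)])
    with pytest.raises(ValueError, match="two patients"):
        fit(data, SlmeSpec(sector_effects=False), grid)


# ---------------------------------------------------------------------------
# BLUPs
# ---------------------------------------------------------------------------

def test_blups_match_one_way_shrinkage(grid):
    # patients with one eye and iid residuals: the patient BLUP is the
    # residual mean shrunk by sd_b^2 / (sd_b^2 + sd_s^2/9)
    data = _one_level_data(40, seed=16)
    spec = SlmeSpec(patient_effects=("age",),
                    random_levels=("patient",))
    f = fit(data, spec, grid, n_starts=1)
    b, u = predict_blups(f)
    resid = f.design.y - f.design.X @ f.beta.to_numpy()
    sb2, ss2 = f.theta.sd_patient**2, f.theta.sd_resid**2
    shrink = sb2 / (sb2 + ss2 / 9.0)
    for code, pid in enumerate(f.design.patient_ids):
        rbar = resid[f.design.patient_codes == code].mean()
        assert b[pid] == pytest.approx(shrink * rbar, rel=1e-8)
    assert abs(b.mean()) < 3.0 * b.std() / np.sqrt(len(b))
    assert len(u) == 0


def test_blups_vanish_without_patient_variance(grid):
    data = _one_level_data(15, seed=17)
    spec = SlmeSpec(patient_effects=("age",), random_levels=("patient",))
    f = fit(data, spec, grid, n_starts=1)
    from dataclasses import replace
    f.theta = replace(f.theta, sd_patient=1e-12)
    b, _ = predict_blups(f)
    assert np.allclose(b.to_numpy(), 0.0, atol=1e-12)


def test_blups_require_random_effects(grid):
    data = _one_level_data(10, seed=18)
    f = fit(data, SlmeSpec(patient_effects=("age",), random_levels=()),
            grid, n_starts=1)
    with pytest.raises(ValueError, match="no random effects"):
        predict_blups(f)
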
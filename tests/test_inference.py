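"""Wald tests, likelihood-ratio tests, information criteria and the
top-down model-selection driver."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slme import (
    SlmeSpec,
    fit,
    information_criteria,
    interaction_coefficients,
    lrt,
    scenario_config,
    simulate_dataset,
    top_down_select,
    wald_test,
)
from slme.fitting import FittedSlme
from slme.kernels import CorrelationSpec


def _mock_fit(beta: dict, cov: np.ndarray, method="ML", loglik=-10.0,
              p_fixed=None, n_theta=1, n_obs=100, spec=None) -> FittedSlme:
    names = list(beta)
    p_fixed = len(names) if p_fixed is None else p_fixed
    return FittedSlme(
        spec=spec or SlmeSpec(),
        method=method,
        beta=pd.Series(beta),
        cov_beta=pd.DataFrame(cov, index=names, columns=names),
        theta=None,
        loglik=loglik, loglik_ml=loglik, loglik_reml=loglik,
        n_obs=n_obs, p_fixed=p_fixed, n_theta=n_theta,
        aic=np.nan, bic=np.nan,
        converged=True, n_iter=1, final_gradient_norm=0.0,
        boundary_params=[],
    )


def test_wald_single_coefficient_z():
    f = _mock_fit({"Intercept": 0.0, "age": 2.0}, np.eye(2))
    res = wald_test(f, "age")
    assert res.statistic == pytest.approx(2.0)
    assert res.p_value == pytest.approx(2 * stats.norm.sf(2.0))
    assert res.test_kind == "wald"
    assert list(res.effects.index) == ["age"]


def test_wald_joint_chi_square():
    f = _mock_fit({"a": 1.0, "b": 2.0}, np.eye(2))
    res = wald_test(f, ["a", "b"])
    assert res.statistic == pytest.approx(5.0)  # 1^2 + 2^2
    assert res.df == 2
    assert res.p_value == pytest.approx(stats.chi2.sf(5.0, 2))


def test_wald_accounts_for_correlation():
    # perfectly known covariance: W = b' V^-1 b
    V = np.array([[1.0, 0.5], [0.5, 1.0]])
    b = np.array([1.0, 1.0])
    f = _mock_fit({"a": 1.0, "b": 1.0}, V)
    expected = float(b @ np.linalg.solve(V, b))
    assert wald_test(f, ["a", "b"]).statistic == pytest.approx(expected)


def test_wald_f_variant():
    f = _mock_fit({"a": 1.0, "b": 2.0}, np.eye(2))
    res = wald_test(f, ["a", "b"], kind="f", ddf=10)
    assert res.statistic == pytest.approx(2.5)  # 5 / 2
    assert res.df == (2, 10)
    assert res.p_value == pytest.approx(stats.f.sf(2.5, 2, 10))


def test_coefficient_prefix_selection():
    f = _mock_fit({"Intercept": 1.0, "sector[SI]": 0.1,
                   "sector[SI]:group[M1]": 0.2,
                   "sector[SO]:group[M1]": 0.3}, np.eye(4))
    res = wald_test(f, "sector[")
    assert res.df == 3
    with pytest.raises(KeyError, match="no coefficient matching"):
        wald_test(f, "bmi")


def test_interaction_coefficient_names():
    f = _mock_fit({"Intercept": 1.0, "group[M1]": 0.5,
                   "sector[SI]": 0.1, "sector[SI]:group[M1]": 0.2,
                   "sector[SO]:group[M1]": 0.3,
                   "sector[SO]:age": 0.4}, np.eye(6))
    assert interaction_coefficients(f, "group") == [
        "sector[SI]:group[M1]", "sector[SO]:group[M1]"]
    assert interaction_coefficients(f, "age") == ["sector[SO]:age"]


def test_lrt_identical_models_is_null():
    f = _mock_fit({"a": 1.0}, np.eye(1), loglik=-20.0)
    res = lrt(f, f)
    assert res.statistic == 0.0
    assert res.df == 0
    assert res.p_value == 1.0


def test_lrt_chi_square_reference():
    spec_f = SlmeSpec(random_levels=("patient", "eye"))
    spec_r = SlmeSpec(random_levels=("patient",))
    full = _mock_fit({"a": 1.0}, np.eye(1), loglik=-17.0, n_theta=3,
                     spec=spec_f)
    red = _mock_fit({"a": 1.0}, np.eye(1), loglik=-20.0, n_theta=2,
                    spec=spec_r)
    res = lrt(full, red)
    assert res.statistic == pytest.approx(6.0)
    assert res.df == 1
    assert res.p_value == pytest.approx(stats.chi2.sf(6.0, 1))
    assert any("boundary" in n for n in res.notes)


def test_lrt_clips_negative_statistic():
    full = _mock_fit({"a": 1.0}, np.eye(1), loglik=-21.0, n_theta=2)
    red = _mock_fit({"a": 1.0}, np.eye(1), loglik=-20.0, n_theta=1)
    assert lrt(full, red).statistic == 0.0


def test_lrt_rejects_mixed_objectives_and_designs():
    ml = _mock_fit({"a": 1.0}, np.eye(1), method="ML")
    reml = _mock_fit({"a": 1.0}, np.eye(1), method="REML")
    with pytest.raises(ValueError, match="same estimation method"):
        lrt(ml, reml)
    r2 = _mock_fit({"a": 1.0, "b": 2.0}, np.eye(2), method="REML",
                   n_theta=2)
    with pytest.raises(ValueError, match="identical"):
        lrt(r2, reml)


def test_information_criteria_closed_form():
    # l = -10, p = 2 fixed + 1 variance = 3: AIC = 20 + 6 = 26
    f = _mock_fit({"a": 1.0, "b": 2.0}, np.eye(2), loglik=-10.0,
                  n_theta=1, n_obs=100, method="ML")
    aic, bic = information_criteria(f)
    assert aic == pytest.approx(26.0)
    assert bic == pytest.approx(20.0 + 3 * np.log(100))
    _, bic2 = information_criteria(f, paper_variant=True)
    assert bic2 == pytest.approx(20.0 + 6 * np.log(100))


def test_information_criteria_reml_effective_n():
    f = _mock_fit({"a": 1.0, "b": 2.0}, np.eye(2), loglik=-10.0,
                  n_theta=1, n_obs=100, method="REML")
    _, bic = information_criteria(f)
    assert bic == pytest.approx(20.0 + 3 * np.log(98))


def test_top_down_select_recovers_spatial_structure(grid):
    # strongly correlated residuals, no random intercept in truth: the
    # driver must keep a spatial family over independence
    cfg = scenario_config(3, n_reps=1, base_seed=9).replace(
        n_patients=80, sd_random_intercept=4.0)
    data = simulate_dataset(cfg, 777, grid)
    saturated = SlmeSpec(
        patient_effects=("risk_factor",), eye_effects=("group",),
        sector_effects=True, sector_by_eye=("group",))
    report, final = top_down_select(
        data, saturated,
        candidate_random=[("patient",)],
        candidate_correlations=[CorrelationSpec("independence"),
                                CorrelationSpec("exponential", 0.5)],
        grid=grid, n_starts=1,
    )
    stages = {s["stage"]: s for s in report["stages"]}
    assert stages["random_effects"]["winner"] == "random=patient"
    assert stages["correlation"]["winner"] == "exponential"
    assert final.converged
    assert final.method == "REML"
    assert final.spec.correlation.family == "exponential"


def test_top_down_select_audit_trail(grid):
    cfg = scenario_config(1, n_reps=1, base_seed=10).replace(n_patients=30)
    data = simulate_dataset(cfg, 5, grid)
    saturated = SlmeSpec(patient_effects=("risk_factor",),
                         eye_effects=("group",), sector_effects=True)
    reduced = SlmeSpec(patient_effects=("risk_factor",),
                       eye_effects=("group",), sector_effects=False)
    report, final = top_down_select(
        data, saturated,
        candidate_random=[(), ("patient",)],
        candidate_correlations=[CorrelationSpec("independence")],
        candidate_fixed=[saturated, reduced],
        grid=grid, n_starts=1, criterion="bic",
    )
    assert report["criterion"] == "bic"
    assert [s["stage"] for s in report["stages"]] == [
        "random_effects", "correlation", "fixed_effects"]
    for stage in report["stages"]:
        for cand in stage["candidates"]:
            assert "fitted" not in cand  # serialisable audit records
            assert {"label", "aic", "bic", "converged"} <= set(cand)
    assert "spec" in report["final"]
    with pytest.raises(ValueError, match="criterion"):
        top_down_select(data, saturated, [()],
                        [CorrelationSpec("independence")],
                        grid=grid, criterion="waic")
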
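"""Hypothesis tests and model selection for fitted models.

Wald tests use the GLS sampling covariance (X'H^-1X)^-1 of the fixed
effects; joint tests are chi-square with one degree of freedom per
coefficient by default, with an F variant whose denominator degrees of
freedom follow a between-within style count at the eye level.  Likelihood
ratio tests compare nested fits on the same objective; when a variance
component is tested on its boundary the naive chi-square reference is
conservative, which is flagged rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FittedSlme, fit
from .model import SlmeSpec


@dataclass
class TestResult:
    statistic: float
    df: float | tuple
    p_value: float
    test_kind: str  # wald | f | lrt
    effects: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def __repr__(self):
        return (f"TestResult({self.test_kind}: stat={self.statistic:.4g}, "
                f"df={self.df}, p={self.p_value:.4g})")


def _select_coefficients(fitted: FittedSlme, coefficients) -> list[str]:
    if isinstance(coefficients, str):
        coefficients = [coefficients]
    names = list(fitted.beta.index)
    chosen = []
    for c in coefficients:
        if c in names:
            chosen.append(c)
        else:
            matches = [n for n in names if n.startswith(c)]
            if not matches:
                raise KeyError(f"no coefficient matching {c!r}")
            chosen.extend(matches)
    # preserve design order, drop duplicates
    return [n for n in names if n in set(chosen)]


def interaction_coefficients(fitted: FittedSlme, covariate: str) -> list[str]:
    """Names of all sector-by-``covariate`` interaction coefficients — the
    'shape effect' coefficient set for that covariate."""
    return [
        n for n in fitted.beta.index
        if n.startswith("sector[") and f":{covariate}[" in n
        or (n.startswith("sector[") and n.endswith(f":{covariate}"))
    ]


def _bw_denominator_df(fitted: FittedSlme) -> int:
    """Between-within style denominator df, counted at the eye level."""
    n_eyes = len(fitted.design.eye_ids)
    return max(int(fitted.n_obs - n_eyes - fitted.p_fixed + 1), 1)


def wald_test(fitted: FittedSlme, coefficients, kind: str = "wald",
              ddf: int | None = None) -> TestResult:
    """Test that a (set of) fixed-effect coefficient(s) is zero.

    ``kind='wald'`` gives z / chi-square references; ``kind='f'`` divides the
    chi-square statistic by its df and refers it to an F distribution.
    """
    names = _select_coefficients(fitted, coefficients)
    if not names:
        raise ValueError("empty coefficient set")
    b = fitted.beta[names].to_numpy()
    V = fitted.cov_beta.loc[names, names].to_numpy()
    effects = pd.DataFrame({"estimate": fitted.beta[names],
                            "se": fitted.se[names]})
    if len(names) == 1 and kind == "wald":
        z = b[0] / np.sqrt(V[0, 0])
        return TestResult(float(z), 1, float(2 * stats.norm.sf(abs(z))),
                          "wald", effects)
    try:
        W = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular covariance sub-matrix in Wald test") from None
    q = len(names)
    if kind == "f":
        den = ddf if ddf is not None else _bw_denominator_df(fitted)
        F = W / q
        return TestResult(float(F), (q, den),
                          float(stats.f.sf(F, q, den)), "f", effects)
    return TestResult(W, q, float(stats.chi2.sf(W, q)), "wald", effects)


def lrt(fitted_full: FittedSlme, fitted_reduced: FittedSlme) -> TestResult:
    """Likelihood ratio test of a reduced model nested in a full model.

    Both fits must use the same objective; REML comparisons additionally
    require identical fixed-effect designs.  The statistic is clipped at
    zero; a note flags boundary-tested variance components (naive chi-square
    is conservative there).
    """
    if fitted_full.method != fitted_reduced.method:
        raise ValueError("both fits must use the same estimation method")
    if fitted_full.method == "REML":
        if list(fitted_full.beta.index) != list(fitted_reduced.beta.index):
            raise ValueError(
                "REML likelihoods are only comparable for identical "
                "fixed-effects designs"
            )
    df = fitted_full.p_total - fitted_reduced.p_total
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'reduced'")
    stat = max(2.0 * (fitted_full.loglik - fitted_reduced.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    notes = []
    full_levels = set(fitted_full.spec.random_levels)
    red_levels = set(fitted_reduced.spec.random_levels)
    if full_levels != red_levels:
        notes.append(
            "variance component tested on its boundary: the chi-square "
            "reference is conservative"
        )
    return TestResult(stat, df, p, "lrt", notes=notes)


def information_criteria(fitted: FittedSlme,
                         paper_variant: bool = False) -> tuple[float, float]:
    """(AIC, BIC) with p = dim(beta) + dim(theta).

    BIC uses p*log(n_eff) with n_eff = n (ML) or n - p_fixed (REML); the
    ``paper_variant`` switch doubles the BIC penalty to 2p*log(n_eff).
    """
    p = fitted.p_total
    ll = fitted.loglik
    n_eff = (fitted.n_obs - fitted.p_fixed if fitted.method == "REML"
             else fitted.n_obs)
    aic = -2.0 * ll + 2.0 * p
    mult = 2.0 if paper_variant else 1.0
    bic = -2.0 * ll + mult * p * np.log(n_eff)
    return float(aic), float(bic)


# ---------------------------------------------------------------------------
# top-down model selection
# ---------------------------------------------------------------------------

def _fit_entry(dataset, spec, grid, method, label, **fit_kw):
    try:
        f = fit(dataset, spec, grid=grid, method=method, **fit_kw)
        return {"label": label, "fitted": f, "aic": f.aic, "bic": f.bic,
                "loglik": f.loglik, "converged": f.converged, "error": None}
    except Exception as e:  # noqa: BLE001 - candidates may legitimately fail
        return {"label": label, "fitted": None, "aic": np.inf, "bic": np.inf,
                "loglik": -np.inf, "converged": False, "error": str(e)}


def _strip(entries):
    return [{k: v for k, v in e.items() if k != "fitted"} for e in entries]


def top_down_select(
    dataset,
    saturated_spec: SlmeSpec,
    candidate_random: list[tuple[str, ...]],
    candidate_correlations: list,
    candidate_fixed: list[SlmeSpec] | None = None,
    grid=None,
    criterion: str = "aic",
    **fit_kw,
):
    """Top-down model selection.

    1. fit the saturated fixed effects with an independence structure,
    2. choose the random-effect levels by REML AIC/BIC (with LRTs recorded),
    3. choose the residual correlation family by REML AIC/BIC,
    4. reduce the fixed effects by ML AIC/BIC among the supplied nested
       candidates, then refit the winner by REML.

    Returns (report, fitted): a stage-by-stage audit trail and the final fit.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    from .kernels import CorrelationSpec

    report = {"criterion": criterion, "stages": []}

    # stage 2: random structure under saturated fixed + independence (REML)
    indep = CorrelationSpec("independence")
    entries = []
    for levels in candidate_random:
        spec = saturated_spec.replace(random_levels=tuple(levels),
                                      correlation=indep)
        entries.append(_fit_entry(dataset, spec, grid, "REML",
                                  f"random={'+'.join(levels) or 'none'}",
                                  **fit_kw))
    best_rand = min(entries, key=lambda e: e[criterion])
    report["stages"].append({"stage": "random_effects",
                             "candidates": _strip(entries),
                             "winner": best_rand["label"]})
    if best_rand["fitted"] is None:
        raise RuntimeError("all random-structure candidates failed to fit")
    chosen_random = best_rand["fitted"].spec.random_levels

    # stage 3: correlation family (REML, same fixed effects)
    entries = []
    for corr in candidate_correlations:
        spec = saturated_spec.replace(random_levels=chosen_random,
                                      correlation=corr)
        entries.append(_fit_entry(dataset, spec, grid, "REML",
                                  corr.family, **fit_kw))
    best_corr = min(entries, key=lambda e: e[criterion])
    report["stages"].append({"stage": "correlation",
                             "candidates": _strip(entries),
                             "winner": best_corr["label"]})
    if best_corr["fitted"] is None:
        raise RuntimeError("all correlation candidates failed to fit")
    chosen_corr = best_corr["fitted"].spec.correlation

    # stage 4: fixed-effect reduction (ML)
    final_spec = saturated_spec.replace(random_levels=chosen_random,
                                        correlation=chosen_corr)
    if candidate_fixed:
        entries = []
        for i, cand in enumerate(candidate_fixed):
            spec = cand.replace(random_levels=chosen_random,
                                correlation=chosen_corr)
            entries.append(_fit_entry(dataset, spec, grid, "ML",
                                      f"fixed_{i}", **fit_kw))
        best_fixed = min(entries, key=lambda e: e[criterion])
        report["stages"].append({"stage": "fixed_effects",
                                 "candidates": _strip(entries),
                                 "winner": best_fixed["label"]})
        if best_fixed["fitted"] is not None:
            final_spec = best_fixed["fitted"].spec

    final = fit(dataset, final_spec, grid=grid, method="REML", **fit_kw)
    report["final"] = {"aic": final.aic, "bic": final.bic,
                       "converged": final.converged,
                       "spec": final_spec.to_dict()}
    return report, final
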
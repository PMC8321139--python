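"""Variance-component optimisation and the fitted-model container.

The ML or REML objective is maximised over an unconstrained transform of the
variance parameters: natural logs of the random-effect SDs, the residual SD,
the kernel decay rate and the heteroscedasticity ratios, and the logit of the
AR coefficient (which lives in (0,1)).  A bounded quasi-Newton optimiser
(L-BFGS-B with finite-difference gradients) is run from a moment-based start
plus jittered restarts; estimates sitting on a transform bound (e.g. a
random-effect SD collapsing to zero) are reported via ``boundary_params``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .data import LongDataset
from .grid import SectorGrid, build_sector_grid
from .likelihood import (
    BlockStructure,
    compute_summaries,
    loglik_reml_summaries,
    profiled_loglik_ml,
    profiled_loglik_reml,
)
from .model import SlmeSpec, VarianceComponents, build_design

# bounds on the transformed scale; values at a bound are flagged
_LOG_SD_BOUNDS = (-8.0, 10.0)
_LOG_GAMMA_BOUNDS = (-8.0, 6.0)
_LOGIT_AR_BOUNDS = (-10.0, 10.0)
_LOG_LAM_BOUNDS = (-5.0, 5.0)


class ThetaMap:
    """Pack/unpack the active variance parameters for a given model."""

    def __init__(self, spec: SlmeSpec, weight_levels: list | None):
        self.spec = spec
        self.names: list[str] = []
        self.bounds: list[tuple[float, float]] = []
        if spec.has_patient_re:
            self.names.append("log_sd_patient")
            self.bounds.append(_LOG_SD_BOUNDS)
        if spec.has_eye_re:
            self.names.append("log_sd_eye")
            self.bounds.append(_LOG_SD_BOUNDS)
        self.names.append("log_sd_resid")
        self.bounds.append(_LOG_SD_BOUNDS)
        self.ar = spec.correlation.family == "ar_lag"
        if spec.correlation.has_parameter:
            self.names.append("logit_gamma" if self.ar else "log_gamma")
            self.bounds.append(_LOGIT_AR_BOUNDS if self.ar
                               else _LOG_GAMMA_BOUNDS)
        self.weight_levels = weight_levels
        if weight_levels is not None:
            # first level is the reference, fixed at 1
            for lvl in weight_levels[1:]:
                self.names.append(f"log_lam[{lvl}]")
                self.bounds.append(_LOG_LAM_BOUNDS)

    @property
    def n_params(self) -> int:
        return len(self.names)

    def pack(self, theta: VarianceComponents) -> np.ndarray:
        x = []
        for name in self.names:
            if name == "log_sd_patient":
                x.append(np.log(theta.sd_patient))
            elif name == "log_sd_eye":
                x.append(np.log(theta.sd_eye))
            elif name == "log_sd_resid":
                x.append(np.log(theta.sd_resid))
            elif name == "log_gamma":
                x.append(np.log(theta.gamma))
            elif name == "logit_gamma":
                x.append(logit(theta.gamma))
            else:  # log_lam[...]
                lvl = name[len("log_lam["):-1]
                x.append(np.log(theta.weight_ratios[lvl]))
        return np.array(x)

    def unpack(self, x: np.ndarray) -> VarianceComponents:
        kw = dict(sd_patient=0.0, sd_eye=0.0, sd_resid=1.0, gamma=None,
                  weight_ratios=None)
        ratios = None
        if self.weight_levels is not None:
            ratios = {self.weight_levels[0]: 1.0}
        for name, xi in zip(self.names, x):
            if name == "log_sd_patient":
                kw["sd_patient"] = float(np.exp(xi))
            elif name == "log_sd_eye":
                kw["sd_eye"] = float(np.exp(xi))
            elif name == "log_sd_resid":
                kw["sd_resid"] = float(np.exp(xi))
            elif name == "log_gamma":
                kw["gamma"] = float(np.exp(xi))
            elif name == "logit_gamma":
                kw["gamma"] = float(expit(xi))
            else:
                ratios[name[len("log_lam["):-1]] = float(np.exp(xi))
        kw["weight_ratios"] = ratios
        return VarianceComponents(**kw)


@dataclass
class FittedSlme:
    """Estimates, uncertainties, likelihoods and diagnostics of one fit."""

    spec: SlmeSpec
    method: str
    beta: pd.Series
    cov_beta: pd.DataFrame
    theta: VarianceComponents
    loglik: float  # value of the objective that was maximised
    loglik_ml: float
    loglik_reml: float
    n_obs: int
    p_fixed: int
    n_theta: int
    aic: float
    bic: float
    converged: bool
    n_iter: int
    final_gradient_norm: float
    boundary_params: list[str]
    grid: SectorGrid = field(repr=False, default=None)
    design: object = field(repr=False, default=None)
    structure: object = field(repr=False, default=None)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_beta.to_numpy())),
                         index=self.beta.index)

    @property
    def p_total(self) -> int:
        return self.p_fixed + self.n_theta

    def coef_table(self) -> pd.DataFrame:
        from scipy import stats
        se = self.se
        z = self.beta / se
        return pd.DataFrame({
            "estimate": self.beta,
            "se": se,
            "z": z,
            "p_value": 2 * stats.norm.sf(np.abs(z)),
        })

    def to_report(self) -> dict:
        return {
            "schema_version": 1,
            "method": self.method,
            "n_obs": self.n_obs,
            "fixed_effects": {
                name: {"estimate": float(b), "se": float(s)}
                for name, b, s in zip(self.beta.index, self.beta, self.se)
            },
            "variance_components": self.theta.to_dict(),
            "loglik": self.loglik,
            "loglik_ml": self.loglik_ml,
            "loglik_reml": self.loglik_reml,
            "aic": self.aic,
            "bic": self.bic,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "final_gradient_norm": float(self.final_gradient_norm),
            "boundary_params": list(self.boundary_params),
            "spec": self.spec.to_dict(),
        }


def _initial_theta(design, spec: SlmeSpec, grid: SectorGrid,
                   tm: ThetaMap) -> VarianceComponents:
    """Moment-based starting values: OLS residual spread split across the
    levels, kernel rate from the median pairwise distance."""
    X, y = design.X, design.y
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta0
    s_tot = max(float(e.std()), 1e-3)
    df = pd.DataFrame({
        "e": e,
        "pat": design.patient_codes,
        "eye": design.eye_codes,
    })
    pat_means = df.groupby("pat")["e"].mean()
    eye_means = df.groupby(["pat", "eye"])["e"].mean()
    sd_b = max(float(np.nan_to_num(pat_means.std())), 0.1 * s_tot)
    dev = eye_means - pat_means.reindex(
        eye_means.index.get_level_values(0)).to_numpy()
    sd_u = max(float(np.nan_to_num(dev.std())), 0.1 * s_tot)
    gamma0 = None
    if spec.correlation.has_parameter:
        if tm.ar:
            gamma0 = 0.5
        else:
            d = grid.distance_matrix
            off = d[np.triu_indices_from(d, k=1)]
            gamma0 = float(np.log(2.0) / np.median(off))
            if spec.correlation.family == "gaussian":
                gamma0 = gamma0 / float(np.median(off))
    ratios = None
    if tm.weight_levels is not None:
        ratios = {l: 1.0 for l in tm.weight_levels}
    return VarianceComponents(
        sd_patient=sd_b if spec.has_patient_re else 0.0,
        sd_eye=sd_u if spec.has_eye_re else 0.0,
        sd_resid=0.8 * s_tot,
        gamma=gamma0,
        weight_ratios=ratios,
    )


def fit(
    dataset: LongDataset,
    spec: SlmeSpec,
    grid: SectorGrid | None = None,
    method: str = "REML",
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FittedSlme:
    """Fit the model by maximising the ML or REML objective.

    ``n_starts`` controls the number of jittered optimiser restarts (the
    first start is moment-based); ``seed`` makes the jitter reproducible.
    Non-convergence is reported through ``converged``, not raised.
    """
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    if dataset.n_patients < 2:
        raise ValueError("need at least two patients to fit")
    grid = grid or build_sector_grid()
    design = build_design(dataset, spec, grid)
    structure = BlockStructure(design)
    tm = ThetaMap(spec, design.weight_levels)
    objective_fn = (profiled_loglik_reml if method == "REML"
                    else profiled_loglik_ml)

    def neg_obj(x: np.ndarray) -> float:
        try:
            theta = tm.unpack(x)
            return -objective_fn(theta, spec, grid, structure)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return 1e15

    x0 = tm.pack(_initial_theta(design, spec, grid, tm))
    x0 = np.clip(x0, [b[0] + 0.5 for b in tm.bounds],
                 [b[1] - 0.5 for b in tm.bounds])
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, 0.5, size=len(x0))
        xs = np.clip(xs, [b[0] for b in tm.bounds], [b[1] for b in tm.bounds])
        res = minimize(
            neg_obj, xs, method="L-BFGS-B", bounds=tm.bounds,
            options={
                "maxiter": max_iter,
                "ftol": tol * 1e-2,
                "gtol": 1e-6,
                "eps": 1e-6,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = tm.unpack(best.x)
    s = compute_summaries(theta_hat, spec, grid, structure)
    beta_hat = s.beta_hat()
    cov = s.cov_beta()
    quad = s.YtHiY - float(beta_hat @ s.XtHiY)
    ll_ml = -0.5 * (s.logdet + quad + s.n_obs * np.log(2 * np.pi))
    ll_reml = loglik_reml_summaries(s, structure.p)
    ll = ll_reml if method == "REML" else ll_ml

    # A parameter is "on the boundary" if it sits on a transform bound, or
    # if a random-effect SD has collapsed to a negligible fraction of the
    # residual SD (the optimum is effectively at variance zero even when the
    # log-scale estimate stalls short of the hard bound).
    log_collapse = np.log(theta_hat.sd_resid) + np.log(1e-3)
    boundary = [
        name for name, xi, (lo, hi) in zip(tm.names, best.x, tm.bounds)
        if (xi - lo < 1e-3 or hi - xi < 1e-3
            or (name in ("log_sd_patient", "log_sd_eye")
                and xi < log_collapse))
    ]
    p_fixed, n_theta = design.p, tm.n_params
    p_total = p_fixed + n_theta
    n_eff = s.n_obs - p_fixed if method == "REML" else s.n_obs
    fitted = FittedSlme(
        spec=spec,
        method=method,
        beta=pd.Series(beta_hat, index=design.colnames),
        cov_beta=pd.DataFrame(cov, index=design.colnames,
                              columns=design.colnames),
        theta=theta_hat,
        loglik=ll,
        loglik_ml=ll_ml,
        loglik_reml=ll_reml,
        n_obs=s.n_obs,
        p_fixed=p_fixed,
        n_theta=n_theta,
        aic=-2.0 * ll + 2.0 * p_total,
        bic=-2.0 * ll + p_total * np.log(n_eff),
        converged=bool(best.success),
        n_iter=int(best.nit),
        final_gradient_norm=float(np.max(np.abs(best.jac))),
        boundary_params=boundary,
        grid=grid,
        design=design,
        structure=structure,
    )
    return fitted


def predict_blups(fitted: FittedSlme):
    """Empirical-Bayes predictions of the random intercepts.

    Returns (b, u): patient-level BLUPs indexed by patient id, and eye-level
    BLUPs indexed by (patient id, eye id).  Each is the conditional mean of
    the random effect given the data at the plugged-in estimates, i.e. a
    variance-ratio shrinkage of the block residual:
    b_i = sd_patient^2 * 1' H_i^-1 (y_i - X_i beta_hat).
    """
    spec, design = fitted.spec, fitted.design
    if not spec.has_patient_re and not spec.has_eye_re:
        raise ValueError("model has no random effects to predict")
    from .likelihood import _lam_by_level, _theta_correlation
    from .model import block_covariance

    theta = fitted.theta
    C = _theta_correlation(theta, spec, fitted.grid)
    lam_levels = _lam_by_level(theta, design)
    resid_all = design.y - design.X @ fitted.beta.to_numpy()
    b = {}
    u = {}
    for g in fitted.structure.groups:
        lam = None if lam_levels is None else lam_levels[g.weight_codes]
        H = block_covariance(theta, spec, C, g.sector_idx, g.eye_local, lam)
        Hinv_r = np.linalg.solve(H, resid_all[g.rows].T)  # (n, q)
        sums = Hinv_r.sum(axis=0)  # (q,)
        for j, pcode in enumerate(g.patient_codes):
            pid = design.patient_ids[pcode]
            if spec.has_patient_re:
                b[pid] = theta.sd_patient**2 * float(sums[j])
            if spec.has_eye_re:
                for eye in np.unique(g.eye_local):
                    mask = g.eye_local == eye
                    ecode = design.eye_codes[g.rows[j][mask][0]]
                    key = design.eye_ids[ecode]
                    u[key] = theta.sd_eye**2 * float(
                        Hinv_r[mask, j].sum())
    b_s = pd.Series(b, name="blup_patient") if b else pd.Series(dtype=float)
    u_s = pd.Series(u, name="blup_eye") if u else pd.Series(dtype=float)
    if len(u_s):
        u_s.index = pd.MultiIndex.from_tuples(
            u_s.index, names=["patient_id", "eye_id"])
    return b_s, u_s
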
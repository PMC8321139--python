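"""Model specification, design construction, and marginal covariance assembly.

The mean model partitions the fixed effects as

    x'b = b0 + b1*x_patient + b2*x_eye + b3*sector
          + b4*sector:x_patient + b5*sector:x_eye

with the reference sector (central subfield by default) as the sector
baseline.  The marginal covariance of one patient's stacked observations is

    H_i = sd_patient^2 * J  +  blockdiag_eyes( sd_eye^2 * J_eye )
          + sd_resid^2 * Lambda C_sub Lambda  (within-eye only)

where C_sub is the kernel correlation restricted to the eye's observed
sectors and Lambda holds optional per-group heteroscedasticity multipliers on
the residual standard deviation (reference group fixed at 1).  Patients are
independent, so H is block-diagonal across patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import LongDataset, SchemaError
from .grid import SectorGrid
from .kernels import CorrelationSpec, correlation_matrix


@dataclass(frozen=True)
class SlmeSpec:
    """Which fixed effects, random levels, correlation family and variance
    weights define the model."""

    response: str = "thickness"
    patient_effects: tuple[str, ...] = ()
    eye_effects: tuple[str, ...] = ()
    sector_effects: bool = True
    sector_by_patient: tuple[str, ...] = ()
    sector_by_eye: tuple[str, ...] = ()
    random_levels: tuple[str, ...] = ("patient", "eye")
    correlation: CorrelationSpec = field(default_factory=CorrelationSpec)
    variance_weights_by: str | None = None
    reference_group: str | None = None
    reference_sector: str = "CS"

    def __post_init__(self):
        bad = set(self.random_levels) - {"patient", "eye"}
        if bad:
            raise ValueError(f"unknown random levels: {sorted(bad)}")
        if "eye" in self.random_levels and "patient" not in self.random_levels:
            raise ValueError("eye random effects require the patient level")

    @property
    def has_patient_re(self) -> bool:
        return "patient" in self.random_levels

    @property
    def has_eye_re(self) -> bool:
        return "eye" in self.random_levels

    def replace(self, **kw) -> "SlmeSpec":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = {
            "response": self.response,
            "patient_effects": list(self.patient_effects),
            "eye_effects": list(self.eye_effects),
            "sector_effects": self.sector_effects,
            "sector_by_patient": list(self.sector_by_patient),
            "sector_by_eye": list(self.sector_by_eye),
            "random_levels": list(self.random_levels),
            "correlation": self.correlation.to_dict(),
            "variance_weights_by": self.variance_weights_by,
            "reference_group": self.reference_group,
            "reference_sector": self.reference_sector,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SlmeSpec":
        d = dict(d)
        d["correlation"] = CorrelationSpec.from_dict(d["correlation"])
        for k in ("patient_effects", "eye_effects", "sector_by_patient",
                  "sector_by_eye", "random_levels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class VarianceComponents:
    """theta: random-effect SDs, residual SD, kernel parameter, and
    per-group residual-SD multipliers (reference fixed at 1)."""

    sd_patient: float = 0.0
    sd_eye: float = 0.0
    sd_resid: float = 1.0
    gamma: float | None = None
    weight_ratios: dict | None = None

    def __post_init__(self):
        if self.sd_patient < 0 or self.sd_eye < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        if self.sd_resid <= 0:
            raise ValueError("sd_resid must be positive")
        if self.weight_ratios is not None:
            if any(v <= 0 for v in self.weight_ratios.values()):
                raise ValueError("weight ratios must be positive")

    def to_dict(self) -> dict:
        return {
            "sd_patient": self.sd_patient,
            "sd_eye": self.sd_eye,
            "sd_resid": self.sd_resid,
            "gamma": self.gamma,
            "weight_ratios": dict(self.weight_ratios or {}),
        }


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _encode(df: pd.DataFrame, col: str):
    """Numeric column -> itself; categorical -> baseline-dropped dummies."""
    s = df[col]
    if pd.api.types.is_numeric_dtype(s) and not isinstance(
        s.dtype, pd.CategoricalDtype
    ):
        return [(col, s.to_numpy(float))]
    if isinstance(s.dtype, pd.CategoricalDtype):
        levels = list(s.cat.categories)
    else:
        levels = sorted(pd.unique(s.dropna()))
    base = levels[0]
    return [
        (f"{col}[{lvl}]", (s == lvl).to_numpy(float))
        for lvl in levels
        if lvl != base
    ]


@dataclass
class DesignMatrices:
    """Fixed-effect design plus row-aligned grouping codes."""

    X: np.ndarray  # (N, p)
    colnames: list[str]
    y: np.ndarray  # (N,)
    patient_codes: np.ndarray  # (N,) int, dense codes
    eye_codes: np.ndarray  # (N,) int, dense codes (global, nested)
    sector_idx: np.ndarray  # (N,) int index into grid.sector_ids
    weight_levels: list | None  # ordered levels of the weight factor
    weight_codes: np.ndarray | None  # (N,) int index into weight_levels
    patient_ids: list  # code -> original id
    eye_ids: list  # code -> (patient_id, eye_id)
    row_index: pd.Index  # original dataframe index of retained rows
    n_dropped: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def incidence_patient(self) -> np.ndarray:
        """0/1 patient random-intercept incidence matrix (N x m)."""
        Z = np.zeros((self.n_obs, len(self.patient_ids)))
        Z[np.arange(self.n_obs), self.patient_codes] = 1.0
        return Z

    def incidence_eye(self) -> np.ndarray:
        """0/1 eye random-intercept incidence matrix (N x n_eyes)."""
        D = np.zeros((self.n_obs, len(self.eye_ids)))
        D[np.arange(self.n_obs), self.eye_codes] = 1.0
        return D


def build_design(dataset: LongDataset, spec: SlmeSpec, grid: SectorGrid
                 ) -> DesignMatrices:
    """Build X and grouping codes for the Eq.-style partitioned mean model.

    Rows with missing values in any used covariate are dropped with a
    warning (no silent imputation).
    """
    dataset.check_sectors(grid)
    if spec.reference_sector not in grid.sector_ids:
        raise SchemaError(f"reference sector {spec.reference_sector!r} "
                          "not in grid")
    df = dataset.df
    used = set(
        spec.patient_effects + spec.eye_effects
        + spec.sector_by_patient + spec.sector_by_eye
    )
    if spec.variance_weights_by:
        used.add(spec.variance_weights_by)
    unknown = used - set(df.columns)
    if unknown:
        raise SchemaError(f"unknown covariates: {sorted(unknown)}")
    n_dropped = 0
    if used:
        keep = df[list(used)].notna().all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            warnings.warn(
                f"dropping {n_dropped} rows with missing covariate values",
                stacklevel=2,
            )
            df = df[keep]
    if df.empty:
        raise SchemaError("no rows left after dropping missing covariates")

    cols: list[tuple[str, np.ndarray]] = [("Intercept", np.ones(len(df)))]
    for c in spec.patient_effects + spec.eye_effects:
        cols.extend(_encode(df, c))

    sector_order = [spec.reference_sector] + [
        s for s in grid.sector_ids if s != spec.reference_sector
    ]
    sec = pd.Categorical(df["sector"], categories=sector_order)
    sector_dummies = [
        (f"sector[{s}]", (sec == s).astype(float))
        for s in sector_order[1:]
        if (sec == s).any()
    ]
    if spec.sector_effects:
        cols.extend(sector_dummies)
    for c in spec.sector_by_patient + spec.sector_by_eye:
        for cname, cvals in _encode(df, c):
            for sname, svals in sector_dummies:
                cols.append((f"{sname}:{cname}", svals * cvals))

    names = [n for n, _ in cols]
    X = np.column_stack([v for _, v in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SchemaError("fixed-effects design matrix is rank deficient")

    pat = pd.Categorical(df["patient_id"])
    eye_key = pd.Categorical(
        df["patient_id"].astype(str) + "/" + df["eye_id"].astype(str)
    )
    eye_ids = [tuple(k.split("/", 1)) for k in eye_key.categories]

    weight_levels = weight_codes = None
    if spec.variance_weights_by:
        w = df[spec.variance_weights_by]
        if isinstance(w.dtype, pd.CategoricalDtype):
            levels = list(w.cat.categories)
        else:
            levels = sorted(pd.unique(w))
        if spec.reference_group is not None:
            if spec.reference_group not in levels:
                raise SchemaError(
                    f"reference group {spec.reference_group!r} not among "
                    f"levels {levels}"
                )
            levels = [spec.reference_group] + [
                l for l in levels if l != spec.reference_group
            ]
        weight_levels = levels
        lookup = {l: i for i, l in enumerate(levels)}
        weight_codes = w.map(lookup).to_numpy(int)

    return DesignMatrices(
        X=X,
        colnames=names,
        y=df[spec.response].to_numpy(float),
        patient_codes=np.asarray(pat.codes, int),
        eye_codes=np.asarray(eye_key.codes, int),
        sector_idx=np.array([grid.position(s) for s in df["sector"]]),
        weight_levels=weight_levels,
        weight_codes=weight_codes,
        patient_ids=list(pat.categories),
        eye_ids=eye_ids,
        row_index=df.index,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# covariance assembly
# ---------------------------------------------------------------------------

def _lambda_values(theta: VarianceComponents, design: DesignMatrices
                   ) -> np.ndarray | None:
    """Per-row residual-SD multipliers, or None when homoscedastic."""
    if design.weight_levels is None:
        return None
    ratios = theta.weight_ratios or {}
    missing = [l for l in design.weight_levels if l not in ratios]
    if missing:
        raise KeyError(f"no weight ratio for group(s) {missing}")
    lam = np.array([ratios[l] for l in design.weight_levels])
    return lam[design.weight_codes]


def block_covariance(
    theta: VarianceComponents,
    spec: SlmeSpec,
    C: np.ndarray,
    sector_idx: np.ndarray,
    eye_codes: np.ndarray,
    lam: np.ndarray | None,
) -> np.ndarray:
    """Marginal covariance of one patient's stacked cells.

    ``C`` is the full-grid correlation matrix; ``sector_idx`` / ``eye_codes``
    describe the patient's observed cells; ``lam`` the per-cell residual
    multipliers (None = 1).  Residual correlation applies within an eye only.
    """
    n = len(sector_idx)
    H = np.zeros((n, n))
    if spec.has_patient_re:
        H += theta.sd_patient**2
    same_eye = eye_codes[:, None] == eye_codes[None, :]
    if spec.has_eye_re:
        H += theta.sd_eye**2 * same_eye
    Csub = C[np.ix_(sector_idx, sector_idx)]
    resid = theta.sd_resid**2 * Csub * same_eye
    if lam is not None:
        resid = resid * np.outer(lam, lam)
    return H + resid


@dataclass
class AssembledCovariance:
    """Per-patient covariance blocks, block-diagonal across patients."""

    patient_ids: list
    blocks: list[np.ndarray]
    rows: list[np.ndarray]  # row positions (into the design) per patient

    def dense(self, n_obs: int) -> np.ndarray:
        H = np.zeros((n_obs, n_obs))
        for rows, B in zip(self.rows, self.blocks):
            H[np.ix_(rows, rows)] = B
        return H


def assemble_covariance(
    theta: VarianceComponents,
    spec: SlmeSpec,
    grid: SectorGrid,
    design: DesignMatrices,
) -> AssembledCovariance:
    """Assemble every patient's marginal covariance block at theta."""
    corr = spec.correlation
    if corr.has_parameter:
        if theta.gamma is None:
            raise ValueError("theta.gamma required for a parametric kernel")
        corr = corr.with_gamma(theta.gamma)
    C = correlation_matrix(corr, grid)
    lam_all = _lambda_values(theta, design)
    ids, blocks, rows = [], [], []
    order = np.argsort(design.patient_codes, kind="stable")
    bounds = np.searchsorted(
        design.patient_codes[order], np.arange(len(design.patient_ids) + 1)
    )
    for c, pid in enumerate(design.patient_ids):
        r = order[bounds[c]:bounds[c + 1]]
        B = block_covariance(
            theta, spec, C,
            design.sector_idx[r], design.eye_codes[r],
            None if lam_all is None else lam_all[r],
        )
        # symmetric PD check via Cholesky
        try:
            np.linalg.cholesky(B)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"covariance block for patient {pid!r} is not positive "
                "definite"
            ) from None
        ids.append(pid)
        blocks.append(B)
        rows.append(r)
    return AssembledCovariance(ids, blocks, rows)
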
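"""Residual spatial correlation kernels over a sector lattice.

Four parametric families restrict the 9x9 within-eye residual correlation
matrix to a single parameter gamma:

* ``ar_lag``      : s(delta) = gamma**delta on an integer lag (gamma in (0,1))
* ``gaussian``    : s(d) = exp(-gamma * d**2)
* ``exponential`` : s(d) = exp(-gamma * d)
* ``spherical``   : s(d) = 1 - (3*gamma*d - gamma**3 * d**3)/2, clamped to 0
                    for d >= 1/gamma (outside the variogram support)
* ``independence``: identity (no free parameter)

gamma is a *rate*: larger gamma means faster decay (weaker correlation).  A
helper converts between this rate and the "range" parameterisation
exp(-d/range) common elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FAMILIES = ("ar_lag", "gaussian", "exponential", "spherical", "independence")


@dataclass(frozen=True)
class CorrelationSpec:
    """A kernel family plus its decay parameter."""

    family: str = "independence"
    gamma: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown correlation family {self.family!r}")
        if self.family == "independence":
            return
        if self.gamma is None:
            raise ValueError(f"{self.family} kernel requires gamma")
        if self.family == "ar_lag":
            if not 0 < self.gamma < 1:
                raise ValueError("ar_lag requires gamma in (0, 1)")
        elif self.gamma <= 0:
            raise ValueError(f"{self.family} requires gamma > 0")

    @property
    def has_parameter(self) -> bool:
        return self.family != "independence"

    def with_gamma(self, gamma: float) -> "CorrelationSpec":
        return CorrelationSpec(self.family, gamma)

    def to_dict(self) -> dict:
        return {"family": self.family, "gamma": self.gamma}

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationSpec":
        return cls(d["family"], d.get("gamma"))


def rate_to_range(gamma: float) -> float:
    """Convert an exponential decay rate (exp(-gamma*d)) to the equivalent
    range parameter rho of exp(-d/rho)."""
    return 1.0 / gamma


range_to_rate = rate_to_range  # the map is its own inverse


def kernel_value(spec: CorrelationSpec, distance_or_lag) -> np.ndarray:
    """Evaluate the kernel at a distance (spatial families) or integer lag
    (``ar_lag``).  Vectorised over its argument; returns values in [0, 1]."""
    d = np.asarray(distance_or_lag, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances / lags must be nonnegative")
    fam = spec.family
    if fam == "independence":
        return np.where(d == 0, 1.0, 0.0)
    g = spec.gamma
    if fam == "ar_lag":
        if np.any(d != np.round(d)):
            raise ValueError("ar_lag kernel takes integer lags")
        return g**d
    if fam == "gaussian":
        return np.exp(-g * d**2)
    if fam == "exponential":
        return np.exp(-g * d)
    # spherical, zero beyond its support at d = 1/gamma
    val = 1.0 - 0.5 * (3.0 * g * d - g**3 * d**3)
    return np.where(d >= 1.0 / g, 0.0, val)


# PSD safeguard thresholds: matrices with eigenvalues below HARD_FLOOR are
# rejected; tiny negative eigenvalues (numerical) are clipped up to CLIP_AT.
_HARD_FLOOR = -1e-8
_CLIP_AT = 1e-10


def correlation_matrix(spec: CorrelationSpec, grid, check: bool = True) -> np.ndarray:
    """Assemble the sector-by-sector correlation matrix for a grid.

    Exponential/Gaussian kernels are positive definite on any planar point
    set and the AR kernel on any integer lattice; the spherical family can be
    numerically indefinite on irregular lattices, so an eigenvalue safeguard
    (reject below -1e-8, clip tiny negatives and renormalise the diagonal)
    is applied when ``check`` is on.
    """
    if spec.family == "independence":
        return np.eye(grid.n_sectors)
    arg = grid.lag_matrix() if spec.family == "ar_lag" else grid.distance_matrix
    C = kernel_value(spec, arg)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    if check:
        w = np.linalg.eigvalsh(C)
        if w[0] < _HARD_FLOOR:
            raise np.linalg.LinAlgError(
                f"{spec.family} correlation matrix is indefinite "
                f"(min eigenvalue {w[0]:.3e})"
            )
        if w[0] < _CLIP_AT:
            w_clipped = np.clip(w, _CLIP_AT, None)
            vecs = np.linalg.eigh(C)[1]
            C = (vecs * w_clipped) @ vecs.T
            # renormalise so the diagonal is exactly 1
            s = 1.0 / np.sqrt(np.diag(C))
            C = C * np.outer(s, s)
            np.fill_diagonal(C, 1.0)
    return C
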
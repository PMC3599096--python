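"""Risk-based kinetic laws of neurodegeneration.

The central model treats degeneration of a neuronal population as a
probabilistic (one-hit) process whose instantaneous hazard ``r(t)`` is driven
by a measured pathogenic biomarker.  With ``N(t)`` the surviving
neuron/axon density (proxied by an integrity biomarker such as fractional
anisotropy),

    dN/dt = -r(t) N(t)        =>        N(t) = N0 exp(-R(t)),

where ``R(t) = ∫ r(s) ds`` is the *cumulative risk* (the cumulative hazard
of survival analysis).  The hazard itself is log-linear in the excess of the
pathogenic biomarker over a normal threshold,

    r(t) = r0 exp(beta * p(t)),        p(t) = IOP(t) - theta,

which nests the classical constant-risk (radioactive-decay-like) model at
``beta = 0``.  A stretched-exponential (Weibull) generalisation
``N = N0 exp(-R**gamma)`` accommodates heterogeneous decay rates, and a
linear transsynaptic coupling propagates primary loss into downstream
(secondary) regions.

Everything here is a pure deterministic computation on arrays; fitting lives
in :mod:`riskkinetics.fitting`.

Units: time in days, pressure in mmHg, ``r0`` in 1/day, ``beta`` in 1/mmHg,
``N`` dimensionless (FA or an FA ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import RiskSeries

__all__ = [
    "ExcessRiskConfig",
    "KineticParameters",
    "CumulativeRiskCurve",
    "SecondaryCoupling",
    "MultiRiskProfile",
    "excess_pressure",
    "risk_function",
    "multi_risk_function",
    "cumulative_risk",
    "pressure_cumulative_risk",
    "predict_constant_rate",
    "predict_survival",
    "predict_heterogeneity",
    "predict_secondary",
]

# exp() argument beyond which we refuse to evaluate the hazard rather than
# silently return inf
_EXP_OVERFLOW = 700.0


@dataclass(frozen=True)
class ExcessRiskConfig:
    """Threshold configuration for the excess-pressure covariate p(t).

    ``threshold`` defaults to 29 mmHg, the 95% upper confidence limit of
    normal intraocular pressure; ``clamp_negative`` optionally floors
    sub-threshold excursions at zero (off by default: the hazard stays
    positive through the exponential either way).
    """

    threshold: float = 29.0
    clamp_negative: bool = False

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive (mmHg)")


@dataclass
class KineticParameters:
    """Parameter set (N0, r0, beta, gamma) with free/fixed bookkeeping.

    ``free`` names the parameters estimated from data; the rest are fixed
    (e.g. N0 = 1 for relative-FA fits, beta = 0 for the constant-risk model,
    gamma = 1 unless the heterogeneity model is used).
    """

    n0: float = 1.0
    r0: float = 0.0
    beta: float = 0.0
    gamma: float = 1.0
    free: tuple[str, ...] = field(default=("n0", "r0", "beta"))

    def __post_init__(self) -> None:
        if not self.n0 > 0:
            raise ValueError("N0 must be positive")
        if self.r0 < 0:
            raise ValueError("r0 must be nonnegative (1/day)")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        unknown = set(self.free) - {"n0", "r0", "beta", "gamma"}
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")

    @property
    def p_free(self) -> int:
        return len(self.free)


@dataclass
class CumulativeRiskCurve:
    """Time-indexed cumulative risk R(t) = ∫ r dt, the decay abscissa."""

    days: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.days.shape != self.R.shape:
            raise ValueError("days and R must have matching shapes")
        if not np.all(np.isfinite(self.R)):
            raise ValueError("cumulative risk must be finite")
        if np.any(np.diff(self.R) < -1e-12):
            raise ValueError("cumulative risk must be nondecreasing")


@dataclass
class SecondaryCoupling:
    """Linear transsynaptic coupling of a secondary region to primary loss.

    dN_B/dt = k_t dN_A/dt integrates to N_B = N_B0 + k_t N_A; when N_A itself
    decays as N_A0 exp(-R), the secondary trajectory is
    N_B(t) = N_B0 + A exp(-R(t)) with amplitude A = k_t N_A0 and plateau
    N_B0 at infinite time.
    """

    k_t: float
    n_b0: float
    amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative for degenerative coupling")


@dataclass
class MultiRiskProfile:
    """Several risk covariates acting multiplicatively on the hazard.

    factors: sequence of (beta_i, p_i) with all p_i on one shared day grid.
    """

    factors: Sequence[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("at least one risk factor required")
        lengths = {len(np.asarray(p)) for _, p in self.factors}
        if len(lengths) != 1:
            raise ValueError("all covariate series must share the same day grid")


def excess_pressure(iop: RiskSeries | np.ndarray, cfg: ExcessRiskConfig | None = None) -> np.ndarray:
    """Excess-pressure covariate p(t) = IOP(t) - threshold."""
    cfg = cfg or ExcessRiskConfig()
    values = iop.iop if isinstance(iop, RiskSeries) else np.asarray(iop, dtype=float)
    p = values - cfg.threshold
    if cfg.clamp_negative:
        p = np.maximum(p, 0.0)
    return p


def risk_function(p_values: np.ndarray, r0: float, beta: float) -> np.ndarray:
    """Instantaneous hazard r = r0 exp(beta * p); beta = 0 gives constant r0."""
    if r0 < 0:
        raise ValueError("r0 must be nonnegative")
    p = np.asarray(p_values, dtype=float)
    arg = beta * p
    if np.any(np.abs(arg) > _EXP_OVERFLOW):
        raise OverflowError("beta * p too large: hazard would overflow")
    return r0 * np.exp(arg)


def multi_risk_function(profile: MultiRiskProfile, r0: float) -> np.ndarray:
    """Multiplicative multi-factor hazard r = r0 exp(sum_j beta_j p_j)."""
    if r0 < 0:
        raise ValueError("r0 must be nonnegative")
    total = np.zeros(len(np.asarray(profile.factors[0][1], dtype=float)))
    for beta_j, p_j in profile.factors:
        total = total + beta_j * np.asarray(p_j, dtype=float)
    if np.any(np.abs(total) > _EXP_OVERFLOW):
        raise OverflowError("summed risk exponent too large")
    return r0 * np.exp(total)


def _check_grid(days: np.ndarray, name: str = "days") -> np.ndarray:
    days = np.asarray(days, dtype=float)
    if days.ndim != 1 or days.size < 2:
        raise ValueError(f"{name} must be a 1-d grid with at least 2 points")
    if np.any(np.diff(days) <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    return days


def cumulative_risk(
    days: np.ndarray,
    r_values: np.ndarray,
    query_days: np.ndarray | None = None,
) -> CumulativeRiskCurve:
    """Trapezoid-rule cumulative risk R(t) over a discrete hazard series.

    Query days inside the measured span are inserted into the grid before
    integrating.  Because the hazard is log-linear in the (linearly
    interpolated) pressure covariate, inserted points interpolate log r
    linearly when the hazard is strictly positive; a zero hazard anywhere
    falls back to linear interpolation of r itself.

    R is zero at the first measurement day and nondecreasing.  Query days
    outside [days[0], days[-1]] raise (no extrapolation).
    """
    days = _check_grid(days)
    r = np.asarray(r_values, dtype=float)
    if r.shape != days.shape:
        raise ValueError("r_values must match days in length")
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise ValueError("hazard values must be finite and nonnegative")

    if query_days is None:
        query = days
    else:
        query = np.atleast_1d(np.asarray(query_days, dtype=float))
        if np.any(query < days[0] - 1e-12) or np.any(query > days[-1] + 1e-12):
            raise ValueError("query day outside the measured span: refusing to extrapolate")

    grid = np.union1d(days, query)
    if np.all(r > 0):
        r_grid = np.exp(np.interp(grid, days, np.log(r)))
    else:
        r_grid = np.interp(grid, days, r)
    R_grid = _cumtrapz(r_grid, grid)
    R_query = R_grid[np.searchsorted(grid, query)]
    return CumulativeRiskCurve(days=query, R=R_query)


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x), out=out[1:])
    return out


def pressure_cumulative_risk(
    days: np.ndarray,
    p_values: np.ndarray,
    r0: float,
    beta: float,
    query_days: np.ndarray | None = None,
) -> CumulativeRiskCurve:
    """Cumulative risk directly from the pressure covariate.

    The measured quantity is p(t); inserted days interpolate p linearly and
    the hazard r0 exp(beta p) is then integrated by the trapezoid rule.  This
    is the routine the fitting layer re-evaluates at every parameter iterate.
    """
    days = _check_grid(days)
    p = np.asarray(p_values, dtype=float)
    if p.shape != days.shape:
        raise ValueError("p_values must match days in length")
    if query_days is None:
        query = days
    else:
        query = np.atleast_1d(np.asarray(query_days, dtype=float))
        if np.any(query < days[0] - 1e-12) or np.any(query > days[-1] + 1e-12):
            raise ValueError("query day outside the measured span: refusing to extrapolate")
    grid = np.union1d(days, query)
    p_grid = np.interp(grid, days, p)
    r_grid = risk_function(p_grid, r0, beta)
    R_grid = _cumtrapz(r_grid, grid)
    return CumulativeRiskCurve(days=query, R=R_grid[np.searchsorted(grid, query)])


def _as_R(R: CumulativeRiskCurve | np.ndarray) -> np.ndarray:
    return R.R if isinstance(R, CumulativeRiskCurve) else np.asarray(R, dtype=float)


def predict_constant_rate(days: np.ndarray, n0: float, r0: float) -> np.ndarray:
    """Classical linear decline N(t) = N0 - r0 t (no floor; may go negative)."""
    return n0 - r0 * np.asarray(days, dtype=float)


def predict_survival(R: CumulativeRiskCurve | np.ndarray, n0: float) -> np.ndarray:
    """One-hit survival N = N0 exp(-R); positive, nonincreasing in R."""
    return n0 * np.exp(-_as_R(R))


def predict_heterogeneity(R: CumulativeRiskCurve | np.ndarray, n0: float, gamma: float) -> np.ndarray:
    """Stretched-exponential (Weibull) survival N = N0 exp(-R**gamma).

    gamma = 1 reproduces :func:`predict_survival` exactly; gamma < 1 is
    stretched, gamma > 1 compressed/sigmoidal decay.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    Rv = _as_R(R)
    if np.any(Rv < 0):
        raise ValueError("cumulative risk must be nonnegative")
    return n0 * np.exp(-(Rv**gamma))


def predict_secondary(N_A: np.ndarray, coupling: SecondaryCoupling) -> np.ndarray:
    """Secondary-region trajectory N_B = N_B0 + k_t N_A."""
    return coupling.n_b0 + coupling.k_t * np.asarray(N_A, dtype=float)
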
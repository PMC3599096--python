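"""Pooled nonlinear least-squares fitting and nested model selection.

The kinetic laws in :mod:`riskkinetics.kinetics` are fit to pooled
longitudinal observations by bounded least squares, with one shared
parameter set across subjects: each subject's cumulative risk is recomputed
from its own IOP series at every parameter iterate, so the optimisation
surface is non-convex in (r0, beta) and the fit uses multistart with
heuristic initial values.

Model selection between nested pairs (constant-risk ⊂ variable-risk ⊂
heterogeneity, and constant- vs variable-risk secondary fits) uses the
extra-sum-of-squares F-test

    F = ((RSS_reduced - RSS_full) / df1) / (RSS_full / df2),
    df1 = Δp_free,  df2 = n - p_free(full).

Degrees of freedom count only *free* parameters: fixing N0 = 1 for relative
data removes one.  Fit significance against the mean-only null is reported
as an F statistic on (p_free - 1{N0 free}, n - p_free) degrees of freedom —
a declared convention for these nonlinear fits.

The public classes are scikit-learn-style estimators
(:class:`KineticDecayModel`, :class:`SecondaryDecayModel`); module-level
functions are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .io import DegenerationSeries, RiskSeries, StudyDataset
from .kinetics import (
    CumulativeRiskCurve,
    ExcessRiskConfig,
    KineticParameters,
    SecondaryCoupling,
    excess_pressure,
    predict_constant_rate,
    predict_heterogeneity,
    pressure_cumulative_risk,
)

__all__ = [
    "ModelSpec",
    "FitOptions",
    "FitResult",
    "ModelComparison",
    "KineticDecayModel",
    "SecondaryDecayModel",
    "fit_kinetic_model",
    "fit_secondary_linear",
    "fit_secondary_risk",
    "compare_models",
    "r_squared",
    "regression_pvalue",
    "nested_f_test",
    "f_tail_probability",
]

PRIMARY_MODELS = ("constant_rate", "constant_risk", "variable_risk", "heterogeneity")
SECONDARY_MODELS = ("secondary_linear", "secondary_risk")

# reduced -> full pairs eligible for the extra-sum-of-squares F-test
NESTING = {
    ("constant_risk", "variable_risk"),
    ("variable_risk", "heterogeneity"),
    ("constant_risk", "heterogeneity"),
}

_BOUNDS = {
    "n0": (1e-6, 10.0),
    "r0": (0.0, 1.0),
    "beta": (-5.0, 5.0),
    "gamma": (1e-6, 5.0),
    "n_b0": (0.0, 10.0),
    "amplitude": (0.0, 10.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """A named kinetic model with its fixed-parameter choices.

    ``fix_n0`` pins the initial level (1.0 for relative data, per the
    field convention); secondary models use ``n_b0``/``amplitude`` instead
    of ``n0``, and ``fix_beta=0`` turns a secondary risk fit into its
    constant-risk reduced form.
    """

    name: str
    fix_n0: float | None = None
    fix_beta: float | None = None

    def __post_init__(self) -> None:
        if self.name not in PRIMARY_MODELS + SECONDARY_MODELS:
            raise ValueError(f"unknown model {self.name!r}")
        if self.fix_n0 is not None and not self.fix_n0 > 0:
            raise ValueError("fixed N0 must be positive")

    def free_parameters(self) -> tuple[str, ...]:
        if self.name == "secondary_linear":
            return ("n_b0", "amplitude")
        if self.name == "secondary_risk":
            params = ["n_b0", "amplitude", "r0"]
            if self.fix_beta is None:
                params.append("beta")
            return tuple(params)
        params = [] if self.fix_n0 is not None else ["n0"]
        params.append("r0")
        if self.name in ("variable_risk", "heterogeneity") and self.fix_beta is None:
            params.append("beta")
        if self.name == "heterogeneity":
            params.append("gamma")
        return tuple(params)

    @property
    def p_free(self) -> int:
        return len(self.free_parameters())

    def is_nested_in(self, full: "ModelSpec") -> bool:
        if self.fix_n0 != full.fix_n0:
            return False
        if self.name == "secondary_risk" and full.name == "secondary_risk":
            return self.fix_beta is not None and full.fix_beta is None
        return (self.name, full.name) in NESTING


@dataclass
class FitOptions:
    """Optimiser controls: bounds come from the model, these are the knobs."""

    n_starts: int = 8
    seed: int = 0
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 2000

    def __post_init__(self) -> None:
        if min(self.ftol, self.xtol, self.gtol) <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    """Outcome of one pooled NLS fit."""

    spec: ModelSpec
    params: KineticParameters
    rss: float
    tss: float
    n: int
    p_free: int
    r2: float
    p_value: float
    fitted: np.ndarray
    observed: np.ndarray
    coupling: SecondaryCoupling | None = None
    flags: tuple[str, ...] = ()


@dataclass
class ModelComparison:
    """Extra-sum-of-squares F-test between two nested fits."""

    reduced: FitResult
    full: FitResult
    F: float
    df1: int
    df2: int
    p_value: float


# ---------------------------------------------------------------------------
# statistics helpers


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - RSS/TSS (TSS about the mean)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("observed and fitted must be equal-length, n >= 2")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero total variance: R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / tss


def f_tail_probability(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability P(F_{df1,df2} >= F)."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if F < 0:
        raise ValueError("F must be nonnegative")
    return float(stats.f.sf(F, df1, df2))


def regression_pvalue(fit: FitResult) -> float:
    """Fit significance vs the mean-only null, as an upper F tail.

    df1 counts free parameters beyond a free level term (at least 1); df2
    is the residual degrees of freedom n - p_free.
    """
    df2 = fit.n - fit.p_free
    if df2 < 1:
        raise ValueError("no residual degrees of freedom")
    level_free = "n0" in fit.spec.free_parameters() or "n_b0" in fit.spec.free_parameters()
    df1 = max(fit.p_free - (1 if level_free else 0), 1)
    if fit.rss >= fit.tss:
        return 1.0
    F = ((fit.tss - fit.rss) / df1) / (fit.rss / df2) if fit.rss > 0 else np.inf
    return f_tail_probability(F, df1, df2) if np.isfinite(F) else 0.0


def nested_f_test(reduced: FitResult, full: FitResult) -> ModelComparison:
    """Extra-sum-of-squares F-test for a nested model pair."""
    if not reduced.spec.is_nested_in(full.spec):
        raise ValueError(f"{reduced.spec.name!r} is not nested in {full.spec.name!r}")
    if reduced.n != full.n:
        raise ValueError("nested fits must share the same observations")
    df1 = full.p_free - reduced.p_free
    df2 = full.n - full.p_free
    if df1 < 1 or df2 < 1:
        raise ValueError("invalid degrees of freedom for the F-test")
    rss_r, rss_f = reduced.rss, full.rss
    if rss_f > rss_r + 1e-12 * max(rss_r, 1.0):
        warnings.warn(
            "full-model RSS exceeds reduced-model RSS (optimizer failure?); flooring F at 0",
            RuntimeWarning,
            stacklevel=2,
        )
        F = 0.0
    elif rss_f <= 0:
        F = np.inf
    else:
        F = max(((rss_r - rss_f) / df1) / (rss_f / df2), 0.0)
    p = 0.0 if np.isinf(F) else f_tail_probability(F, df1, df2)
    return ModelComparison(reduced=reduced, full=full, F=float(F), df1=df1, df2=df2, p_value=p)


# ---------------------------------------------------------------------------
# pooled data preparation


@dataclass
class _Entry:
    """Per-series precomputed grids for fast re-evaluation in the optimizer."""

    grid_days: np.ndarray
    grid_p: np.ndarray
    obs_idx: np.ndarray  # positions of observation days within the grid
    obs_days: np.ndarray
    y: np.ndarray


def _prepare(
    degen: Sequence[DegenerationSeries],
    risk: Sequence[RiskSeries],
    cfg: ExcessRiskConfig,
) -> list[_Entry]:
    by_key = {(r.subject_id, r.eye): r for r in risk}
    entries = []
    for d in degen:
        r = by_key.get((d.subject_id, "affected")) or by_key.get((d.subject_id, d.eye))
        if r is None:
            raise ValueError(f"no risk series for subject {d.subject_id}")
        if len(r) < 2:
            raise ValueError(f"risk series {r.subject_id}/{r.eye} too short to integrate")
        if not r.spans(d.days):
            raise ValueError(
                f"risk series {r.subject_id}/{r.eye} does not span degeneration days"
            )
        grid = np.union1d(r.days, d.days)
        p_meas = excess_pressure(r, cfg)
        grid_p = np.interp(grid, r.days, p_meas)
        entries.append(
            _Entry(
                grid_days=grid,
                grid_p=grid_p,
                obs_idx=np.searchsorted(grid, d.days),
                obs_days=d.days,
                y=d.values,
            )
        )
    return entries


def _cumrisk_at_obs(entry: _Entry, r0: float, beta: float) -> np.ndarray:
    arg = beta * entry.grid_p
    np.clip(arg, -700.0, 700.0, out=arg)
    r = r0 * np.exp(arg)
    dR = 0.5 * (r[1:] + r[:-1]) * np.diff(entry.grid_days)
    R = np.concatenate(([0.0], np.cumsum(dR)))
    return R[entry.obs_idx]


# ---------------------------------------------------------------------------
# estimators


class _BaseKineticEstimator(BaseEstimator):
    """Shared multistart bounded-least-squares machinery."""

    def _options(self) -> FitOptions:
        return FitOptions(
            n_starts=self.n_starts,
            seed=self.seed,
            ftol=self.ftol,
            xtol=self.xtol,
            gtol=self.gtol,
            max_nfev=self.max_nfev,
        )

    def _optimize(
        self,
        residual,
        names: tuple[str, ...],
        inits: list[np.ndarray],
        n_obs: int,
    ) -> tuple[np.ndarray, float]:
        opts = self._options()
        if n_obs <= len(names):
            raise ValueError(
                f"insufficient data: n = {n_obs} pooled points for {len(names)} free parameters"
            )
        lo = np.array([_BOUNDS[n][0] for n in names])
        hi = np.array([_BOUNDS[n][1] for n in names])
        rng = np.random.default_rng(opts.seed)
        starts = [np.clip(x0, lo, hi) for x0 in inits]
        while len(starts) < opts.n_starts:
            base = starts[len(starts) % len(inits)]
            jitter = base * np.exp(rng.normal(0.0, 0.5, size=base.size))
            jitter = np.where(np.abs(base) < 1e-12, rng.normal(0.0, 0.02, size=base.size), jitter)
            starts.append(np.clip(jitter, lo, hi))
        best, best_cost, last_err = None, np.inf, None
        for x0 in starts[: max(opts.n_starts, len(inits))]:
            try:
                sol = optimize.least_squares(
                    residual,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    x_scale="jac",
                    ftol=opts.ftol,
                    xtol=opts.xtol,
                    gtol=opts.gtol,
                    max_nfev=opts.max_nfev,
                )
            except Exception as exc:  # noqa: BLE001 - keep trying other starts
                last_err = exc
                continue
            if sol.cost < best_cost:
                best, best_cost = sol, sol.cost
        if best is None:
            raise RuntimeError(f"optimization failed from every start: {last_err}")
        return best.x, float(2.0 * best.cost)

    @staticmethod
    def _boundary_flags(names: tuple[str, ...], x: np.ndarray) -> tuple[str, ...]:
        flags = []
        for name, v in zip(names, x):
            lo, hi = _BOUNDS[name]
            tol = 1e-8 * max(abs(hi), 1.0)
            if name == "gamma" and v >= hi - tol:
                flags.append("gamma_at_upper_bound")
            if name == "r0" and v <= lo + 1e-8:
                flags.append("r0_at_lower_bound")
        return tuple(flags)


class KineticDecayModel(_BaseKineticEstimator):
    """Pooled kinetic-decay estimator for primary neurodegeneration.

    Parameters
    ----------
    model:
        One of ``constant_rate``, ``constant_risk``, ``variable_risk``,
        ``heterogeneity``.
    threshold, clamp_negative:
        Excess-pressure configuration p(t) = IOP - threshold.
    fix_n0:
        Fix the initial level; ``None`` auto-fixes N0 = 1 when every fitted
        series is relative (the ratio convention), and leaves it free
        otherwise.
    n_starts, seed, ftol, xtol, gtol, max_nfev:
        Multistart bounded-least-squares controls; fits are deterministic
        given the data and ``seed``.
    warm_start_params:
        Optional parameter vector used as an extra start (used by
        :func:`compare_models` to enforce RSS monotonicity along a nest).

    Fitted attributes (trailing underscore): ``params_``, ``rss_``, ``tss_``,
    ``r2_``, ``p_value_``, ``n_``, ``result_``.
    """

    def __init__(
        self,
        model: str = "variable_risk",
        threshold: float = 29.0,
        clamp_negative: bool = False,
        fix_n0: float | None = None,
        n_starts: int = 8,
        seed: int = 0,
        ftol: float = 1e-12,
        xtol: float = 1e-12,
        gtol: float = 1e-12,
        max_nfev: int = 2000,
        warm_start_params: KineticParameters | None = None,
    ):
        self.model = model
        self.threshold = threshold
        self.clamp_negative = clamp_negative
        self.fix_n0 = fix_n0
        self.n_starts = n_starts
        self.seed = seed
        self.ftol = ftol
        self.xtol = xtol
        self.gtol = gtol
        self.max_nfev = max_nfev
        self.warm_start_params = warm_start_params

    # -- spec plumbing ------------------------------------------------------
    def _resolve_spec(self, degen: Sequence[DegenerationSeries]) -> ModelSpec:
        fix_n0 = self.fix_n0
        if fix_n0 is None and degen and all(d.kind == "relative" for d in degen):
            fix_n0 = 1.0
        fix_beta = 0.0 if self.model == "constant_risk" else None
        return ModelSpec(name=self.model, fix_n0=fix_n0, fix_beta=fix_beta)

    def _unpack(self, spec: ModelSpec, x: np.ndarray) -> KineticParameters:
        names = spec.free_parameters()
        vals = dict(zip(names, x))
        return KineticParameters(
            n0=vals.get("n0", spec.fix_n0 if spec.fix_n0 is not None else 1.0),
            r0=max(vals.get("r0", 0.0), 0.0),
            beta=vals.get("beta", spec.fix_beta if spec.fix_beta is not None else 0.0),
            gamma=vals.get("gamma", 1.0),
            free=names,
        )

    def _predict_entries(self, entries: list[_Entry], params: KineticParameters) -> np.ndarray:
        out = []
        for e in entries:
            if self.model == "constant_rate":
                out.append(predict_constant_rate(e.obs_days, params.n0, params.r0))
            else:
                R = _cumrisk_at_obs(e, params.r0, params.beta)
                out.append(predict_heterogeneity(R, params.n0, params.gamma))
        return np.concatenate(out)

    # -- sklearn surface ----------------------------------------------------
    def fit(
        self,
        degen: Sequence[DegenerationSeries] | DegenerationSeries,
        risk: Sequence[RiskSeries] | RiskSeries,
    ) -> "KineticDecayModel":
        degen = [degen] if isinstance(degen, DegenerationSeries) else list(degen)
        risk = [risk] if isinstance(risk, RiskSeries) else list(risk)
        if not degen:
            raise ValueError("no degeneration series to fit")
        spec = self._resolve_spec(degen)
        cfg = ExcessRiskConfig(threshold=self.threshold, clamp_negative=self.clamp_negative)
        entries = _prepare(degen, risk, cfg)
        y = np.concatenate([e.y for e in entries])
        n = y.size
        if n < spec.p_free + 2:
            raise ValueError(
                f"insufficient data: n = {n} pooled points for {spec.p_free} free parameters"
            )
        names = spec.free_parameters()

        def residual(x: np.ndarray) -> np.ndarray:
            return self._predict_entries(entries, self._unpack(spec, x)) - y

        inits = self._initial_values(spec, entries, y)
        if self.warm_start_params is not None:
            w = self.warm_start_params
            full = {"n0": w.n0, "r0": w.r0, "beta": w.beta, "gamma": w.gamma}
            inits.insert(0, np.array([full[nm] for nm in names]))
        x, rss = self._optimize(residual, names, inits, n)
        params = self._unpack(spec, x)
        fitted = self._predict_entries(entries, params)
        tss = float(np.sum((y - y.mean()) ** 2))

        self.spec_ = spec
        self.params_ = params
        self.rss_ = rss
        self.tss_ = tss
        self.n_ = n
        self.r2_ = 1.0 - rss / tss if tss > 0 else np.nan
        self.result_ = FitResult(
            spec=spec,
            params=params,
            rss=rss,
            tss=tss,
            n=n,
            p_free=spec.p_free,
            r2=self.r2_,
            p_value=np.nan,
            fitted=fitted,
            observed=y,
            flags=self._boundary_flags(names, x),
        )
        self.result_.p_value = regression_pvalue(self.result_)
        self.p_value_ = self.result_.p_value
        return self

    def _initial_values(
        self, spec: ModelSpec, entries: list[_Entry], y: np.ndarray
    ) -> list[np.ndarray]:
        names = spec.free_parameters()
        t = np.concatenate([e.obs_days for e in entries])
        n0_init = spec.fix_n0 if spec.fix_n0 is not None else max(float(np.max(y)), 1e-3)
        inits = []
        if self.model == "constant_rate":
            slope = -np.polyfit(t, y, 1)[0] if np.ptp(t) > 0 else 1e-4
            base = {"n0": n0_init, "r0": float(np.clip(slope, 1e-6, 1.0)), "beta": 0.01}
            inits.append(np.array([base[nm] for nm in names]))
            return inits
        # decay models: r0 from a log-linear slope vs time, beta swept
        logy = np.log(np.clip(y / n0_init, 1e-9, None))
        slope = -np.polyfit(t, logy, 1)[0] if np.ptp(t) > 0 else 1e-4
        r0_loglin = float(np.clip(slope, 1e-6, 1.0))
        for beta0 in (0.01, 0.0, 0.05):
            base = {
                "n0": n0_init,
                "r0": r0_loglin * np.exp(-beta0 * 10.0),
                "beta": beta0,
                "gamma": 1.0,
            }
            inits.append(np.array([base[nm] for nm in names]))
            if "beta" not in names:
                break
        return inits

    def predict(
        self,
        risk: RiskSeries,
        days: np.ndarray | None = None,
    ) -> np.ndarray:
        """Forward trajectory for one subject at the given days."""
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        days = risk.days if days is None else np.asarray(days, dtype=float)
        p = self.params_
        if self.model == "constant_rate":
            return predict_constant_rate(days, p.n0, p.r0)
        cfg = ExcessRiskConfig(threshold=self.threshold, clamp_negative=self.clamp_negative)
        curve = pressure_cumulative_risk(
            risk.days, excess_pressure(risk, cfg), p.r0, p.beta, query_days=days
        )
        return predict_heterogeneity(curve, p.n0, p.gamma)

    def cumulative_risk_curve(self, risk: RiskSeries) -> CumulativeRiskCurve:
        """Fitted cumulative-risk abscissa for one subject's risk series."""
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        cfg = ExcessRiskConfig(threshold=self.threshold, clamp_negative=self.clamp_negative)
        return pressure_cumulative_risk(
            risk.days, excess_pressure(risk, cfg), self.params_.r0, self.params_.beta
        )

    def score(self, degen, risk) -> float:  # noqa: D102 - sklearn convention
        degen = [degen] if isinstance(degen, DegenerationSeries) else list(degen)
        risk = [risk] if isinstance(risk, RiskSeries) else list(risk)
        cfg = ExcessRiskConfig(threshold=self.threshold, clamp_negative=self.clamp_negative)
        entries = _prepare(degen, risk, cfg)
        y = np.concatenate([e.y for e in entries])
        return r_squared(y, self._predict_entries(entries, self.params_))


class SecondaryDecayModel(_BaseKineticEstimator):
    """Risk-based fit of a secondary (transsynaptic) region.

    Fits N_B(t) = N_B0 + A exp(-R(t)) with the amplitude A = k_t N_A0
    collapsed into a single parameter; ``constant_risk=True`` fixes beta = 0,
    giving the reduced form comparable by :func:`nested_f_test`.
    """

    def __init__(
        self,
        constant_risk: bool = False,
        threshold: float = 29.0,
        clamp_negative: bool = False,
        n_starts: int = 8,
        seed: int = 0,
        ftol: float = 1e-12,
        xtol: float = 1e-12,
        gtol: float = 1e-12,
        max_nfev: int = 2000,
        warm_start: np.ndarray | None = None,
    ):
        self.constant_risk = constant_risk
        self.threshold = threshold
        self.clamp_negative = clamp_negative
        self.n_starts = n_starts
        self.seed = seed
        self.ftol = ftol
        self.xtol = xtol
        self.gtol = gtol
        self.max_nfev = max_nfev
        self.warm_start = warm_start

    def fit(
        self,
        degen: Sequence[DegenerationSeries] | DegenerationSeries,
        risk: Sequence[RiskSeries] | RiskSeries,
    ) -> "SecondaryDecayModel":
        degen = [degen] if isinstance(degen, DegenerationSeries) else list(degen)
        risk = [risk] if isinstance(risk, RiskSeries) else list(risk)
        spec = ModelSpec(
            name="secondary_risk", fix_beta=0.0 if self.constant_risk else None
        )
        names = spec.free_parameters()
        cfg = ExcessRiskConfig(threshold=self.threshold, clamp_negative=self.clamp_negative)
        entries = _prepare(degen, risk, cfg)
        y = np.concatenate([e.y for e in entries])
        n = y.size
        if n < spec.p_free + 2:
            raise ValueError(
                f"insufficient data: n = {n} pooled points for {spec.p_free} free parameters"
            )

        def unpack(x: np.ndarray) -> dict:
            vals = dict(zip(names, x))
            vals.setdefault("beta", 0.0)
            return vals

        def predict(x: np.ndarray) -> np.ndarray:
            v = unpack(x)
            return np.concatenate(
                [
                    v["n_b0"] + v["amplitude"] * np.exp(-_cumrisk_at_obs(e, v["r0"], v["beta"]))
                    for e in entries
                ]
            )

        def residual(x: np.ndarray) -> np.ndarray:
            return predict(x) - y

        spread = float(np.max(y) - np.min(y))
        base = {
            "n_b0": max(float(np.min(y)) - 0.5 * spread, 0.0),
            "amplitude": max(spread, 1e-3),
            "r0": 0.005,
            "beta": 0.01,
        }
        inits = [np.array([base[nm] for nm in names])]
        if self.warm_start is not None:
            inits.insert(0, np.asarray(self.warm_start, dtype=float))
        x, rss = self._optimize(residual, names, inits, n)
        vals = unpack(x)
        fitted = predict(x)
        tss = float(np.sum((y - y.mean()) ** 2))

        flags = list(self._boundary_flags(names, x))
        if spread < 1e-12 or vals["amplitude"] < 1e-9:
            flags.append("amplitude_unidentifiable")
        self.spec_ = spec
        self.coupling_ = SecondaryCoupling(
            k_t=np.nan, n_b0=vals["n_b0"], amplitude=vals["amplitude"]
        )
        self.params_ = KineticParameters(
            n0=1.0, r0=vals["r0"], beta=vals["beta"], gamma=1.0,
            free=tuple(nm for nm in names if nm in ("r0", "beta")),
        )
        self.x_ = x
        self.rss_ = rss
        self.tss_ = tss
        self.n_ = n
        self.r2_ = 1.0 - rss / tss if tss > 0 else np.nan
        self.result_ = FitResult(
            spec=spec,
            params=self.params_,
            rss=rss,
            tss=tss,
            n=n,
            p_free=spec.p_free,
            r2=self.r2_,
            p_value=np.nan,
            fitted=fitted,
            observed=y,
            coupling=self.coupling_,
            flags=tuple(flags),
        )
        self.result_.p_value = regression_pvalue(self.result_)
        self.p_value_ = self.result_.p_value
        return self


# ---------------------------------------------------------------------------
# functional wrappers


def fit_kinetic_model(
    degen: Sequence[DegenerationSeries],
    risk: Sequence[RiskSeries],
    spec: ModelSpec | str = "variable_risk",
    cfg: ExcessRiskConfig | None = None,
    opts: FitOptions | None = None,
    warm_start: KineticParameters | None = None,
) -> FitResult:
    """Fit one kinetic model to pooled observations; see KineticDecayModel."""
    if isinstance(spec, str):
        spec = ModelSpec(name=spec)
    cfg = cfg or ExcessRiskConfig()
    opts = opts or FitOptions()
    est = KineticDecayModel(
        model=spec.name,
        threshold=cfg.threshold,
        clamp_negative=cfg.clamp_negative,
        fix_n0=spec.fix_n0,
        n_starts=opts.n_starts,
        seed=opts.seed,
        ftol=opts.ftol,
        xtol=opts.xtol,
        gtol=opts.gtol,
        max_nfev=opts.max_nfev,
        warm_start_params=warm_start,
    )
    return est.fit(degen, risk).result_


def fit_secondary_linear(N_A: np.ndarray, N_B: np.ndarray) -> SecondaryCoupling:
    """OLS of the secondary on the primary trajectory: slope k_t, intercept N_B0."""
    a = np.asarray(N_A, dtype=float)
    b = np.asarray(N_B, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length N_A and N_B with n >= 3")
    if np.ptp(a) == 0:
        raise ValueError("N_A is constant: coupling slope is unidentifiable")
    X = np.column_stack([np.ones_like(a), a])
    (intercept, slope), *_ = np.linalg.lstsq(X, b, rcond=None)
    return SecondaryCoupling(k_t=float(slope), n_b0=float(intercept), amplitude=None)


def fit_secondary_risk(
    degen_B: Sequence[DegenerationSeries] | DegenerationSeries,
    risk: Sequence[RiskSeries] | RiskSeries,
    spec: ModelSpec | None = None,
    cfg: ExcessRiskConfig | None = None,
    opts: FitOptions | None = None,
) -> FitResult:
    """Risk-based secondary fit N_B(t) = N_B0 + A exp(-R(t))."""
    cfg = cfg or ExcessRiskConfig()
    opts = opts or FitOptions()
    constant = spec is not None and spec.fix_beta is not None
    est = SecondaryDecayModel(
        constant_risk=constant,
        threshold=cfg.threshold,
        clamp_negative=cfg.clamp_negative,
        n_starts=opts.n_starts,
        seed=opts.seed,
        ftol=opts.ftol,
        xtol=opts.xtol,
        gtol=opts.gtol,
        max_nfev=opts.max_nfev,
    )
    return est.fit(degen_B, risk).result_


def compare_secondary_models(
    degen_B: Sequence[DegenerationSeries] | DegenerationSeries,
    risk: Sequence[RiskSeries] | RiskSeries,
    cfg: ExcessRiskConfig | None = None,
    opts: FitOptions | None = None,
) -> tuple[FitResult, FitResult, ModelComparison]:
    """Constant- vs variable-risk secondary fits with the nested F-test.

    The variable-risk (full) fit is warm-started at the constant-risk
    optimum with beta = 0, so its RSS can never exceed the reduced one.
    """
    cfg = cfg or ExcessRiskConfig()
    opts = opts or FitOptions()
    common = dict(
        threshold=cfg.threshold,
        clamp_negative=cfg.clamp_negative,
        n_starts=opts.n_starts,
        seed=opts.seed,
        ftol=opts.ftol,
        xtol=opts.xtol,
        gtol=opts.gtol,
        max_nfev=opts.max_nfev,
    )
    reduced_est = SecondaryDecayModel(constant_risk=True, **common).fit(degen_B, risk)
    warm = np.append(reduced_est.x_, 0.0)
    full = SecondaryDecayModel(constant_risk=False, warm_start=warm, **common).fit(
        degen_B, risk
    ).result_
    reduced = reduced_est.result_
    return reduced, full, nested_f_test(reduced, full)


def compare_models(
    dataset: StudyDataset,
    specs: Sequence[ModelSpec | str],
    cfg: ExcessRiskConfig | None = None,
    opts: FitOptions | None = None,
    region: str = "optic_nerve",
    kind: str = "relative",
) -> tuple[list[FitResult], list[ModelComparison]]:
    """Fit an ordered list of models and F-test each declared nested pair.

    Later models along a nest are warm-started at the best nested reduced
    optimum, which enforces RSS monotonicity (a free parameter never hurts).
    """
    specs = [ModelSpec(name=s) if isinstance(s, str) else s for s in specs]
    degen = dataset.degen(region=region, kind=kind, glaucoma_only=True)
    if not degen:
        raise ValueError(f"no {kind} degeneration series for region {region!r}")
    risk = dataset.risk_series
    results: list[FitResult] = []
    for spec in specs:
        warm = None
        for prev_spec, prev_res in zip(specs[: len(results)], results):
            if prev_spec.is_nested_in(spec):
                warm = prev_res.params
        results.append(fit_kinetic_model(degen, risk, spec, cfg, opts, warm_start=warm))
    comparisons = []
    for i, reduced in enumerate(specs):
        for j, full in enumerate(specs):
            if reduced.is_nested_in(full) and _adjacent(reduced, full):
                comparisons.append(nested_f_test(results[i], results[j]))
    return results, comparisons


def _adjacent(reduced: ModelSpec, full: ModelSpec) -> bool:
    # report only single-step comparisons (constant->variable, variable->het)
    return full.p_free - reduced.p_free == 1
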
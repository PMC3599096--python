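"""Simulation experiments: recovery, size/power and coupling checks.

Each experiment generates many independent synthetic studies at the default
study design (5 glaucoma + 3 control subjects, ~12–15 pooled optic-nerve
points, variable-risk truth r0 = 0.0019/day, beta = 0.057/mmHg unless a
null is stated) and summarises an operating characteristic of the fitting
and model-selection machinery.  Replicate seeds derive deterministically
from one base seed.

Monte-Carlo fits use two warm-started optimizer starts — ample for these
low-dimensional, well-initialised problems — rather than the interactive
default of eight.
"""

from __future__ import annotations

import warnings

import numpy as np

from .fitting import (
    FitOptions,
    ModelSpec,
    compare_secondary_models,
    fit_kinetic_model,
    fit_secondary_linear,
    nested_f_test,
)
from .kinetics import KineticParameters
from .simulate import SimulationConfig, simulate_study

__all__ = [
    "parameter_recovery_experiment",
    "recovery_correlation_experiment",
    "null_type1_experiment",
    "power_experiment",
    "secondary_linear_experiment",
    "secondary_risk_preference_experiment",
]

_MC_OPTS = dict(n_starts=2, ftol=1e-10, xtol=1e-10, gtol=1e-10)

# Table-level constant-risk rate used as the null truth (relative-FA scale)
NULL_R0 = 0.0084
TRUE_R0 = 0.0019
TRUE_BETA = 0.057


def _rep_seed(seed: int, i: int) -> int:
    return (seed * 1_000_003 + i) % (2**31 - 1)


def _fit_pair(study, seed_fit: int = 0):
    """Constant-risk and (warm-started) variable-risk fits on relative FA."""
    rel = study.degen(region="optic_nerve", kind="relative", glaucoma_only=True)
    opts = FitOptions(seed=seed_fit, **_MC_OPTS)
    reduced = fit_kinetic_model(
        rel, study.risk_series, ModelSpec("constant_risk", fix_n0=1.0), opts=opts
    )
    full = fit_kinetic_model(
        rel,
        study.risk_series,
        ModelSpec("variable_risk", fix_n0=1.0),
        opts=opts,
        warm_start=reduced.params,
    )
    return reduced, full


def parameter_recovery_experiment(
    n_studies: int = 200, seed: int = 0, fa_noise_sd: float = 0.02
) -> dict:
    """Median relative error of (r0, beta) across paper-like studies."""
    r0s, betas, ns = [], [], []
    for i in range(n_studies):
        cfg = SimulationConfig(seed=_rep_seed(seed, i), fa_noise_sd=fa_noise_sd)
        study = simulate_study(cfg)
        _, full = _fit_pair(study)
        r0s.append(full.params.r0)
        betas.append(full.params.beta)
        ns.append(full.n)
    r0s = np.asarray(r0s)
    betas = np.asarray(betas)
    return {
        "median_rel_err_r0": float(np.median(np.abs(r0s - TRUE_R0) / TRUE_R0)),
        "median_rel_err_beta": float(np.median(np.abs(betas - TRUE_BETA) / TRUE_BETA)),
        "median_r0": float(np.median(r0s)),
        "median_beta": float(np.median(betas)),
        "median_n": float(np.median(ns)),
        "n_studies": n_studies,
    }


def recovery_correlation_experiment(n_studies: int = 60, seed: int = 0) -> dict:
    """Estimated-vs-true correlation when the truth varies across studies."""
    rng = np.random.default_rng(seed)
    true_r0 = np.exp(rng.uniform(np.log(0.001), np.log(0.004), size=n_studies))
    true_beta = rng.uniform(0.03, 0.09, size=n_studies)
    est_r0, est_beta = [], []
    for i in range(n_studies):
        cfg = SimulationConfig(
            seed=_rep_seed(seed, i),
            true_params=KineticParameters(n0=1.0, r0=true_r0[i], beta=true_beta[i]),
        )
        _, full = _fit_pair(simulate_study(cfg))
        est_r0.append(full.params.r0)
        est_beta.append(full.params.beta)
    return {
        "corr_r0": float(np.corrcoef(true_r0, est_r0)[0, 1]),
        "corr_beta": float(np.corrcoef(true_beta, est_beta)[0, 1]),
        "n_studies": n_studies,
    }


def null_type1_experiment(
    n_rep: int = 1000, seed: int = 0, alpha: float = 0.05, r0_null: float = NULL_R0
) -> dict:
    """Empirical size of the nested F-test under constant-risk truth."""
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n_rep):
            cfg = SimulationConfig(
                seed=_rep_seed(seed, i),
                true_model="constant_risk",
                true_params=KineticParameters(n0=1.0, r0=r0_null, beta=0.0),
            )
            reduced, full = _fit_pair(simulate_study(cfg))
            rejections += nested_f_test(reduced, full).p_value < alpha
    return {"rate": rejections / n_rep, "n_rep": n_rep, "alpha": alpha}


def power_experiment(n_rep: int = 200, seed: int = 0, alpha: float = 0.05) -> dict:
    """Empirical power against constant risk under variable-risk truth."""
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n_rep):
            cfg = SimulationConfig(seed=_rep_seed(seed, i))
            reduced, full = _fit_pair(simulate_study(cfg))
            rejections += nested_f_test(reduced, full).p_value < alpha
    return {"rate": rejections / n_rep, "n_rep": n_rep, "alpha": alpha}


def secondary_linear_experiment(n_rep: int = 200, seed: int = 0) -> dict:
    """Recovery of the transsynaptic coupling slope k_t by pooled OLS."""
    slopes = []
    for i in range(n_rep):
        cfg = SimulationConfig(seed=_rep_seed(seed, i))
        study = simulate_study(cfg)
        primary = {
            d.subject_id: d
            for d in study.degen(region="optic_nerve", kind="relative", glaucoma_only=True)
        }
        n_a, n_b = [], []
        for d in study.degen(region="optic_radiation", glaucoma_only=True):
            n_a.extend(primary[d.subject_id].values)
            n_b.extend(d.values)
        slopes.append(fit_secondary_linear(np.asarray(n_a), np.asarray(n_b)).k_t)
        true_kt = cfg.secondary_kt
    slopes = np.asarray(slopes)
    return {
        "median_rel_err_kt": float(np.median(np.abs(slopes - true_kt) / true_kt)),
        "median_kt": float(np.median(slopes)),
        "n_rep": n_rep,
    }


def secondary_risk_preference_experiment(
    n_rep: int = 150, seed: int = 0, alpha: float = 0.05
) -> dict:
    """How often the risk-based secondary fit prefers variable over constant risk."""
    preferred = 0
    opts = FitOptions(seed=0, **_MC_OPTS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n_rep):
            cfg = SimulationConfig(seed=_rep_seed(seed, i))
            study = simulate_study(cfg)
            secondary = study.degen(region="optic_radiation", glaucoma_only=True)
            _, _, comp = compare_secondary_models(secondary, study.risk_series, opts=opts)
            preferred += comp.p_value < alpha
    return {"rate": preferred / n_rep, "n_rep": n_rep, "alpha": alpha}
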
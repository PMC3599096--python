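"""Synthetic glaucoma-study generator.

Emulates the statistical structure of a longitudinal laser-induced ocular
hypertension experiment: five glaucomatous and three control subjects,
follow-up ending 33–168 days after induction, IOP measured intermittently
every 3–28 days, the affected eye elevated around a subject-level mean of
54.9 mmHg (between-subject sd 9.4 mmHg, within-subject visit sd 8 mmHg)
against a 23.2 ± 0.8 mmHg baseline, FA decaying according to a chosen
kinetic law with noise applied after three-replicate averaging, a secondary
(optic-radiation-like) region linearly coupled to the primary loss, and
terminal axon-density histology linear in FA.

All randomness flows from the single configured seed through per-subject
streams keyed on (seed, subject index, stream tag) — no global state, and
generated studies are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DegenerationSeries, RiskSeries, StudyDataset, derive_relative_series
from .kinetics import (
    ExcessRiskConfig,
    KineticParameters,
    SecondaryCoupling,
    excess_pressure,
    predict_constant_rate,
    predict_heterogeneity,
    predict_secondary,
    pressure_cumulative_risk,
)

__all__ = [
    "SimulationConfig",
    "HistologyConfig",
    "simulate_iop_course",
    "simulate_degeneration",
    "simulate_histology",
    "simulate_study",
]


@dataclass
class SimulationConfig:
    """Study-design and generative-model parameters.

    Defaults reproduce the reference study conditions: subject counts,
    follow-up and measurement-interval ranges, IOP summary statistics, and
    variable-risk truth (r0 = 0.0019/day, beta = 0.057/mmHg, N0 = 1 on the
    relative-FA scale).  ``quantitative_n0`` is the healthy-nerve FA level
    used for the quantitative-scale series; ``secondary_kt``/``secondary_nb0``
    are invented defaults for the transsynaptic coupling (no measured values
    exist for them).  The within-subject visit sd (8 mmHg) is a declared
    guess, not an inferred quantity.
    """

    n_glaucoma: int = 5
    n_control: int = 3
    follow_up_days: tuple[float, float] = (33.0, 168.0)
    iop_interval_days: tuple[float, float] = (3.0, 28.0)
    baseline_iop: tuple[float, float] = (23.2, 0.8)  # mean, sd
    affected_iop: tuple[float, float] = (54.9, 9.4)  # between-subject mean, sd
    affected_visit_sd: float = 8.0
    true_model: str = "variable_risk"
    true_params: KineticParameters = field(
        default_factory=lambda: KineticParameters(n0=1.0, r0=0.0019, beta=0.057, gamma=1.0)
    )
    threshold: float = 29.0
    fa_noise_sd: float = 0.02
    n_mri_sessions: tuple[int, int] = (2, 3)
    n_replicates: int = 3
    quantitative_n0: float = 0.73
    secondary_kt: float = 0.5
    secondary_nb0: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("follow_up_days", "iop_interval_days"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} range must be ordered")
        if self.baseline_iop[1] < 0 or self.affected_iop[1] < 0 or self.affected_visit_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.fa_noise_sd < 0:
            raise ValueError("fa_noise_sd must be nonnegative")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")


@dataclass
class HistologyConfig:
    """Linear map from terminal FA to neurofilament-positive axon density.

    density = intercept + slope * FA + N(0, noise_sd), truncated at 0.
    Defaults put healthy optic nerve around 1.1e5 axons/mm^2 and set the
    noise so the FA-density correlation lands near the observed ~0.9.
    """

    slope: float = 1.5e5
    intercept: float = 0.0
    noise_sd: float = 1.2e4
    target_correlation: float = 0.92

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _rng(cfg_seed: int, subject_index: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg_seed, subject_index, tag]))


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, size=None) -> np.ndarray:
    draw = rng.normal(mean, sd, size=size)
    return np.clip(draw, 1.0, None)  # IOP below 1 mmHg is not physiological


def simulate_iop_course(
    cfg: SimulationConfig, subject_index: int, group: str = "glaucoma"
) -> tuple[RiskSeries, RiskSeries]:
    """One subject's (affected, fellow) IOP course.

    Day 0 carries the pre-induction baseline; subsequent visits fall at
    irregular intervals drawn uniformly from ``iop_interval_days`` up to a
    subject-specific follow-up end drawn from ``follow_up_days``.  Affected
    eyes of glaucoma subjects fluctuate around a subject-level elevated mean
    drawn once; fellow (and control) eyes stay at baseline level.
    """
    rng = _rng(cfg.seed, subject_index, 1)
    end = rng.uniform(*cfg.follow_up_days)
    days = [0.0]
    while True:
        step = rng.uniform(*cfg.iop_interval_days)
        if days[-1] + step > end:
            break
        days.append(days[-1] + step)
    if len(days) < 3:  # guarantee at least two post-induction visits
        days.append(end)
    days = np.round(np.asarray(days), 1)

    mean_b, sd_b = cfg.baseline_iop
    fellow_iop = _positive_normal(rng, mean_b, sd_b, size=days.size)
    if group == "glaucoma":
        subject_mean = rng.normal(cfg.affected_iop[0], cfg.affected_iop[1])
        affected_iop = _positive_normal(rng, subject_mean, cfg.affected_visit_sd, size=days.size)
        affected_iop[0] = _positive_normal(rng, mean_b, sd_b)  # pre-induction baseline
    else:
        affected_iop = _positive_normal(rng, mean_b, sd_b, size=days.size)

    sid = f"{'g' if group == 'glaucoma' else 'c'}{subject_index + 1}"
    make = lambda eye, iop: RiskSeries(
        subject_id=sid, group=group, eye=eye, days=days.copy(), iop=iop
    )
    return make("affected", affected_iop), make("fellow", fellow_iop)


def _mri_days(cfg: SimulationConfig, risk: RiskSeries, rng: np.random.Generator) -> np.ndarray:
    post = risk.days[1:]
    lo, hi = cfg.n_mri_sessions
    n = int(rng.integers(lo, hi + 1))
    if post.size <= n:
        return post
    # always image at the terminal visit; spread the rest over the follow-up
    chosen = rng.choice(post[:-1], size=n - 1, replace=False) if n > 1 else np.array([])
    return np.sort(np.append(chosen, post[-1]))


def _forward(
    cfg: SimulationConfig,
    risk: RiskSeries,
    days: np.ndarray,
    params: KineticParameters,
    zero_risk: bool,
) -> np.ndarray:
    if zero_risk:
        return np.full(days.shape, params.n0, dtype=float)
    if cfg.true_model == "constant_rate":
        return predict_constant_rate(days, params.n0, params.r0)
    beta = 0.0 if cfg.true_model == "constant_risk" else params.beta
    p = excess_pressure(risk, ExcessRiskConfig(threshold=cfg.threshold))
    curve = pressure_cumulative_risk(risk.days, p, params.r0, beta, query_days=days)
    gamma = params.gamma if cfg.true_model == "heterogeneity" else 1.0
    return predict_heterogeneity(curve, params.n0, gamma)


def simulate_degeneration(
    risk: RiskSeries,
    cfg: SimulationConfig,
    true_model: str | None = None,
    true_params: KineticParameters | None = None,
    rng: np.random.Generator | None = None,
    days: np.ndarray | None = None,
    zero_risk: bool = False,
    region: str = "optic_nerve",
    kind: str = "relative",
) -> DegenerationSeries:
    """Noisy forward-model FA series at MRI session days.

    Measurement noise has sd ``fa_noise_sd / sqrt(n_replicates)`` (noise of
    a replicate-averaged value); eyes carrying no risk (controls, fellows)
    are generated with zero cumulative risk, i.e. a flat trajectory.
    """
    if true_model is not None:
        cfg = SimulationConfig(**{**cfg.__dict__, "true_model": true_model})
    params = true_params or cfg.true_params
    rng = rng if rng is not None else _rng(cfg.seed, 0, 2)
    days = _mri_days(cfg, risk, rng) if days is None else np.asarray(days, dtype=float)
    if days.size and not risk.spans(days):
        raise ValueError("MRI day outside the measured IOP span")
    clean = _forward(cfg, risk, days, params, zero_risk)
    noisy = clean + rng.normal(0.0, cfg.fa_noise_sd / np.sqrt(cfg.n_replicates), size=days.shape)
    upper = 1.0 if kind == "quantitative" else np.inf
    noisy = np.clip(noisy, 1e-6, upper)
    return DegenerationSeries(
        subject_id=risk.subject_id,
        eye=risk.eye,
        region=region,
        days=days,
        values=noisy,
        kind=kind,
        n_replicates=cfg.n_replicates,
    )


def simulate_histology(
    terminal_fa: pd.DataFrame,
    hcfg: HistologyConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Axon-density table from terminal FA via a noisy linear map.

    ``terminal_fa`` needs columns subject_id, eye, fa.  Returns per-nerve
    nf_density plus, on affected rows, the affected/fellow axon-count ratio.
    """
    out = terminal_fa.copy()
    noise = rng.normal(0.0, hcfg.noise_sd, size=len(out))
    out["nf_density"] = np.clip(hcfg.intercept + hcfg.slope * out["fa"] + noise, 0.0, None)
    out["axon_count_ratio"] = np.nan
    for sid, grp in out.groupby("subject_id"):
        eyes = grp.set_index("eye")["nf_density"]
        if "affected" in eyes.index and "fellow" in eyes.index and eyes["fellow"] > 0:
            mask = (out["subject_id"] == sid) & (out["eye"] == "affected")
            out.loc[mask, "axon_count_ratio"] = eyes["affected"] / eyes["fellow"]
    return out


def simulate_study(
    cfg: SimulationConfig | None = None,
    hcfg: HistologyConfig | None = None,
) -> StudyDataset:
    """Generate a complete synthetic study bundle.

    Per glaucoma subject: paired-eye IOP series; quantitative optic-nerve FA
    in both eyes (affected decaying by the true model scaled to the healthy
    FA level, fellow flat); the derived relative series; a secondary
    optic-radiation series coupled to the primary trajectory by
    (k_t, N_B0); and terminal histology.  Control subjects contribute flat
    baseline series only.
    """
    cfg = cfg or SimulationConfig()
    hcfg = hcfg or HistologyConfig()
    coupling = SecondaryCoupling(
        k_t=cfg.secondary_kt, n_b0=cfg.secondary_nb0, amplitude=cfg.secondary_kt
    )
    risk_series: list[RiskSeries] = []
    degen_series: list[DegenerationSeries] = []
    terminal_rows = []

    groups = [("glaucoma", i) for i in range(cfg.n_glaucoma)] + [
        ("control", cfg.n_glaucoma + i) for i in range(cfg.n_control)
    ]
    for group, idx in groups:
        affected, fellow = simulate_iop_course(cfg, idx, group=group)
        risk_series += [affected, fellow]
        rng = _rng(cfg.seed, idx, 2)
        days = _mri_days(cfg, affected, rng)
        glaucomatous = group == "glaucoma"

        quant_truth = KineticParameters(
            n0=cfg.quantitative_n0,
            r0=cfg.true_params.r0,
            beta=cfg.true_params.beta,
            gamma=cfg.true_params.gamma,
        )
        aff_on = simulate_degeneration(
            affected, cfg, true_params=quant_truth, rng=rng, days=days,
            zero_risk=not glaucomatous, region="optic_nerve", kind="quantitative",
        )
        fel_on = simulate_degeneration(
            fellow, cfg, true_params=quant_truth, rng=rng, days=days,
            zero_risk=True, region="optic_nerve", kind="quantitative",
        )
        degen_series += [aff_on, fel_on, derive_relative_series(aff_on, fel_on)]

        # secondary region: plateau + coupled exponential on the relative scale
        clean_primary = _forward(cfg, affected, days, cfg.true_params, not glaucomatous)
        clean_secondary = predict_secondary(clean_primary, coupling)
        noise = rng.normal(0.0, cfg.fa_noise_sd / np.sqrt(cfg.n_replicates), size=days.shape)
        degen_series.append(
            DegenerationSeries(
                subject_id=affected.subject_id,
                eye="affected",
                region="optic_radiation",
                days=days,
                values=np.clip(clean_secondary + noise, 1e-6, 1.0),
                kind="quantitative",
                n_replicates=cfg.n_replicates,
            )
        )
        for series in (aff_on, fel_on):
            terminal_rows.append(
                {"subject_id": series.subject_id, "eye": series.eye, "fa": series.values[-1]}
            )

    hist_rng = _rng(cfg.seed, 10_000, 3)
    histology = simulate_histology(pd.DataFrame(terminal_rows), hcfg, hist_rng)
    return StudyDataset(
        risk_series=risk_series,
        degen_series=degen_series,
        histology=histology[["subject_id", "eye", "nf_density", "axon_count_ratio"]],
    )
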
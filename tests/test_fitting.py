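import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad
from sklearn.base import clone

from riskkinetics import DegenerationSeries, KineticParameters, RiskSeries
from riskkinetics.fitting import (
    FitOptions,
    KineticDecayModel,
    ModelSpec,
    SecondaryDecayModel,
    compare_models,
    compare_secondary_models,
    f_tail_probability,
    fit_kinetic_model,
    fit_secondary_linear,
    fit_secondary_risk,
    nested_f_test,
    r_squared,
    regression_pvalue,
)
from riskkinetics.kinetics import ExcessRiskConfig, excess_pressure, pressure_cumulative_risk
from riskkinetics.simulate import SimulationConfig, simulate_study
from riskkinetics.experiments import recovery_correlation_experiment


def _f_tail_oracle(F, d1, d2):
    """Numeric integration of the F density, written from the beta function.

    The tail is mapped to the finite interval u = d2/(d2 + d1 x) so the
    quadrature is accurate to machine precision even for heavy tails.
    """
    logB = math.lgamma(d1 / 2) + math.lgamma(d2 / 2) - math.lgamma((d1 + d2) / 2)

    def integrand(u):
        x = d2 * (1 - u) / (d1 * u)
        density = (d1 / d2) ** (d1 / 2) * x ** (d1 / 2 - 1) * u ** ((d1 + d2) / 2) / math.exp(logB)
        return density * d2 / (d1 * u * u)

    value, _ = quad(integrand, 0.0, d2 / (d2 + d1 * F), limit=200, epsabs=1e-14, epsrel=1e-13)
    return value


class TestRSquared:
    def test_perfect_and_null_fits(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(3, y.mean())) == 0.0

    def test_hand_arithmetic(self):
        # RSS = 0.02, TSS = 2 -> R^2 = 0.99
        assert r_squared([1.0, 2.0, 3.0], [1.1, 2.0, 2.9]) == pytest.approx(0.99)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestFTail:
    def test_zero_statistic(self):
        assert f_tail_probability(0.0, 1, 10) == 1.0

    @pytest.mark.parametrize("F", [0.5, 2.0, 9.0, 37.9])
    @pytest.mark.parametrize("k", [3, 9, 10])
    def test_t_distribution_identity_at_df1_one(self, F, k):
        # P(F_{1,k} >= F) = 2 (1 - T_k(sqrt F))
        expected = 2.0 * stats.t.sf(np.sqrt(F), k)
        assert f_tail_probability(F, 1, k) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "F, d1, d2",
        [(29.7, 1, 3), (37.9, 1, 10), (38.6, 1, 9), (9.0, 1, 9), (3.5, 1, 8)],
    )
    def test_matches_numeric_integration_oracle(self, F, d1, d2):
        assert f_tail_probability(F, d1, d2) == pytest.approx(
            _f_tail_oracle(F, d1, d2), abs=1e-10
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            f_tail_probability(1.0, 0, 5)
        with pytest.raises(ValueError):
            f_tail_probability(-1.0, 1, 5)


def _result(rss, tss, n, spec):
    from riskkinetics.fitting import FitResult

    return FitResult(
        spec=spec,
        params=KineticParameters(n0=1.0, r0=0.001, beta=0.05, free=spec.free_parameters()),
        rss=rss,
        tss=tss,
        n=n,
        p_free=spec.p_free,
        r2=1 - rss / tss,
        p_value=np.nan,
        fitted=np.zeros(n),
        observed=np.zeros(n),
    )


class TestRegressionPValue:
    def test_perfect_fit_tends_to_zero(self):
        spec = ModelSpec("variable_risk", fix_n0=1.0)
        assert regression_pvalue(_result(1e-300, 2.0, 12, spec)) < 1e-20

    def test_fit_no_better_than_mean(self):
        spec = ModelSpec("variable_risk", fix_n0=1.0)
        assert regression_pvalue(_result(2.0, 2.0, 12, spec)) == 1.0

    def test_free_parameter_bookkeeping(self):
        # fixed N0: df1 = p_free = 2, df2 = 10; F = ((2 - 0.02)/2)/(0.02/10) = 495
        spec = ModelSpec("variable_risk", fix_n0=1.0)
        p = regression_pvalue(_result(0.02, 2.0, 12, spec))
        assert p == pytest.approx(_f_tail_oracle(495.0, 2, 10), rel=1e-6)
        assert p == pytest.approx(1.0e-10, rel=1e-3)


class TestNestedFTest:
    def test_direct_formula(self):
        reduced = _result(2.0, 4.0, 12, ModelSpec("constant_risk", fix_n0=1.0))
        full = _result(1.0, 4.0, 12, ModelSpec("variable_risk", fix_n0=1.0))
        # free-N0 variant has p_free 2 vs 3: same df arithmetic either way
        comp = nested_f_test(reduced, full)
        assert comp.df1 == 1
        assert comp.df2 == 10
        assert comp.F == pytest.approx(((2.0 - 1.0) / 1) / (1.0 / 10))

    def test_identical_rss_gives_unit_p(self):
        reduced = _result(1.0, 4.0, 12, ModelSpec("constant_risk", fix_n0=1.0))
        full = _result(1.0, 4.0, 12, ModelSpec("variable_risk", fix_n0=1.0))
        comp = nested_f_test(reduced, full)
        assert comp.F == 0.0
        assert comp.p_value == 1.0

    def test_non_nested_rejected(self):
        a = _result(1.0, 4.0, 12, ModelSpec("variable_risk", fix_n0=1.0))
        b = _result(1.0, 4.0, 12, ModelSpec("constant_risk", fix_n0=1.0))
        with pytest.raises(ValueError, match="nested"):
            nested_f_test(a, b)

    def test_optimizer_failure_floors_f_with_warning(self):
        reduced = _result(1.0, 4.0, 12, ModelSpec("constant_risk", fix_n0=1.0))
        full = _result(1.5, 4.0, 12, ModelSpec("variable_risk", fix_n0=1.0))
        with pytest.warns(RuntimeWarning, match="floor"):
            comp = nested_f_test(reduced, full)
        assert comp.F == 0.0

    def test_published_statistic_below_its_printed_bound(self):
        # F(1,10) = 37.9 for variable- vs constant-risk on relative FA
        p = f_tail_probability(37.9, 1, 10)
        assert p == pytest.approx(1.07e-4, rel=1e-2)
        assert p < 0.0005


def _make_noiseless(params, seed=3, n_subjects=5):
    """Subject-level IOP courses with exact forward-model observations."""
    rng = np.random.default_rng(seed)
    risk, degen = [], []
    for i in range(n_subjects):
        days = np.sort(np.concatenate([[0.0], rng.uniform(5.0, 160.0, size=5)]))
        iop = np.concatenate([[23.0], rng.normal(55.0, 8.0, size=5)])
        r = RiskSeries(f"s{i}", "glaucoma", "affected", days, np.clip(iop, 10, None))
        obs_days = days[-3:]
        curve = pressure_cumulative_risk(
            r.days, excess_pressure(r), params.r0, params.beta, query_days=obs_days
        )
        values = params.n0 * np.exp(-curve.R ** params.gamma)
        degen.append(
            DegenerationSeries(f"s{i}", "affected", "optic_nerve", obs_days, values, "relative")
        )
        risk.append(r)
    return degen, risk


class TestKineticDecayModel:
    def test_noiseless_generating_model_fixed_point(self):
        truth = KineticParameters(n0=1.0, r0=0.002, beta=0.06)
        degen, risk = _make_noiseless(truth)
        res = fit_kinetic_model(degen, risk, ModelSpec("variable_risk", fix_n0=1.0))
        assert res.params.r0 == pytest.approx(truth.r0, rel=1e-6)
        assert res.params.beta == pytest.approx(truth.beta, rel=1e-6)
        assert res.rss < 1e-12

    def test_constant_observations_drive_r0_to_bound(self):
        degen, risk = _make_noiseless(KineticParameters(n0=1.0, r0=0.0, beta=0.0))
        res = fit_kinetic_model(degen, risk, ModelSpec("constant_risk", fix_n0=1.0))
        assert res.params.r0 == pytest.approx(0.0, abs=1e-8)
        assert "r0_at_lower_bound" in res.flags

    def test_insufficient_data_rejected(self):
        degen, risk = _make_noiseless(KineticParameters(n0=1.0, r0=0.002, beta=0.06))
        tiny = [degen[0]]
        tiny[0] = DegenerationSeries(
            tiny[0].subject_id, "affected", "optic_nerve",
            tiny[0].days[:2], tiny[0].values[:2], "relative",
        )
        with pytest.raises(ValueError, match="insufficient"):
            fit_kinetic_model(tiny, risk, ModelSpec("variable_risk", fix_n0=1.0))

    def test_subject_order_invariance(self, default_study):
        degen = default_study.degen(region="optic_nerve", kind="relative", glaucoma_only=True)
        risk = default_study.risk_series
        spec = ModelSpec("variable_risk", fix_n0=1.0)
        forward = fit_kinetic_model(degen, risk, spec)
        backward = fit_kinetic_model(degen[::-1], risk[::-1], spec)
        assert backward.params.r0 == pytest.approx(forward.params.r0, rel=1e-8)
        assert backward.params.beta == pytest.approx(forward.params.beta, rel=1e-8)
        assert backward.rss == pytest.approx(forward.rss, rel=1e-10)

    def test_deterministic_given_seed(self, default_study):
        degen = default_study.degen(region="optic_nerve", kind="relative", glaucoma_only=True)
        a = fit_kinetic_model(degen, default_study.risk_series, "variable_risk")
        b = fit_kinetic_model(degen, default_study.risk_series, "variable_risk")
        assert a.params.r0 == b.params.r0
        assert a.params.beta == b.params.beta

    def test_relative_data_auto_fixes_n0(self, default_study):
        degen = default_study.degen(region="optic_nerve", kind="relative", glaucoma_only=True)
        est = KineticDecayModel(model="variable_risk").fit(degen, default_study.risk_series)
        assert est.spec_.fix_n0 == 1.0
        assert "n0" not in est.spec_.free_parameters()
        assert est.n_ - est.spec_.p_free == est.n_ - 2

    def test_sklearn_params_round_trip(self):
        est = KineticDecayModel(model="heterogeneity", threshold=31.0, seed=5)
        params = est.get_params()
        assert params["threshold"] == 31.0
        cloned = clone(est)
        assert cloned.get_params() == params
        cloned.set_params(threshold=29.0)
        assert cloned.threshold == 29.0

    def test_predict_matches_fitted_values(self, noiseless_study):
        degen = noiseless_study.degen(region="optic_nerve", kind="relative", glaucoma_only=True)
        est = KineticDecayModel(model="variable_risk").fit(degen, noiseless_study.risk_series)
        d = degen[0]
        risk = noiseless_study.risk_for(d.subject_id, "affected")
        pred = est.predict(risk, d.days)
        np.testing.assert_allclose(pred, d.values, rtol=1e-6)
        assert est.score(degen, noiseless_study.risk_series) > 0.999


class TestModelLadder:
    def test_variable_risk_preferred_on_variable_risk_truth(self, default_study):
        results, comparisons = compare_models(
            default_study,
            [
                ModelSpec("constant_risk", fix_n0=1.0),
                ModelSpec("variable_risk", fix_n0=1.0),
                ModelSpec("heterogeneity", fix_n0=1.0),
            ],
        )
        by_pair = {(c.reduced.spec.name, c.full.spec.name): c for c in comparisons}
        assert by_pair[("constant_risk", "variable_risk")].p_value < 0.05
        assert by_pair[("variable_risk", "heterogeneity")].p_value > 0.05
        # a free parameter never increases RSS along the nest
        rss = {r.spec.name: r.rss for r in results}
        assert rss["variable_risk"] <= rss["constant_risk"] + 1e-12
        assert rss["heterogeneity"] <= rss["variable_risk"] + 1e-12

    def test_no_risk_signal_no_improvement(self):
        cfg = SimulationConfig(
            seed=11,
            true_model="constant_rate",
            true_params=KineticParameters(n0=1.0, r0=0.002, beta=0.0),
        )
        study = simulate_study(cfg)
        _, comparisons = compare_models(
            study,
            [ModelSpec("constant_risk", fix_n0=1.0), ModelSpec("variable_risk", fix_n0=1.0)],
        )
        assert comparisons[0].p_value > 0.01

    def test_single_spec_no_comparisons(self, default_study):
        results, comparisons = compare_models(
            default_study, [ModelSpec("variable_risk", fix_n0=1.0)]
        )
        assert len(results) == 1
        assert comparisons == []

    def test_recovery_correlates_with_varied_truth(self):
        out = recovery_correlation_experiment(n_studies=40, seed=9)
        assert out["corr_r0"] > 0.8
        assert out["corr_beta"] > 0.8


class TestSecondary:
    def test_exact_line_recovery(self):
        n_a = np.array([1.0, 0.8, 0.6, 0.4])
        coupling = fit_secondary_linear(n_a, 0.4 + 0.5 * n_a)
        assert coupling.k_t == pytest.approx(0.5)
        assert coupling.n_b0 == pytest.approx(0.4)

    def test_constant_primary_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_secondary_linear(np.ones(5), np.linspace(0.4, 0.9, 5))

    def test_noiseless_risk_based_recovery(self):
        truth = KineticParameters(n0=1.0, r0=0.002, beta=0.06)
        primary, risk = _make_noiseless(truth)
        secondary = [
            DegenerationSeries(
                d.subject_id, d.eye, "optic_radiation", d.days, 0.3 + 0.7 * d.values, "relative"
            )
            for d in primary
        ]
        res = fit_secondary_risk(secondary, risk)
        assert res.coupling.n_b0 == pytest.approx(0.3, abs=1e-5)
        assert res.coupling.amplitude == pytest.approx(0.7, abs=1e-5)
        assert res.params.r0 == pytest.approx(0.002, rel=1e-3)
        assert res.params.beta == pytest.approx(0.06, rel=1e-3)

    def test_flat_series_flagged_unidentifiable(self):
        rng = np.random.default_rng(0)
        days = np.arange(0.0, 170.0, 24.0)
        risk = [
            RiskSeries(
                "s0", "glaucoma", "affected", days,
                np.clip(rng.normal(55, 5, days.size), 10, None),
            )
        ]
        flat = [
            DegenerationSeries(
                "s0", "affected", "optic_radiation",
                days[1:], np.full(days.size - 1, 0.4), "relative",
            )
        ]
        res = fit_secondary_risk(flat, risk)
        assert "amplitude_unidentifiable" in res.flags

    def test_nested_secondary_comparison_monotone(self, default_study):
        secondary = default_study.degen(region="optic_radiation", glaucoma_only=True)
        reduced, full, comp = compare_secondary_models(secondary, default_study.risk_series)
        assert full.rss <= reduced.rss + 1e-12
        assert comp.df1 == 1
        assert comp.F >= 0
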
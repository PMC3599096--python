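# riskkinetics

Risk-based stochastic kinetic modelling of neurodegeneration from
longitudinal biomarkers.

Slowly progressive neurodegenerative disease is hard to forecast because its
pace varies strongly between subjects. When a *pathogenic* biomarker that
drives the damage can be measured repeatedly — intraocular pressure (IOP) in
glaucoma is the canonical example — the course of a *neurodegeneration*
biomarker (here, fractional anisotropy, FA, of the optic nerve from
diffusion tensor imaging) can be modelled as a survival process whose hazard
follows the measured risk. This package implements that family of kinetic
models, the pooled nonlinear least-squares fitting and nested-model F-test
workflow used to choose among them, and a synthetic-study generator that
reproduces the statistical structure of a primate laser-induced glaucoma
experiment so that the whole pipeline can be validated end to end without
any imaging data.

## Models

Writing N(t) for the surviving axon density (proxied by FA or an
affected/fellow FA ratio) and r(t) for the instantaneous hazard:

| model | form | free parameters |
|---|---|---|
| constant-rate | N = N₀ − r₀·t | N₀, r₀ |
| constant-risk | N = N₀·exp(−r₀·t) | N₀, r₀ |
| variable-risk | N = N₀·exp(−∫r(t)dt), r(t) = r₀·e^{β·p(t)} | N₀, r₀, β |
| heterogeneity | N = N₀·exp(−(∫r(t)dt)^γ) | N₀, r₀, β, γ |

with p(t) = IOP(t) − 29 mmHg the excess pressure over the upper normal
limit. The cumulative risk ∫r(t)dt (the cumulative hazard of survival
analysis) is integrated from the irregular IOP measurements by the
trapezoid rule; β = 0 collapses variable- to constant-risk and γ = 1
collapses heterogeneity to variable-risk, so the ladder is nested and the
extra-sum-of-squares F-test

F = ((RSS_reduced − RSS_full)/Δp) / (RSS_full/(n − p_full))

selects the simplest adequate model. A linear transsynaptic coupling
N_B = N_B0 + k_t·N_A propagates primary loss into downstream regions
(optic radiation), giving the secondary form N_B(t) = N_B0 + A·e^{−R(t)}.
N₀ is fixed at 1 when fitting affected/fellow ratios.

## Worked example

Generate a synthetic study (5 glaucoma + 3 control subjects, IOP every
3–28 days, 2–3 MRI sessions per subject) and run the model ladder on the
relative optic-nerve FA:

```
$ riskkinetics simulate --seed 11 --out study/
$ riskkinetics compare --risk study/risk.csv \
      --degen study/degeneration_relative.csv --relative --out table1.csv
constant_risk: R2=0.514 P=5.80e-03
variable_risk: R2=0.996 P=9.62e-13
heterogeneity: R2=0.997 P=1.74e-11
constant_risk -> variable_risk: F(1,10) = 1219.55, P = 8.787e-12
variable_risk -> heterogeneity: F(1,9) = 1.80, P = 0.2128
```

The variable-risk model explains the pooled n = 12 observations far better
than constant risk (F-test on 1 and 10 degrees of freedom), while the extra
shape parameter of the heterogeneity model brings no significant
improvement — exactly the behaviour expected when the data were generated
under variable-risk truth. The single-model fit recovers the generating
parameters:

```
$ riskkinetics fit --risk study/risk.csv \
      --degen study/degeneration_relative.csv --relative --out fit.csv
variable-risk: N0=1 r0=0.00191 beta=0.0566 gamma=1 R2=0.996 P=9.62e-13 (n=12)
```

against a truth of r₀ = 0.0019/day and β = 0.057/mmHg. The same workflow is
available from Python through scikit-learn-style estimators:

```python
from riskkinetics import KineticDecayModel
from riskkinetics.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=11))
degen = study.degen(region="optic_nerve", kind="relative", glaucoma_only=True)
model = KineticDecayModel(model="variable_risk").fit(degen, study.risk_series)
print(model.params_.r0, model.params_.beta, model.r2_)
```

`riskkinetics validate-histology` correlates terminal FA with simulated
axon-density histology (Pearson with one-tailed t p-value; Spearman with an
exact permutation p for n ≤ 8 animals).

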
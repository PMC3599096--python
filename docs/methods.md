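# Methods

## The kinetic models

The package treats neurodegeneration as a one-hit survival process: each
axon dies independently with instantaneous hazard r(t), so the expected
surviving density obeys dN/dt = −r(t)·N(t) and

    N(t) = N0 · exp(−R(t)),        R(t) = ∫ r(s) ds.

The hazard is log-linear in the excess of the pathogenic biomarker over a
normal threshold, r(t) = r0·exp(β·p(t)) with p(t) = IOP(t) − θ. Setting
β = 0 yields the classical constant-risk (radioactive-decay) model; the
classical constant-rate model N = N0 − r0·t is retained as a baseline and,
by design, has no floor at zero — it can predict negative densities, a
known property of that model. The heterogeneity model N = N0·exp(−R^γ) is
the Weibull/stretched-exponential generalisation (γ < 1 stretched, γ = 1
identical to plain survival, γ > 1 compressed); it absorbs between-axon
rate heterogeneity but also, in practice, measurement-quality effects, so
fitted γ near a bound is flagged rather than interpreted. Secondary
(transsynaptic) degeneration in a region B downstream of the primary region
A is modelled as dN_B/dt = k_t·dN_A/dt, which integrates to
N_B = N_B0 + k_t·N_A and, under the survival law for N_A, to
N_B(t) = N_B0 + A·e^{−R(t)} with the amplitude A = k_t·N_A0 collapsed into
one parameter. The multiplicative multi-factor hazard
r = r0·exp(Σ βj·pj(t)) makes the family formally equivalent to a Cox
proportional-hazards model with time-dependent covariates; only the
parametric least-squares route is implemented, not partial likelihood.

## Parameters and units

| parameter | meaning | unit | default/bounds |
|---|---|---|---|
| θ | excess-pressure threshold | mmHg | 29 (the upper normal limit of IOP) |
| N0 | initial biomarker level | — | free, (1e-6, 10]; fixed at 1 for ratio data |
| r0 | baseline hazard | 1/day | free, [0, 1] |
| β | risk sensitivity | 1/mmHg | free, [−5, 5] |
| γ | heterogeneity shape | — | free, (0, 5]; boundary estimates flagged |
| k_t, N_B0 | secondary coupling slope and plateau | — | free |

p(t) is not clamped at zero by default: sub-threshold pressure simply drives
the hazard below r0 through the exponential. A clamp option exists because
the treatment of sub-threshold affected-eye values is a genuine modelling
choice. Control and fellow eyes are assigned zero cumulative risk by
convention (their r0 is zero), mirroring how normal eyes enter such
analyses.

## Cumulative-risk integration

R(t) is computed by the trapezoid rule over the irregular IOP measurement
days, starting from the first available measurement (day 0, the induction
day, in the synthetic studies). Days that must be inserted into the grid
(MRI sessions between IOP visits) interpolate the *pressure* linearly and
then exponentiate — equivalently, log r is interpolated linearly — because
pressure is the measured quantity and this preserves hazard positivity when
IOP swings widely. For a hazard exponential in time the trapezoid error
vanishes as O(h²); at a 0.01-day step the relative error against the closed
form r0(e^{βT}−1)/β is ~2×10⁻⁸. Because r depends on the fitted (r0, β),
each subject's R is recomputed at every optimizer iterate from precomputed
(day, pressure) grids; queries outside the measured IOP span raise rather
than extrapolate.

## Fitting and model selection

All glaucoma subjects are pooled with one shared parameter set (the
reference design has ~12 optic-nerve points over 5 subjects); per-subject
predicted curves come from the shared parameters applied to each subject's
own cumulative risk. Estimation is bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective, numerical
Jacobian, `x_scale="jac"`) with multistart: heuristic initial values
(N0 from the data maximum or its fixed value, r0 from a log-linear slope of
the observations against time, β swept over {0, 0.01, 0.05}, γ = 1) plus
seeded log-normal jitter, eight starts by default. Fits are deterministic
given the data and seed. Series shorter than p_free + 2 pooled points are
rejected up front.

Goodness of fit is R² = 1 − RSS/TSS about the observed mean. The fit
p-value tests the mean-only null with F = ((TSS − RSS)/df1)/(RSS/df2),
df1 = p_free minus one if a level parameter (N0 or N_B0) is free, df2 =
n − p_free — a declared convention, since no canonical significance test
exists for these nonlinear fits. Nested pairs (constant-risk ⊂
variable-risk ⊂ heterogeneity; constant- ⊂ variable-risk secondary) are
compared with the extra-sum-of-squares F-test; degrees of freedom count
only free parameters, so ratio data (N0 fixed) give the F(1, n−2) /
F(1, n−3) pattern. The full model is warm-started at the reduced optimum,
which guarantees RSS monotonicity along the nest; if an optimizer failure
still leaves RSS_full above RSS_reduced, F is floored at zero with a
warning rather than reported negative.

## The synthetic-study generator

The generator emulates the reference experiment's statistical structure:
five glaucoma and three control subjects; a subject-specific follow-up end
uniform in [33, 168] days; IOP visits at uniform 3–28-day intervals with a
day-0 pre-induction baseline; affected-eye pressures around a subject-level
mean drawn from N(54.9, 9.4²) mmHg with 8 mmHg visit-to-visit noise, fellow
eyes at N(23.2, 0.8²). The between-subject sd reconstructs subject-level
spread from a published ±4.2 standard error over five animals (4.2·√5 ≈
9.4); the within-subject visit sd is a declared guess with no published
counterpart. FA decays by the chosen generating law (variable-risk truth
r0 = 0.0019/day, β = 0.057/mmHg by default) with Gaussian noise of sd
0.02/√3, i.e. after three-replicate averaging; 2–3 MRI sessions per subject
(always including the terminal visit) give a pooled n of 10–15. The
quantitative scale uses a healthy-nerve FA level of 0.73; relative series
are derived as affected/fellow ratios of the noisy quantitative series, so
their effective noise is realistically inflated. The secondary region uses
invented coupling defaults k_t = 0.5, N_B0 = 0.4 (no measured values
exist). Terminal histology maps FA to neurofilament-positive axon density
linearly (slope 1.5×10⁵ mm⁻², noise sd 1.2×10⁴ mm⁻², chosen to put the
FA–density correlation near the observed ~0.9). All randomness flows from
one seed through per-subject `SeedSequence([seed, subject, stream])`
streams; identical seeds give byte-identical CSV exports.

What the generator does *not* emulate: imaging itself (FA enters as
numbers), spatial correlation between regions, drift or session effects in
the scanner, the second laser treatment as a discrete event (absorbed into
IOP variability), and attrition. Passing recovery/size/power checks on
these simulations therefore validates the estimator and test machinery
under the assumed generative law, not the biological adequacy of that law
for real data.

## Operating characteristics and chosen problem sizes

`riskkinetics.experiments` runs the Monte-Carlo studies used by the test
suite and the acceptance script: parameter recovery over 200 default
studies (median relative error of r0 and β, typically ~5% and ~3%); a
varied-truth variant checking estimated-vs-true correlation; nested-F
type-I error over 1000 constant-risk-truth replicates (the null rate uses
r0 = 0.0084/day, the constant-risk estimate on the reference ratio data);
power over 200 variable-risk-truth replicates; and secondary-coupling
recovery (200 OLS replicates, 150 risk-based comparisons). Monte-Carlo
fits use two warm-started optimizer starts — ample for these
well-initialised two-to-four-parameter problems — versus the interactive
default of eight.

## Statistics of the histology cross-check

Pearson correlation between FA and axon density is reported with a
one-tailed p from t = r·√(df/(1−r²)), df = n − 2, since the hypothesis is
directional. The Spearman correlation between per-animal FA ratios and
axon-count ratios uses an exact permutation p for n ≤ 8 (all n! orderings
of one rank vector enumerated; perfect agreement over five animals gives
exactly 1/120 ≈ 0.0083 one-sided); both one- and two-sided values are
reported because directionality conventions differ. Beyond n = 8 the
asymptotic approximation is used; at n = 8 and |ρ| < 0.5 the two agree
within 0.02.

## Known limitations

- (r0, β) are only weakly separable when excess pressure varies little
  across subjects and visits; the heterogeneity model's N0 and γ trade off
  strongly (boundary flags surface this rather than resolving it).
- The fit p-value convention above is one reasonable choice among several
  for nonlinear models; nested-model comparisons, which are convention-free,
  should carry the inferential weight.
- The F-test's nominal size relies on approximately Gaussian residuals and
  a correct reduced model; with n ≈ 12 the empirical size is close to but
  not exactly nominal.
- No mixed-effects layer: subjects share one parameter set, so systematic
  between-subject kinetic differences inflate residual variance rather than
  being modelled.
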
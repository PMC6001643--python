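# Methods

This note documents the statistical machinery implemented in
`ranksexplained`: the explained-variation measure, the excess hazard model
behind it, the synthetic-data generator used throughout the tests, and the
numerical and design choices that were genuinely open.

## 1. Ranks explained (RE) and its weighted form (REw)

**Model and assumptions.** RE treats each observed failure as a ranking
problem: at failure time *t*ᵢ the model's hazards order everyone still at
risk, and the measure asks how close the failing subject sits to the top of
that ordering, averaged over failures and normalised so that a perfect
model scores 1, an uninformative model 0, and a systematically reversed
model −1. Censoring is handled by inverse-probability weights
1/Ĝ(*t*⁻) from the reverse Kaplan–Meier estimator of the censoring
distribution, which is consistent under independent censoring.

In the relative-survival setting the observed events are *all-cause*
deaths. Each death is therefore weighted by
w = λ_E/(λ_E + λ_P), the model-estimated probability that it is a death
from the disease, with λ_E the fitted excess hazard and λ_P the life-table
expected hazard, both evaluated at the death time. Σw estimates the number
of disease deaths; the package reports it, its share of all deaths, and
warns when that share leaves the 30–90% band in which excess hazard
models are considered reliable.

**Conventions** (these matter and are tested):

- Risk sets are inclusive: subjects with follow-up ≥ *t*ᵢ, the failing
  subject among them; `r_null = (n+1)/2`. A singleton risk set then
  contributes zero to numerator and denominator alike.
- Hazard ties get mid-rank credit (½ each), so an all-equal-hazards model
  scores exactly 0.
- Ĝ is estimated from censorings only — deaths are never censoring events
  for Ĝ in any mode (the cause split is the weights' job, not Ĝ's) — and is
  evaluated left-continuously, with deaths preceding censorings at ties.
  Without censoring every weight is exactly 1.
- The ranking hazard is always the *excess* hazard λ_E. This is the only
  choice under which the weighted measure degenerates exactly to the
  cause-specific RE when the weights degenerate to cause indicators, which
  is the property that makes the two settings comparable.
- Default horizon τ: the last death strictly before an administrative
  censoring atom (two or more censored records sharing the maximum
  observed time), else the last death. Cumulative curves are reported at
  month 1 and then quarterly by default.
- Local REw uses a window of x = 20 failures (x/2 on either side of the
  index event, truncated at the series ends; 10-a-side is the documented
  alternative). The smoother is a running mean over the event index with a
  default span of 0.3 — a degree-0 "lowess" — and output clipped to
  [−1, 1]. The span is configurable; no canonical value exists.
- Variance: subject-level percentile bootstrap (default B = 1999,
  refitting the excess model per resample). A closed-form delta-method
  variance exists in the literature but is not reproduced here; a
  non-refitting bootstrap is available as a fast diagnostic that ignores
  estimation uncertainty.
- Tied follow-up times (administrative censoring, rounded recording) can
  be broken by `jitter_ties`: seeded symmetric perturbations of ±ε
  (default 10⁻⁶ of the median time) within tied groups, erroring if ε
  could reorder distinct times. The RE front ends apply it automatically
  when more than 5% of times are tied. Under this package's tie
  conventions the measure is in fact already stable under heavy tied
  censoring — a censoring atom multiplies later numerator and denominator
  terms by the same constant, and the mid-rank ratio is invariant to
  risk-set size — so jitter mainly serves comparability with
  implementations that use strict risk-set inequalities (see §5).

## 2. The excess hazard model

Royston–Parmar form on the log cumulative hazard scale:

ln H_E(t|x) = γ₀ + s(ln t; γ) + Σₖ βₖ′Zₖ(x) + Σₖ αₖ′[Zₖ(x) ⊗ Tₖ(ln t)]

- `s` is a restricted (natural) cubic spline in ln t, non-orthogonalised
  basis (linear column plus truncated cubics that are linear beyond the
  boundary knots). Default knots: boundary at min/max of the log event
  times, interior at quantiles (tertiles for 3 df, the default).
- Covariate blocks Zₖ: identity, categorical indicators against a declared
  reference level, or a restricted cubic spline in the covariate.
- Non-proportional effects: covariate columns interact with a spline basis
  Tₖ in ln t; one basis column (ln t itself) by default.

λ_E(t|x) = H_E(t|x) · (1/t) · ∂ln H_E/∂ln t follows analytically and *can*
be negative for some parameter vectors; the likelihood guards feasibility
at the event times (a death with λ_P + λ_E ≤ 0 has likelihood zero), and
`hazard_matrix` floors negative values at 0 (with a logged count) for
ranking and weighting. The fit reports min ∂ln H/∂ln t over the observed
event times as a monotonicity diagnostic.

The log-likelihood, dropping the expected cumulative hazard (a constant in
the parameters), is Σᵢ [dᵢ ln(λ_P,ᵢ + λ_E(tᵢ|xᵢ)) − H_E(tᵢ|xᵢ)].
Optimisation: L-BFGS-B with the analytic gradient on internally
standardised design columns (the unscaled cubic basis columns differ by
orders of magnitude); infeasible points return a large finite repelling
penalty with a gradient toward feasibility rather than +∞, which keeps the
line search informative. Start values come from a first fit that ignores
λ_P (an overall-survival model), itself started at the exponential-hazard
solution — this stabilises the excess fit when disease deaths are a
minority. The covariance is the inverse observed information (numerical
Hessian of the analytic gradient); it is withheld with a warning when
singular or indefinite. Follow-up times of exactly 0 are shifted to half
the smallest positive time with a warning (ln t must be finite). With
λ_P ≡ 0 the model *is* an ordinary cause-specific Royston–Parmar model;
the test suite verifies log-likelihood agreement with R's
`flexsurv::flexsurvspline` at fixed parameters to 10⁻⁸.

## 3. Rate tables

Life tables are dense grids of hazards per person-year over left-closed
right-open age × calendar-period cells plus categorical strata. Lookups
floor the attained age (age at diagnosis + t) and period (diagnosis date +
t) to the grid; beyond the last break the final cell is carried forward
with a logged warning rather than erroring, since follow-up routinely
outlives published tables. Cumulative expected hazards are exact
piecewise-constant integrals along the subject's joint age/period
trajectory. Loaders accept long-format delimited files with rates per
person-year, per person-month (×12), or annual death probabilities
(−ln(1−q)/width). The packaged `toy_rate_table()` is Gompertz-like
(exp(−9.8 + 0.087·age), sex × deprivation multipliers, 1%/year period
improvement) — plausible magnitudes for a high-income country, not any
country's published rates.

## 4. The synthetic-data generator

Each subject gets two independent latent death times (the net-survival
independence assumption, conditional on the covariates that stratify the
life table):

- **Expected (other-cause) time** — a month-by-month walk: each month an
  Exponential(rate = monthly λ_P at the current attained age and calendar
  month) draw is compared with one month; death within the month if
  smaller, else age one month. A subject who over-lives every month
  reaches the administrative horizon. With a constant rate this is exactly
  an exponential law (verified by Kolmogorov–Smirnov test).
- **Cancer time** — inversion sampling of the scenario's closed-form
  log cumulative excess hazard: solve H_E(t|x) = −ln u by 100-step
  bisection on ln t over [10⁻⁶, 10³] years (exact to ~10⁻¹⁵ relative for
  exponential/Weibull truths). Covariate patterns whose ln H is
  non-monotone in ln t (detected analytically from the ln-t slopes) fall
  back to numerical integration of the floored hazard on a dense ln-t
  grid; unreachable targets yield +∞ — the subject never dies of cancer.

Observed time = min(cancer, expected, horizon); the true cause label and
the true λ_E, λ_P at exit are attached for oracle weighting. Randomness
uses one spawned stream per subject index, so growing n never reshuffles
earlier subjects. Tied *death* times are jittered by default; the
administrative censoring atom at the horizon is deliberately left tied —
it is the structure one wants to study. A `round_to_months` option
emulates registry-style coarse recording.

**Packaged scenarios.** Baseline spline coefficients are *derived* by
exactly interpolating three stated net-survival targets rather than listed
as raw numbers (the unscaled cubic basis makes raw coefficients
unreadable); the targets and effects are fixed, field-realistic choices:

- `scenario_s1` — colon-like lethality (net survival 88%/74%/55% at
  0.25/1/5 y for a 70-year-old), one linear proportional age effect,
  β = 0.35 per decade. Cancer deaths come out near 73% of all deaths at
  n = 2000, inside the 30–90% band.
- `scenario_s2` — lung-like stage gradients: quadratic standardised-age
  effect multiplied by (1 + ln t), strong stage effects (β = 0, 1, 2, 3)
  that wane with time (α = 0, −0.25, −0.40, −0.55), small deprivation
  effects; stage mix 16/9/25/50%. The waning dominant effect is what makes
  late deaths less predictable and the local REw trend downward.
- `scenario_s3` — the fully proportional counterpart of s2 (flat local
  REw).

The age distribution is a truncated normal (mean 71, sd 11, bounds
40–99), sex balanced, deprivation uniform over quintiles, diagnosis
mid-2000. The quadratic-in-standardised-age shape in s2 is an explicit
stand-in for an unpublished registry-derived age transform and is labelled
as such.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real covariate distributions and their
correlations (stage–age, deprivation–life-table interactions), informative
or intermittent censoring, delayed entry, period effects in the excess
hazard, measurement error in life tables. Conclusions here are about the
estimator's correctness and qualitative behaviour, not about any specific
cancer's parameters.

## 5. Known limitations

- The analytic (delta-method) variance of RE is not implemented; intervals
  are bootstrap percentile only. `REResult.ci` reserves the slot.
- Under heavily tied administrative censoring this implementation shows
  *no* spurious convergence of local or overall REw toward 1 — by
  construction (left-continuous Ĝ, inclusive risk sets, mid-rank ties; see
  §1). Software using strict risk-set inequalities or right-continuous
  censoring weights can show that artefact, which is why the tie-jitter
  remedy exists; here jitter changes results only marginally. Users
  comparing against such software should expect discrepancies precisely in
  heavily tied data.
- Mid-rank hazard ties cap RE strictly below 1 whenever two subjects share
  a hazard at a death time — including duplicated subjects in bootstrap
  resamples, whose intervals therefore never reach exactly 1 even for a
  perfectly discriminating model.
- Time-varying covariates, delayed entry, hierarchical and multi-state
  extensions are out of scope.
- With n = 2000 cohorts the mis-specification and trend contrasts are
  sharp; at a few hundred subjects the local-REw series is noisy and the
  smoothed trend slope becomes unreliable.

## 6. Problem sizes used in the validation battery

The shipped validation (`scripts/acceptance.py`, mirrored by the
end-to-end test suite) uses: 1000 randomised small instances for the
bounds check; 50 datasets of n ≤ 200 against the brute-force double-loop
transcription (agreement to 10⁻¹²); 20 cohorts of n = 2000 for the
setting-agreement (< 0.05 at τ = 1, 5, 8 y) and sum-of-weights (< 5%)
checks; 10 cohorts each for the over-parameterisation (< 0.02 median REw
shift) and dominant-covariate-omission (> 50% drop) experiments; 5 cohorts
per arm for the local-trend contrast; and 200 replicates of n = 2000 for
excess-model bias (< 0.02) and 95% CI coverage (92–97.5%).
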
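# ranksexplained

Explained variation for excess hazard models: the **ranks explained** (RE)
measure and its weighted adaptation **REw** to the relative-survival
setting used in population-based cancer survival research.

## The problem

Cancer registries follow virtually every patient in a country, so
statistical significance says little about how *important* a prognostic
factor is. What one wants to report is how much of the variation in
survival between patients a model — and each variable in it — actually
explains. In registry data the cause of death is unknown or unreliable, so
cancer-specific mortality is modelled through the *excess hazard*: the
all-cause hazard of the patients minus the expected (background) hazard
λ_P taken from population life tables matched on age, sex, calendar year
and deprivation.

## The measure

At each failure time *t*ᵢ, every subject in the risk set *R*ᵢ (the *n*ᵢ
subjects still under observation) is ranked by model hazard. The failing
subject receives

- *r*ᵢ,null = (*n*ᵢ + 1)/2 — mean rank, a model with no information,
- *r*ᵢ,model = 1 + #{k ∈ *R*ᵢ : λₖ(*t*ᵢ) > λᵢ(*t*ᵢ)} (+ ½ per tied hazard),
- *r*ᵢ,perfect = 1 — a perfect model always ranks the failing record first,

and RE is the ratio of explained to total rank variation, with inverse
probability-of-censoring weights from the reverse Kaplan–Meier estimator Ĝ:

    RE(τ) = Σᵢ ∫₀^τ 1/Ĝ(t⁻) (r_null − r_model) dNᵢ(t)
            ───────────────────────────────────────────
            Σᵢ ∫₀^τ 1/Ĝ(t⁻) (r_null − r_perfect) dNᵢ(t)

RE lies in [−1, 1]: 1 for perfect discrimination, 0 for an uninformative
model, negative when the model ranks systematically backwards. In the
relative-survival setting each death is additionally weighted by

    wᵢ = λ_E(tᵢ|xᵢ) / (λ_E(tᵢ|xᵢ) + λ_P(tᵢ)),

its estimated probability of being a cancer death, giving **REw**; the sum
of the wᵢ estimates the number of cancer deaths, a quantity worth reporting
alongside the measure (the excess model is best used when cancer deaths are
30–90% of all deaths). REw can be reported overall, cumulatively over time
(REw(*t*)), and *locally* over a sliding window of 20 failures, smoothed
with a running-mean smoother — the local curve shows *when* the model's
covariates discriminate.

The hazard provider is a flexible parametric excess hazard model on the log
cumulative hazard scale (Royston–Parmar): ln H_E(t|x) = s(ln t; γ) + β′x,
with restricted cubic splines in ln t for the baseline, optional non-linear
covariate splines, and optional effect × ln t interactions for
non-proportional effects. Confidence intervals come from a subject-level
percentile bootstrap (refitting the model per resample).

## Worked example

`examples/03_ranks_explained.py` simulates a colon-cancer-like cohort
(n = 2000, 8-year administrative follow-up, a linear proportional age
effect of 0.35 per decade on the log cumulative excess hazard), fits the
excess model, and prints:

```
REw up to tau = 8.00 y : 0.206
sum of weights: 961.5 -> estimated cancer deaths (true count: 946)
cancer share of deaths: 74.4% (30-90% is the advisable band)
95% bootstrap CI (refitting per resample): (0.170, 0.249)
...
cause-specific RE with true labels: 0.203 (gap 0.003 -- the two settings agree)
```

Age alone explains about 21% of the rank variation in cancer survival; the
weight sum recovers the true cancer death count within 2%; and the weighted
measure agrees with the cause-specific RE computed from the (here known)
true causes of death — the property that justifies using REw when causes
are not recorded. The other scripts in `examples/` cover simulation,
model fitting, local-REw trends, and nested-model variable contributions.

A `rexw` command line (simulate / fit / re / report) drives the same
workflow from a single YAML configuration for shell use; see
`ranksexplained.workflow.RunConfig` for the schema.

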
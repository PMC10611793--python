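# Methods

This note records the models implemented in `gendiag`, the defaults of the
synthetic-cohort generator, and the numerical and design choices a
maintainer would want to know. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Gender score

The score operationalizes *gender diagnosticity*: the probability that a
person is female given a set of gender-related indicators — here, binary
presence indicators of diagnostic codes recorded at the first TBI visit.

**Code filtering.** Over the union vocabulary of the training and
validation splits, a code is removed if (a) it is carried by at most one
person in either split, or (b) all of its carriers are one sex in either
split. Rule (b) guarantees that every retained code has a non-degenerate
2×2 carriage × sex table in both splits, which protects the univariate
logistic screens from complete separation; removal is always from both
splits so the two screens share one vocabulary. Reading the "uncommon or
one-sex" rule per split ("either-set") rather than on pooled data is a
choice; `filter_codes(rule="pooled")` gives the other reading.

**Screening.** Sex (female = 1) is regressed on each code indicator alone.
With one binary covariate the logistic MLE is closed-form: the slope is the
log cross-product ratio of the 2×2 table, and the deviance against the
intercept-only model gives the likelihood-ratio p-value (χ², 1 df). The
closed form is the exact single-covariate fit — the tests cross-check it
against an iterative logistic fit. LRT rather than Wald p-values keep the
screening consistent with the LRT-based model comparison downstream.
Degenerate tables are flagged non-converged and treated as non-significant.

**Multiplicity.** Benjamini–Hochberg step-up at α = 0.05 by default,
Bonferroni selectable. Codes significant after correction in *both* splits
are selected; selection is by significance only (discordant odds-ratio
directions between splits are logged, not excluded). The selected codes
enter one multivariate logistic fit on the training split — plain maximum
likelihood, no regularization; separation raises an error pointing back at
the filters rather than silently shrinking. Held-out patients are scored by
the inverse-logit of the fitted linear predictor; codes absent from a
patient's record count as zero.

## 30-day excess mortality

Restricted to severe TBI with known 30-day survival status and complete
model covariates (complete-case analysis; exclusions are logged per rule).
Severity arrives as a category; the AIS mapping used when classifying raw
scores is mild 1–2, moderate 3, severe ≥ 4 — the boundary value 4 is
assigned to "severe" so that no category vanishes — and is configurable.

Each patient contributes one record per day until death or censoring at day
30; a death on day 0 contributes a single interval of length 0.5. The model
is a log-link Poisson regression of the event indicator with offset
`log(interval_length × annual_rate/365)`, the annual rate looked up in a
life table by (age, sex, calendar year). This is the piecewise-exponential
survival model in which covariate effects multiply the matched population
rate — an SMR-type relative rate. Controls: age (linear), ADG comorbidity
score, rurality, income quintile (linear), mechanism-of-injury indicators
(falls reference).

*Baseline parameterization.* The default baseline is a single intercept; a
30-level day factor is available (`baseline="day-factor"`). A day factor is
fragile at the cohort sizes used here (days with zero deaths), and the
comparison calculus only needs the two single-effect models to share
whatever baseline is chosen.

*Collapsing.* With the single-intercept baseline and covariates constant
within patient, the person-period likelihood is collapsed to one row per
patient (event count, log of rate-weighted exposure) before fitting; the
row-level and collapsed log-likelihoods differ by the parameter-free
constant Σ_deaths log(Δ_last/T), which is added back so reported
log-likelihoods remain on the person-period scale. Estimates, LRTs and
profiles are unaffected; fitting is ~30× faster. An exact equality test
against the directly computed piecewise-exponential likelihood guards this.

*Profile CIs.* A coefficient is profiled by moving `c·x_j` into the offset,
refitting, and locating the two roots of
`2(LL_full − LL_profile(c)) = χ²₁(0.95)` by bracketed bisection (`brentq`),
tolerance 1e-6 on the coefficient scale, with the bracket expanded outward
from the Wald radius (an unbracketable side returns ±inf with a warning —
a separation signal). Profiles are computed for the predictors of interest;
controls get Wald intervals.

## Discharge location

Restricted to acute-care records, alive at discharge (no observed death, or
death after the recorded length of stay), recorded location, complete ADG
and LOS. Outcome categories: home (reference), home with support, LTC, CCC,
rehab, other. The baseline-category logit is maximized by Newton–Raphson
with step-halving on the exact multinomial log-likelihood; convergence at
max |score| < 1e-8. The optimizer supports fixing any single coefficient,
which yields both the profile CIs (same bisection scheme as above) and
clean constrained fits. Unobserved categories are dropped with a warning
and the degrees of freedom reduced. Income quintile enters as a linear 1–5
term for symmetry with the mortality model; LOS enters linearly (its
skewness is acknowledged; a transform is a caller decision). The
supplementary analysis fits one binary logit per sublocation of "other"
(that sublocation's rows versus the home rows), skipping sublocations with
fewer than two rows.

## Sex-versus-gender comparison

Model 1 (sex + controls) and Model 2 (gender score + controls) are not
nested in each other, but both nest in Model 3 (both + controls). Two
readings are reported: the *indirect* pattern of full-model significance
(one effect significant, the other not, favours the corresponding
single-effect model) and the *direct* Bayes factor via BIC. With d₁ = d₂
the penalty cancels and `ΔBIC₁₂ = LRT_S − LRT_G`, so
`BF₁₂ ≈ exp{(LRT_S − LRT_G)/2}`; equality of degrees of freedom is asserted
at run time, and the general `ΔBIC` route (which needs an explicit n) is
available when it fails. Kass–Raftery bands: 1–3 "not worth more than a
mention", 3–20 "positive", 20–150 "strong", >150 "very strong"; boundary
values fall in the lower band; factors below 1 are inverted and attributed
to the other model. Reported Bayes factors above 10⁴ are rounded to one
significant figure (full precision kept internally). The sample size n in
the BIC penalty (patients vs person-days in the person-period layout) is
moot on the equal-df path and is an explicit argument on the general path.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real population:

- **Demographics** — 44.5% female; ages 16–64 uniform; calendar years
  2002–2019; 12.7% acute-care records; 15.5% rural; near-uniform income
  quintiles; severity distribution (unknown, mild, moderate, severe) =
  (0.486, 0.415, 0.028, 0.071).
- **Codes** — independent Bernoulli carriage per catalog code with
  sex-specific prevalences. The default catalog mixes strongly
  male-enriched rare codes, strongly female-enriched rare codes, moderately
  sex-differential common codes (which give the score its spread),
  sex-neutral common codes, two sex-exclusive codes and two near-singleton
  codes (the latter four exist to exercise the filters). A latent "true"
  score — the posterior probability of being female given carriage under
  the generating model — is stored with each cohort; it is what the fitted
  score estimates, and recovery tests fit against it.
- **Mortality** — only severe patients can die. Daily hazard =
  population daily rate × exp(Xβ) with default β: intercept 5.7
  (calibrating 30-day case fatality among severe cases to roughly 9–10% on
  top of the population rate), sex log(1.5), gender score 0, small control
  effects. Day 0 is simulated as a half-length interval from the same
  hazard (p₀ = 1 − exp(−0.5λ)) rather than as a free parameter, so the
  generator is exactly self-consistent with the person-period likelihood.
  Days 1–30 are geometric draws on the daily hazard.
- **Discharge** — acute patients alive at discharge draw a category from
  the baseline-category logit implied by the default coefficients: the
  gender score carries the signal (odds ratios 0.34 for "other", 0.45 for
  rehab, above 1 for the care facilities) and sex, conditional on the
  score, matters only for LTC (odds ratio 1.98). Sublocations within
  "other" are assigned independently of covariates, so every
  sublocation-versus-home contrast inherits the "other" odds ratios — which
  is how the sublocation recovery test constructs a known truth.
- **Missingness** — LOS (10.6%) and ADG (10.1%) masked completely at
  random after outcomes are drawn; ~2% unknown survival status. These
  exercise the complete-case filters.
- **Reproducibility** — one RNG stream per component (demographics, codes,
  mortality, discharge, missingness), all spawned from the master seed, so
  adding a component does not perturb the others.

Generator covariate effects apply to centred covariates (age − 40, LOS − 5,
ADG − 2, income − 3); centring only moves the intercept, so slopes are
directly comparable with fits on the raw scale.

**What passing tests do and do not show.** The generator draws codes
independently given sex, uses a single first event per patient, and has no
secular trends, no informative missingness, and no correlation between
comorbidity and code carriage. Parameter-recovery and power results under
these conditions demonstrate correctness of the estimators, not performance
on real administrative data, where code co-occurrence, coding-depth
differences between emergency and acute records, and informative
missingness all matter.

## Problem sizes and known limitations

Default analyses run at 20 000 simulated patients with a 50/25/25 split;
recovery suites use 5 000 severe patients (50 replicates) for the mortality
rate ratio and 20 000 acute patients for the discharge coefficients. At
these sizes the outcome models rest on a few hundred test-split patients,
so single-run Bayes factors are modest and noisy — the comparison calculus
is exercised, not showcased. Two further limitations are worth naming: the
fitted score carries measurement error relative to the latent score, so a
little genuine gender signal can be absorbed by the sex coefficient
(attenuation); and with rare categories (LTC) the discharge model's Wald
and profile intervals can be very wide or half-unbounded — the code warns
rather than hides this.
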
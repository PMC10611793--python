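# gendiag

Separating **sex** from **gender** effects on traumatic brain injury (TBI)
outcomes when the only measurement of gender available is what is encoded in
administrative diagnostic codes.

Health administrative databases record binary sex but no gender variable.
Yet many ICD-10 codes carry gendered social information — occupational
injuries, risk-taking mechanisms, partner violence — alongside purely
biological ones. `gendiag` implements the *gender diagnosticity* approach:
a **gender score** is defined as the fitted probability that a patient is
female given their recorded diagnostic codes,

```
score(x) = logit⁻¹(β₀ + Σⱼ βⱼ xⱼ),        xⱼ ∈ {0, 1} code indicators,
```

and this score (0 = "man-like", 1 = "woman-like") is then used *alongside*
binary sex in outcome models, so that the two dimensions can be weighed
against each other. The package is aimed at epidemiologists and
biostatisticians working with coded health records; since such records
cannot be redistributed, it ships a synthetic-cohort generator with known
ground truth so every stage is testable end to end.

## What it implements

1. **Code screening and score derivation** — patients × codes indicator
   matrix; removal of codes carried by ≤ 1 person or by one sex only in the
   training or validation split; univariate logistic screens of sex on each
   code with Benjamini–Hochberg (or Bonferroni) correction at α = 0.05;
   codes significant in *both* splits enter a multivariate logistic model
   fitted on the training split; held-out patients are scored.
2. **30-day excess mortality after severe TBI** — person-period (one row per
   patient-day) expansion over a 30-day window, with
   `log(interval × population daily death rate)` from a life table as a
   Poisson offset (a piecewise-exponential survival model; deaths on day 0
   occupy a half-day interval). Rate ratios carry profile-likelihood CIs.
3. **Acute-care discharge location** — six-category baseline-category logit
   ("home" reference; home with support, long-term care, complex continuing
   care, rehabilitation, other), Newton–Raphson with step-halving, profile
   CIs, plus binary logits of each sublocation inside "other" versus home.
4. **Sex-versus-gender model comparison** — for each outcome, Model 1
   (sex + controls), Model 2 (gender score + controls) and Model 3 (both)
   are fitted on identical rows. Because Models 1 and 2 spend equal degrees
   of freedom, the BIC approximation to the Bayes factor collapses to

   ```
   BF₁₂ ≈ exp{(LRT_S − LRT_G)/2},
   ```

   with `LRT_S`, `LRT_G` the full-model likelihood-ratio statistics; the
   result is read on the Kass–Raftery scale (>150 "very strong").

## Worked example

```bash
gendiag run-all --n 20000 --seed 1 --out demo_run
```

simulates 20 000 patients under the default study conditions (44.5% female,
7.1% severe TBI, 12.7% acute-care records), splits 50/25/25, derives the
score on train+validation and evaluates both outcome models on the test
split. It prints (abridged):

```json
{
  "n_selected_codes": 23,
  "mortality": {
    "lrt_sex": 2.88, "lrt_gender": 0.30,
    "bf_sex_over_gender": 3.63,
    "interpretation": "positive", "favored": "sex",
    "indirect_verdict": "neither effect significant: equivocal"
  },
  "discharge": {
    "lrt_sex": 8.73, "lrt_gender": 9.56,
    "bf_gender_over_sex": 1.52,
    "interpretation": "not worth more than a mention",
    "favored": "gender_score"
  }
}
```

Reading this: 23 of the catalog's sex-differential codes were replicated in
both screens and define the score; in the full mortality model the sex LRT
(2.88) exceeds the gender LRT (0.30), a Bayes factor of
exp((2.88 − 0.30)/2) ≈ 3.6 — *positive* but unremarkable evidence favouring
the sex-only model at this desk scale (331 severe test patients, 28 deaths —
8.5% case fatality). The discharge comparison (511 patients) is essentially
equivocal with a slight lean toward the gender score. Larger simulated
cohorts sharpen both comparisons. `demo_run/` also contains the screening
tables, score distribution summaries, Table-1-style characteristics and the
model reports as CSV.

Individual stages are available as `gendiag simulate`, `derive-score`,
`fit-mortality`, `fit-discharge` and `compare`, e.g.

```bash
gendiag compare --lrt-s 11.50 --lrt-g 1.18
# -> {"bf_sex_over_gender": 174.16…, "interpretation": "very strong", …}
```

## Layout

```
src/gendiag/
  synthetic.py   cohort + life-table generator and CSV round-trip
  codes.py       indicator matrix, code filters, train/validation/test split
  score.py       screening, multiplicity correction, score model, scoring
  mortality.py   person-period expansion, offset Poisson models
  discharge.py   baseline-category logit, "other" sublocation logits
  compare.py     LRT, ΔBIC, Bayes factors, Kass–Raftery interpretation
  pipeline.py    orchestration, reports, Table-1 summary
  cli.py         click command-line interface
docs/methods.md  modelling assumptions, defaults and limitations
```
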
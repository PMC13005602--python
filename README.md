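# survtransport

Transport randomized-trial survival results to an external target population
observed through a complex survey.

Given a combined sample of trial participants (treatment `A`, right-censored
time `U`, event indicator `delta`, covariates `X`) and survey records of the
target population (covariates plus design weights `1/p_i`), the package
estimates the counterfactual survival functions `S1(t)`, `S0(t)` and their
difference `delta(t)` — the target average survival treatment effect (TASTE) —
with:

- **IPW1 / IPW2** — inverse-odds-of-sampling weighting combined with inverse
  probability of censoring weighting (Horvitz–Thompson-type and
  self-normalized Hajek-type);
- **DR1 / DR2** — augmented doubly robust estimators adding a failure-time
  outcome regression and a censoring-martingale augmentation; consistent when
  either the sampling + censoring models or the outcome model is correct;
- **OM** — the pure outcome-regression estimator;
- **WKM** — an inverse-odds-weighted Kaplan–Meier reference that ignores
  covariate-dependent censoring.

All estimators incorporate survey weights in the correct places (score fit,
final normalization, and/or the outcome-regression term, depending on the
estimator), and each weighting/DR estimator carries an approximate
influence-function variance with Wald confidence intervals that deliberately
ignores nuisance-estimation uncertainty. Covariate balance between the
weighted trial and the survey-weighted target can be checked with
standardized mean differences.

A simulator reproduces the benchmark data-generating process (logistic trial
selection, logistic survey inclusion, per-arm exponential-baseline Cox
failure times, Cox or uniform censoring), and a Monte Carlo harness
summarizes Bias / ESD / ASE / coverage across model-specification grids.

## Library quick start

```python
import survtransport as st

sample = st.read_sample("sample.csv", pi=0.5)          # or st.generate(...)
score  = st.fit_sampling_score(sample, ["X1", "X2", "X3"])
omega  = score.predict_sample(sample)
cens   = {a: st.fit_censoring_model(sample, a, ["X1", "X2", "X3"]) for a in (0, 1)}
outm   = {a: st.fit_outcome_model(sample, a, ["X1", "X2", "X3"], family="cox")
          for a in (0, 1)}

est = st.estimate_dr2(sample, omega, cens, outm, times=[0.128, 0.331, 0.712])
print(est.to_frame())          # time, S1, S0, delta, se, ci_lo, ci_hi
delta, se, ci = st.taste(est, 0.712)
```

## Command line

```bash
survtransport simulate --scenario weak-cox --seed 7 --out sample.csv
survtransport balance  --input sample.csv --covariates X1,X2,X3
survtransport estimate --input sample.csv --estimator dr2 \
    --times 0.128,0.331,0.712 --outcome-family cox --pi 0.5
survtransport truth    --scenario weak-cox --times 0.128,0.331,0.712
survtransport mc-benchmark --scenario weak-cox --reps 500 \
    --estimators wkm,ipw1,ipw2,dr1,dr2 --seed 11 --out table_weak.csv
```

Scenario presets combine `weak`/`strong` trial selection with `cox`/`uniform`
censoring (e.g. `strong-uniform`).

## Input format

Delimited text (comma or tab) with a header: `S` (trial indicator), `A`, `U`,
`delta` (required for `S=1` rows), optional `w_survey` (defaults to 1, the
fully observed population case), optional `id`/`D`, and one column per
covariate. Column names are remappable via a schema map
(`read_sample(path, schema={"S": "trial", ...})`). The randomization
probability `pi` is sample-level metadata (default 0.5).
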
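# moralchoice

A tested, reusable pipeline for money–pain trade-off experiments on moral
decision-making. It covers the full analysis chain of a two-context
(monetary gain vs. loss), two-recipient (self vs. other), optionally
two-treatment (placebo vs. oxytocin) within-subject design:

1. **`trialgen`** — stimulus construction: an exhaustive 19 × 99 pool of
   (shock-difference, money-difference) pairs, per-condition desired-ratio
   grids, concrete option magnitudes, the gain→loss sign-flip-and-swap
   transform, and the pain-calibration sigmoid fit.
2. **`cohort`** — synthetic cohorts: correlated trait profiles (IH, IB, EC),
   per-subject harm-aversion weights with a built-in
   hyperaltruism/context/treatment pattern, harm-framing reports forming a
   moderated IH → framing → sensitivity mediation chain, and softmax choice
   simulation.
3. **`model`** — the harm-aversion choice model
   `P(less painful) = 1 / (1 + exp(-γ(κΔs − (1−κ)Δm)))` with per-condition
   κ, multi-start bounded MLE per subject/session, AIC/BIC model-variant
   comparison, and the hyperaltruism index κ_other − κ_self.
4. **`regressions`** — per-subject per-cell penalized logistic regressions of
   choice on Δm and Δs, recipient contrasts (relative harm/money
   sensitivity), paired group tests, and the 8-term trait × context OLS.
5. **`mediation`** — moderated mediation (mediator and outcome models,
   context-specific indirect effects ab, moderation index Δab) with a
   cluster (subject-level) bootstrap for CIs and p-values.
6. **`stats`** — within-subject ANOVA with partial η² and simple effects,
   tie-corrected Friedman tests with Bonferroni pairwise follow-ups,
   Cohen's f², and noncentral-F post-hoc power for regression F tests.
7. **`pipeline` / `cli`** — configuration, validation, orchestration and the
   `moralchoice` command.

Everything runs on synthetic data; no downloads are required.

## CLI

```bash
moralchoice generate-trials --n-per-cell 60 --seed 1 --out trials.csv
moralchoice simulate --n-subjects 46 --study study2 --seed 1 --out sim/
moralchoice fit --choices sim/choices.csv --restarts 300 --seed 1 --out fits.csv
moralchoice analyze --choices sim/choices.csv --out sensitivities.csv
moralchoice mediate --data mediation.csv -B 5000 --seed 1 --out mediation.json
moralchoice power --f2 0.491 --predictors 7 --n 46
moralchoice run-all --profile ci --seed 1 --out run/
moralchoice validate run/
```

`run-all` executes every stage (simulate → fit → sensitivities → trait
regressions → mediation → ANOVA/Friedman/power report) and writes a
manifest with per-file checksums; reruns with the same config and seed are
byte-identical. The `ci` profile uses 50 MLE restarts and 1000 bootstrap
draws; `full` uses 300 and 5000.

## Notes on estimation choices

- Group-level sensitivity analyses use a two-stage estimator (per-subject
  ML, then paired tests / OLS on the per-subject contrasts) rather than a
  full random-slope GLMM; the per-subject contrasts are the quantities the
  downstream analyses consume.
- The mediation bootstrap resamples subjects with their paired context
  rows to respect the repeated-measures structure; CIs are percentile
  (bias-corrected available via a flag).
- Trial generation draws among near-closest ratio pairs (stratified over
  shock-difference levels) and regenerates deterministically until
  |corr(Δs, Δm)| < 0.1, keeping stimulus differences uncorrelated across a
  session.
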
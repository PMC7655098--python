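# beliefupdate

Scoring and prognostic modelling for the **belief-update task** in euthymic
bipolar-disorder cohorts.

Bipolar disorder alternates mood episodes with symptom-free *euthymia*.  The
belief-update task quantifies how a person revises probability estimates of
adverse life events after seeing the population base rate: trials where the
base rate is *below* the first estimate deliver **good news**, trials where
it is *above* deliver **bad news**, and the per-trial **update** is the
belief change signed toward the information,

```
update(good) = E1 − E2        update(bad) = E2 − E1
UpdateBias   = mean update(good) − mean update(bad)
```

A positive update bias means preferentially taking in good news — optimistic
updating.  This package implements the full analysis pipeline that asks
whether that bias, measured during euthymia, predicts how long a patient
stays well:

- **`task`** — trial classification, update/memory-error arithmetic,
  per-subject scores and the good-minus-bad Δ control covariates, paired
  good-vs-bad t-tests;
- **`outcomes`** — months in euthymia censored at the 60-month follow-up
  horizon, natural-log transform, skewness/KS normality diagnostics;
- **`regression`** — the registered model family
  `log(months) = b0 + b1·UpdateBias + controls (+ clinical covariates)`,
  fitted by OLS with standardized betas, case-resampling bootstrap CIs
  (percentile, optional BCa), VIF collinearity diagnostics and the
  Fisher-z power calculation;
- **`averaging`** — exhaustive fitting of all 2^p − 1 predictor subsets with
  BIC weights `w ∝ exp(−ΔBIC/2)`, averaged coefficients and a BIC ranking;
- **`validation`** — leave-one-out refitting with predicted-vs-actual r,
  paired t and prediction SSE, plus ablation comparisons;
- **`simulate`** — a synthetic-cohort generator with retained ground truth so
  every stage is testable without patient data;
- **`io` / `pipeline` / `cli`** — CSV schemas, an end-to-end runner and a
  `beliefupdate` command-line front end.

Intended for clinical-research analysts working with this task family; the
library is organised around `EuthymiaModel` (data + model specification) and
the results object its `fit()` returns, in the style of statsmodels.

## Worked example

A synthetic 36-subject cohort with a strong generating effect of the update
bias (0.15 log-months per percentage point):

```python
import beliefupdate as bu

cfg = bu.SyntheticConfig(b1_bias=0.15)
sim = bu.simulate_cohort(cfg, seed=7)
scores = bu.score_cohort(sim.trials)          # per-subject update bias + Δ controls
cohort = bu.build_outcomes(sim.cohort)        # censored log months in euthymia
res = bu.EuthymiaModel.from_scores(scores, cohort, "model1").fit()
print(res.summary())
```

```
EuthymiaModel 'model1': log_months ~ update_bias + mean_first_estimate + ...
n = 36 (dropped 0 incomplete), R² = 0.809, SSE = 8.673, BIC = -1.07
                          coef      se       t       p    beta     vif
term
const                   1.1002  1.8517  0.5941  0.5582     NaN     NaN
update_bias             0.1218  0.0141  8.6609  0.0000  0.9047  1.3155
mean_first_estimate     0.0224  0.0471  0.4751  0.6392  0.0957  4.8886
...
```

The raw `update_bias` coefficient (0.122 log-months per point of bias)
recovers the generating 0.15 up to sampling noise at n = 36; `beta` is the
standardized coefficient and the VIF of 1.32 (< 4) shows the bias is not
collinear with the controls.  Continuing with the same objects:

```python
ci  = res.bootstrap_ci(n_boot=10_000, seed=7)   # update_bias raw 95% CI: 0.089–0.157
avg = res.model.average()                       # 4095 subset models
avg.table.loc["update_bias", "estimate"]        # BIC-weighted beta: 0.892
avg.top_k_membership(8)["update_bias"]          # present in all 8 best models
full, reduced = bu.ablate(res.model, "update_bias")
cmp = bu.compare_models_loo(full, reduced)
print(cmp["with"].summary()); print(cmp["without"].summary())
```

```
leave-one-out validation of 'model1' (n = 36)
  predicted vs actual r = 0.748 (p = 0.0000)
  paired t(35) = 0.169 (p = 0.8664)
  prediction SSE = 21.34
leave-one-out validation of 'model1_without_update_bias' (n = 36)
  predicted vs actual r = -0.259 (p = 0.1277)
  paired t(35) = -0.044 (p = 0.9650)
  prediction SSE = 86.65
```

Held-out predictions correlate strongly with the observed outcomes only when
the update bias is in the model (SSE 21.3 vs 86.7) — the bias carries the
predictive signal.  The same analyses run from the shell:

```sh
beliefupdate simulate --seed 7 --out-dir data/
beliefupdate score --trials data/trials.csv --out scores.csv
beliefupdate fit --model model1 --data merged.csv --boot 10000 --seed 17 --out fit.json
beliefupdate power --r 0.5          # required n = 23
beliefupdate run-all --seed 7 --out-dir results/
```

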
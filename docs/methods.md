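# Methods

## Task scoring

Trials are valenced by comparing the presented base rate with the first
estimate: *good news* when the base rate is lower, *bad news* when higher.
Ties and trials without a first or second estimate are excluded — equality
admits no valence, and an unanswered trial has no update.  Updates are signed
toward the information (`E1 − E2` for good news, `E2 − E1` for bad), so
positive values always mean movement toward the base rate, and per-subject
means are taken separately by valence over the available trials (pairwise
deletion at the trial level).  The update bias is exactly
`mean update(good) − mean update(bad)`.

Every other task measure — estimation error, memory error, reaction times,
trial counts and the five likert ratings — is summarised as a good-minus-bad
Δ, in the measure's native units, and used as a regression control.  Two
scoring choices deserve note:

- **Δ estimation error** is computed on absolute errors
  `|base − E1|` by default.  The signed error `base − E1` is negative on
  every good-news trial and positive on every bad-news trial by definition,
  so its Δ is perfectly confounded with valence and carries no subject-level
  information; the magnitude version captures how far estimates sat from the
  truth in each valence.  A `signed_estimation_error` flag restores the
  signed variant.
- Subjects with no scorable trial in either valence cannot contribute an
  update bias and are dropped with a logged warning; subjects missing an
  entire rating block keep their task scores but fall out of any model that
  needs the missing Δ (complete-case analysis per model).

Percentages stay on the 0–100 scale throughout; no trimming, winsorising or
proportion rescaling is applied.  The paired good-vs-bad comparison of any
measure is a classic paired t (equivalently a one-sample t on the
differences, which the tests exploit as an oracle); when every difference is
exactly zero the statistic is reported as t = 0 rather than an error, while
a constant nonzero difference (zero variance, undefined t) raises a
degenerate-input error.

## Outcome construction

The outcome is the time from task completion to the next mood episode, in
months, up to a 60-month follow-up horizon.  Subjects who do not relapse
within the horizon are assigned 60 months — this censor-as-observed
treatment is deliberately simple, matching the regression framing rather
than survival modelling, and is a known limitation: it shrinks slopes
slightly when the censored fraction is large.  Months are natural-log
transformed (any log base only rescales coefficients, leaving t and p
unchanged).  Diagnostics report the adjusted Fisher–Pearson skewness
(`n/((n−1)(n−2))·Σz³`, the convention of the common commercial packages;
the uncorrected moment estimator sits behind a flag) and a Lilliefors-style
KS statistic against a normal with estimated mean and sd.  No p-value is
attached to the KS statistic: plugging in estimated parameters invalidates
the standard null table, and exact Lilliefors p-values are out of scope.
Next-episode polarity is coded −1 (depressive) / +1 (manic), missing for
censored subjects.

## Regression family

All models are OLS with intercept on complete cases.  `model1` regresses
log months on the update bias plus eleven task controls (mean first
estimate and the Δs of estimation error, memory error, trial count, both
reaction times and the five ratings).  Variants swap the bias for the good-
and/or bad-news update means, restrict to the significant subjective
ratings, add next-episode polarity and its interaction with the bias
(relapsers only — censored subjects have no next episode), or add eleven
demographic/clinical covariates (`model2`), optionally with trait optimism
or past-episode count.

Reported alongside the raw coefficients are **standardized betas** (OLS on
the z-scored outcome and design, interaction columns standardized as
columns, the convention of the reporting software this field uses;
standardized betas can exceed 1 under collinearity).  Uncertainty comes from
a **case-resampling bootstrap**: subjects are resampled with replacement,
the model refitted per replicate, and 95% percentile bounds taken (BCa with
jackknife acceleration behind a flag); rank-deficient replicates are redrawn
and counted.  Both raw-scale and standardized-scale intervals are emitted,
since either convention is defensible for reporting.  **VIF** is
`1/(1−R²_j)` from regressing each design column on the others plus
intercept, with values below 4 read as no collinearity concern and perfect
collinearity reported as infinite with a warning.

**BIC** uses the Gaussian-likelihood form `n·ln(SSE/n) + k·ln(n)` with k
counting the coefficients (intercept included) plus the error variance.
Constants shared by all models on the same rows cancel in ΔBIC, which is all
the averaging uses.

The design-stage power calculation inverts the Fisher-z approximation,
`n = ((z_{1−α/tails} + z_{power})/atanh r)² + 3`, rounded to nearest.  The
default is one-tailed, which for r = 0.50, α = 0.05, power 0.80 gives
n = 23 (two-tailed gives 29); the one-tailed default mirrors the directional
hypothesis this design tests and is stated explicitly wherever the number is
reported.

## Model averaging

All 2^p − 1 non-empty predictor subsets (intercept always included) are
fitted on the identical complete-case rows of the full model, so their BICs
are comparable; with the 12 task predictors that is 4095 models.  Weights
are `w_m ∝ exp(−ΔBIC_m/2)` — the standard information-criterion weighting;
weighting by raw 1/BIC was rejected as scale- and shift-dependent.  The
headline averaged coefficient is **conditional**: the weighted mean of a
predictor's standardized beta over the subsets containing it, weights
renormalized over that sub-family (a predictor absent from many subsets can
still carry a substantial estimate, which is how a nonzero weighted estimate
for a sparsely-included predictor arises).  The **full** average imputing
zero when absent is emitted alongside, as are CIs from the model-averaged
standard error `Σ w̃·sqrt(se² + (β − β̄)²)`; no single CI convention is
privileged.  Ranking is by ascending BIC with ties broken by fewer
predictors, then inclusion mask; membership counts in the k best models are
available for any k.

## Leave-one-out validation

Each complete-case subject is held out in turn and predicted from a model
fitted to the rest; the prediction never sees the held-out outcome.
Evaluation uses the Pearson correlation of predicted vs actual log months,
a paired t-test of their means, and the prediction SSE; comparing SSE with
and without the update bias (on the intersection of complete cases)
quantifies its predictive contribution.  Censored subjects are retained at
the horizon value exactly as in fitting, and everything is evaluated on the
log scale, with back-transformed months available for readability.  The
refit-per-fold implementation is cross-checked in the tests against the
PRESS identity `Σ(eᵢ/(1−hᵢᵢ))²`.

## Synthetic cohort generator

The generator emulates the *structure and moments* of a belief-update
prognosis cohort, not the cognitive mechanism (no Bayesian-learner or
reinforcement-learning process).  Defaults, chosen once as a realistic
calibration and kept fixed:

| parameter | default | rationale |
|---|---|---|
| subjects × events | 36 × 40 | study-sized cohort; standard 40-event task |
| base rates | uniform [10, 70]% | the task's stimulus range |
| responses | integers clipped to [3, 77]% | the task's permitted response range |
| mean update | 10 points | typical movement toward the information |
| bias mean ± sd | 5 ± 10 points | wide asymmetry spread in a patient cohort |
| update noise sd | 3 points | trial-level variability around a subject's asymmetry |
| first estimates | base + subject offset (sd 6) + noise (sd 10) | miscalibrated priors; yields both valences per subject |
| recall noise sd | 8 points | imperfect memory of base rates |
| rating shift | +0.35 likert units (good − bad) | reproduces significant good-vs-bad rating differences |
| missing responses | N(4.73, 4.03) trials/subject | observed missing-response rate in this task |
| outcome | log m = 2.1 + 0.04·bias + effects + N(0, 0.7) | median ≈ 10 months to relapse (about half of patients relapse within a year), small censored tail at 60 months |
| antidepressant effect | −0.35 log-months | the one nonzero clinical effect by default |

Second estimates are first ∓ (valence-specific update + noise), rounded and
clipped to the response bounds; clipping after noise is simpler than
truncated sampling and induces a small boundary mass, which shrinks realized
updates by ~2% relative to the drawn parameters (measured at large n).
Relapse months are floored at 0.25 (relapses register at follow-up visits);
polarity is assigned at random among relapsers, reflecting the absence of a
polarity-specific effect in this design.  The three stimulus lists of the
real task are collapsed into one event catalogue, as no list effects are
modelled.

Ground truth is retained at two levels: drawn subject parameters (true bias,
latent log months) and realized per-valence bookkeeping computed by direct
arithmetic over exactly the trials a scorer keeps — the latter lets the
scoring pipeline be checked to machine precision, the former anchors
parameter recovery.

This calibration keeps the regression estimand essentially consistent:
measurement attenuation from scoring 40 trials is ≈1% (reliability of the
scored bias ≈ 0.99 at bias sd 10), clipping ≈2%, censoring ≈1–2%, so the
pipeline's update-bias coefficient recovers the generating value within a
few percent with near-nominal bootstrap coverage.  Passing recovery tests
therefore demonstrates the *pipeline* is unbiased under these conditions;
they do not show that a real cohort — with heavier censoring (6/36 in a
5-year study is common), fewer trials, or response styles the generator does
not model (anchoring, digit preference, informative missingness) — would
estimate its population effect without attenuation.  The simulation sizes
used in the tests and the acceptance script (200 replicates of 500-subject
cohorts with 500 bootstrap resamples; 100 cohorts for the ablation contrast)
were chosen to make the Monte-Carlo error small relative to the tolerances
while keeping a default run in the minutes range.

## Numerical and design choices

- Complete-case analysis per model; dropped-row counts are always reported.
- Exact-equality classification of ties (no tolerance): estimates and base
  rates are integers in practice.
- Rank deficiency is detected via matrix rank and reported with the
  offending columns (QR diagonal); bootstrap replicates that are
  rank-deficient by resampling are redrawn, not silently dropped.
- Zero-SSE fits report BIC = −∞, which orders exact fits first in averaging
  without special-casing.
- All randomness flows through `numpy.random.default_rng` seeds; a fixed
  seed reproduces cohorts, bootstraps and reports byte-for-byte.
- The subset-enumeration guard refuses more than 20 predictors (over a
  million OLS fits) with advice to reduce the candidate set.

## Known limitations

Censoring-as-observed biases slopes toward zero as the censored fraction
grows; the package intentionally reproduces that analysis choice rather
than fitting a survival model.  The bootstrap is case-resampling only —
small cohorts with influential subjects may prefer BCa (provided) or
residual schemes (not provided).  Model averaging is exhaustive only; no
stochastic search is offered for larger predictor sets.  The generator's
likert ratings are rounded Gaussians, adequate for mean-shift checks but
not for ordinal-model development.
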
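"""Scoring of the belief-update task.

In the task a participant first estimates the probability of an adverse life
event happening to them (*first estimate*), is shown the population base rate
(*information*), and later re-estimates the same event (*second estimate*).
A trial delivers *good news* when the base rate is below the first estimate
(the event is less likely than feared) and *bad news* when it is above.  The
trial-level *update* is the belief change signed so that positive values mean
movement toward the information:

    update(good news) = first estimate − second estimate
    update(bad news)  = second estimate − first estimate

The per-subject *update bias* — mean update on good-news trials minus mean
update on bad-news trials — is the headline measure of valence-dependent
(optimistic) updating.  All other task measures are summarised per subject as
good-minus-bad differences (the "delta" covariates) used as regression
controls downstream.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, UnscorableSubjectError, ValidationError

logger = logging.getLogger(__name__)

GOOD, BAD, EXCLUDED = "good", "bad", "excluded"

#: Permitted response range for probability estimates, in percent.
ESTIMATE_BOUNDS = (3.0, 77.0)
#: Range of the true event base rates, in percent.
BASE_RATE_RANGE = (10.0, 70.0)

#: Trial-level columns a trial table must provide.
TRIAL_COLUMNS = [
    "subject_id",
    "event_id",
    "first_estimate",
    "base_rate",
    "second_estimate",
    "recalled_rate",
    "rt_first",
    "rt_second",
    "familiarity",
    "prior_experience",
    "vividness",
    "arousal",
    "negativity",
]

#: Task measures summarised per valence and differenced good-minus-bad.
DELTA_VARIABLES = [
    "estimation_error",
    "memory_error",
    "rt_first",
    "rt_second",
    "familiarity",
    "prior_experience",
    "vividness",
    "arousal",
    "negativity",
]

LIKERT_VARIABLES = ["familiarity", "prior_experience", "vividness", "arousal", "negativity"]


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_trial(first_estimate: float | None, base_rate: float) -> str:
    """Label one trial ``good`` / ``bad`` / ``excluded``.

    Good news: the presented base rate is lower than the participant's first
    estimate.  Bad news: it is higher.  Trials with equal values, or with a
    missing response, cannot be assigned a valence and are excluded.
    """
    lo, hi = BASE_RATE_RANGE
    if _is_missing(base_rate):
        raise ValidationError("base_rate is missing; a trial always presents a base rate")
    if not lo <= base_rate <= hi:
        raise ValidationError(f"base_rate={base_rate!r} outside [{lo}, {hi}]")
    if _is_missing(first_estimate):
        return EXCLUDED
    elo, ehi = ESTIMATE_BOUNDS
    if not elo <= first_estimate <= ehi:
        raise ValidationError(f"first_estimate={first_estimate!r} outside [{elo}, {ehi}]")
    if base_rate < first_estimate:
        return GOOD
    if base_rate > first_estimate:
        return BAD
    return EXCLUDED


def compute_update(first_estimate: float, second_estimate: float, valence: str) -> float:
    """Signed belief change toward (+) or away from (−) the information."""
    if valence == GOOD:
        return first_estimate - second_estimate
    if valence == BAD:
        return second_estimate - first_estimate
    raise ValueError(f"update is undefined for valence={valence!r}; only good/bad trials carry one")


def compute_memory_error(presented: float, recalled: float | None) -> float:
    """Absolute recall error |presented − recalled|; missing recall propagates as NaN."""
    if _is_missing(recalled):
        return float("nan")
    return abs(presented - recalled)


def classify_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-trial derivations over a trial table.

    Adds ``valence``, ``update``, ``estimation_error`` (absolute),
    ``estimation_error_signed`` (base rate − first estimate) and
    ``memory_error`` columns.  Rows with a missing first *or* second estimate
    get valence ``excluded`` and no update.
    """
    out = trials.copy()
    first = out["first_estimate"].astype(float)
    second = out["second_estimate"].astype(float)
    base = out["base_rate"].astype(float)

    if base.isna().any():
        raise ValidationError("base_rate contains missing values")
    bad_base = ~base.between(*BASE_RATE_RANGE)
    if bad_base.any():
        rows = list(out.index[bad_base][:5])
        raise ValidationError(f"base_rate outside {BASE_RATE_RANGE} at rows {rows}")
    for col, series in (("first_estimate", first), ("second_estimate", second)):
        oob = series.notna() & ~series.between(*ESTIMATE_BOUNDS)
        if oob.any():
            rows = list(out.index[oob][:5])
            raise ValidationError(f"{col} outside {ESTIMATE_BOUNDS} at rows {rows}")

    responded = first.notna() & second.notna()
    valence = np.select(
        [responded & (base < first), responded & (base > first)],
        [GOOD, BAD],
        default=EXCLUDED,
    )
    out["valence"] = valence
    toward = np.where(valence == GOOD, first - second, second - first)
    out["update"] = np.where(np.isin(valence, [GOOD, BAD]), toward, np.nan)
    out["estimation_error_signed"] = base - first
    out["estimation_error"] = (base - first).abs()
    out["memory_error"] = (base - out["recalled_rate"].astype(float)).abs()
    out["missing_response"] = ~responded & (first.isna() | second.isna())
    return out


def _valence_means(trials: pd.DataFrame, variables: Iterable[str]) -> dict[str, float]:
    res: dict[str, float] = {}
    good = trials[trials["valence"] == GOOD]
    bad = trials[trials["valence"] == BAD]
    for var in variables:
        g = good[var].astype(float).mean()
        b = bad[var].astype(float).mean()
        res[f"{var}_good"] = g
        res[f"{var}_bad"] = b
        res[f"delta_{var}"] = g - b
    return res


def score_subject(trials: pd.DataFrame, signed_estimation_error: bool = False) -> pd.Series:
    """Collapse one subject's classified trials into the per-subject scores.

    Per-valence means are taken over non-missing trials only (pairwise
    deletion at the trial level).  ``signed_estimation_error`` switches the
    Δ-estimation-error control from absolute to signed errors.

    Raises :class:`UnscorableSubjectError` when the subject has no valid
    update in either valence — such subjects cannot contribute an update bias.
    """
    n_total = len(trials)
    valence = trials["valence"]
    n_missing = int(trials["missing_response"].sum())
    n_excluded = int((valence == EXCLUDED).sum()) - n_missing
    good_updates = trials.loc[valence == GOOD, "update"].dropna()
    bad_updates = trials.loc[valence == BAD, "update"].dropna()
    if good_updates.empty or bad_updates.empty:
        raise UnscorableSubjectError(
            f"subject {trials['subject_id'].iloc[0]!r}: "
            f"{len(good_updates)} good and {len(bad_updates)} bad scorable trials"
        )

    scores: dict[str, float] = {
        "n_trials": n_total,
        "n_good": int((valence == GOOD).sum()),
        "n_bad": int((valence == BAD).sum()),
        "n_excluded": n_excluded,
        "n_missing": n_missing,
        "mean_update_good": good_updates.mean(),
        "mean_update_bad": bad_updates.mean(),
        "mean_first_estimate": trials["first_estimate"].astype(float).mean(),
    }
    scores["update_bias"] = scores["mean_update_good"] - scores["mean_update_bad"]
    scores["delta_n_trials"] = scores["n_good"] - scores["n_bad"]

    variables = list(DELTA_VARIABLES)
    if signed_estimation_error:
        variables[variables.index("estimation_error")] = "estimation_error_signed"
    means = _valence_means(trials, variables)
    if signed_estimation_error:  # keep downstream column names stable
        means = {k.replace("estimation_error_signed", "estimation_error"): v for k, v in means.items()}
    scores.update(means)
    return pd.Series(scores)


def score_cohort(
    trials: pd.DataFrame,
    signed_estimation_error: bool = False,
    drop_unscorable: bool = True,
) -> pd.DataFrame:
    """Score every subject in a (raw or classified) trial table.

    Vectorised equivalent of applying :func:`score_subject` per subject.
    Returns one row per scorable subject, indexed by ``subject_id``.
    Unscorable subjects (no good or no bad news trials) are dropped with a
    logged warning, mirroring how such subjects are excluded from analysis.
    """
    if "valence" not in trials.columns:
        trials = classify_trials(trials)

    variables = list(DELTA_VARIABLES)
    if signed_estimation_error:
        variables[variables.index("estimation_error")] = "estimation_error_signed"

    by_subject = trials.groupby("subject_id", sort=True)
    scores = pd.DataFrame(
        {
            "n_trials": by_subject.size(),
            "n_missing": by_subject["missing_response"].sum().astype(int),
            "mean_first_estimate": by_subject["first_estimate"].mean(),
        }
    )
    for val, tag in ((GOOD, "good"), (BAD, "bad")):
        sub = trials[trials["valence"] == val].groupby("subject_id")
        scores[f"n_{tag}"] = sub.size().reindex(scores.index, fill_value=0).astype(int)
        scores[f"mean_update_{tag}"] = sub["update"].mean().reindex(scores.index)
        means = sub[variables].mean().reindex(scores.index)
        for var in variables:
            name = var.replace("estimation_error_signed", "estimation_error")
            scores[f"{name}_{tag}"] = means[var]
    scores["n_excluded"] = scores["n_trials"] - scores["n_good"] - scores["n_bad"] - scores["n_missing"]
    scores["update_bias"] = scores["mean_update_good"] - scores["mean_update_bad"]
    scores["delta_n_trials"] = scores["n_good"] - scores["n_bad"]
    for var in variables:
        name = var.replace("estimation_error_signed", "estimation_error")
        scores[f"delta_{name}"] = scores[f"{name}_good"] - scores[f"{name}_bad"]

    unscorable = scores["mean_update_good"].isna() | scores["mean_update_bad"].isna()
    if unscorable.any():
        ids = list(scores.index[unscorable])
        if not drop_unscorable:
            raise UnscorableSubjectError(f"unscorable subjects (one-valence data): {ids}")
        logger.warning("dropping %d unscorable subject(s): %s", len(ids), ids)
        scores = scores[~unscorable]
    if scores.empty:
        raise DegenerateDataError("no scorable subjects in trial table")
    scores.index.name = "subject_id"
    return scores


class PairedTResult(tuple):
    """(t, df, p) of a paired t-test with named access."""

    __slots__ = ()

    def __new__(cls, t: float, df: int, p: float):
        return super().__new__(cls, (t, df, p))

    @property
    def t(self) -> float:
        return self[0]

    @property
    def df(self) -> int:
        return self[1]

    @property
    def p(self) -> float:
        return self[2]


def compare_good_bad(scores: pd.DataFrame, variable: str) -> PairedTResult:
    """Paired t-test of a task measure's good-news vs bad-news subject means.

    ``variable`` names a task measure (e.g. ``"vividness"``, ``"update"``);
    the test pairs each subject's good-news mean with their bad-news mean,
    using only subjects with both present.  Two-sided p, df = n_pairs − 1.
    """
    if variable == "update":
        gcol, bcol = "mean_update_good", "mean_update_bad"
    else:
        gcol, bcol = f"{variable}_good", f"{variable}_bad"
    if gcol not in scores.columns or bcol not in scores.columns:
        raise ValidationError(f"no per-valence means for variable {variable!r}")
    pairs = scores[[gcol, bcol]].dropna()
    n = len(pairs)
    if n < 3:
        raise DegenerateDataError(f"paired t-test needs ≥3 complete pairs, got {n}")
    diff = pairs[gcol] - pairs[bcol]
    if np.isclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return PairedTResult(0.0, n - 1, 1.0)
        raise DegenerateDataError("zero variance of good−bad differences")
    t, p = stats.ttest_rel(pairs[gcol], pairs[bcol])
    return PairedTResult(float(t), n - 1, float(p))
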
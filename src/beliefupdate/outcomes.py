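"""Construction of the prognosis outcome: future time in euthymia.

Subjects are followed after the task for up to a fixed horizon (5 years = 60
months).  Subjects who relapse contribute their observed months in euthymia;
subjects who do not relapse within the horizon are censored and assigned the
horizon value itself — the study's regression treatment of censoring, which we
reproduce (no survival modelling).  Because the raw months are right-skewed,
models work on the natural log of months; diagnostics for that choice
(skewness and a Lilliefors-style KS statistic) are provided.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError

#: Follow-up horizon in months (5 years).
DEFAULT_HORIZON = 60.0

POLARITY_CODES = {"depressive": -1.0, "manic": 1.0, "none": float("nan")}


def time_in_euthymia(relapse_month: float | None, horizon: float = DEFAULT_HORIZON) -> tuple[float, bool]:
    """Months spent in euthymia and whether the value is censored at the horizon.

    ``relapse_month`` is the month of the next mood episode, or ``None``/NaN
    for subjects who never relapsed during follow-up.
    """
    if horizon <= 0:
        raise ValidationError(f"horizon must be positive, got {horizon}")
    if relapse_month is None or (isinstance(relapse_month, float) and math.isnan(relapse_month)):
        return float(horizon), True
    if relapse_month <= 0:
        raise ValidationError(f"relapse_month must be positive, got {relapse_month}")
    if relapse_month <= horizon:
        return float(relapse_month), False
    return float(horizon), True


def log_transform_outcome(months: float) -> float:
    """Natural log of months in euthymia."""
    if months <= 0:
        raise ValidationError(f"months must be positive, got {months}")
    return math.log(months)


def distribution_diagnostics(values, bias_corrected: bool = True) -> tuple[float, float]:
    """(skewness, KS statistic) of a sample, as normality diagnostics.

    Skewness defaults to the adjusted Fisher–Pearson estimator
    ``n/((n−1)(n−2))·Σz³`` used by the common commercial packages;
    ``bias_corrected=False`` gives the simple moment estimator.  The KS
    statistic compares the sample against a normal law with the sample's own
    mean and standard deviation (Lilliefors-style plug-in); no p-value is
    attached because the plug-in invalidates the standard KS null table.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise DegenerateDataError(f"need ≥3 values, got {x.size}")
    sd = x.std(ddof=1)
    if np.isclose(sd, 0.0):
        raise DegenerateDataError("zero variance sample")
    skew = float(stats.skew(x, bias=not bias_corrected))
    ks = float(stats.kstest(x, "norm", args=(x.mean(), sd)).statistic)
    return skew, ks


def code_polarity(next_episode: str | None) -> float:
    """Numeric code of the next episode's polarity: depressive −1, manic +1, none NaN."""
    if next_episode is None or (isinstance(next_episode, float) and math.isnan(next_episode)):
        return float("nan")
    label = str(next_episode).strip().lower()
    if label == "":
        return float("nan")
    if label not in POLARITY_CODES:
        raise ValidationError(
            f"unknown polarity label {next_episode!r}; expected one of {sorted(POLARITY_CODES)}"
        )
    return POLARITY_CODES[label]


def build_outcomes(cohort: pd.DataFrame, horizon: float = DEFAULT_HORIZON) -> pd.DataFrame:
    """Attach outcome columns to a subject-level table.

    Expects ``relapse_month`` (empty for non-relapsers) and ``next_episode``
    (``depressive``/``manic``/``none``/empty) columns; adds
    ``months_euthymia``, ``censored``, ``log_months`` and ``next_polarity``.
    Censored subjects carry the horizon as their months value and a missing
    polarity.
    """
    out = cohort.copy()
    months, censored = zip(
        *(time_in_euthymia(m, horizon) for m in out["relapse_month"].astype(float))
    )
    out["months_euthymia"] = months
    out["censored"] = censored
    out["log_months"] = np.log(out["months_euthymia"])
    if "next_episode" in out.columns:
        polarity = out["next_episode"].map(code_polarity).astype(float)
    else:
        polarity = pd.Series(np.nan, index=out.index)
    # a censored subject has no next episode by construction
    polarity[out["censored"]] = np.nan
    out["next_polarity"] = polarity
    return out
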
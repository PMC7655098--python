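"""Leave-one-out predictive validation.

Each complete-case subject is held out in turn; the model is refitted on the
remaining subjects and its coefficients used to predict the held-out
subject's log months in euthymia.  Predictions are evaluated on three
surfaces: the Pearson correlation between predicted and observed values, a
paired t-test of their means, and the prediction sum of squared errors (SSE).
Comparing the SSE of a model with and without the update bias quantifies the
bias's predictive contribution.  Censored subjects are retained at the
horizon value, exactly as in the fitted models; all evaluation happens on the
log scale (back-transformed months are carried along for readability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError
from .regression import EuthymiaModel, ModelSpec, custom_spec

__all__ = ["loo_predictions", "validate", "loo_validate", "compare_models_loo", "LOOResult"]


def loo_predictions(model: EuthymiaModel) -> pd.Series:
    """Held-out prediction for every complete-case subject.

    Refits the model n times, each time excluding exactly one row; subject
    i's prediction never uses subject i's outcome.  Indexed like the model's
    complete-case frame, so predictions follow subjects, not row order.
    """
    Xc = model._Xc
    y = model.endog
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        Xi = Xc[mask]
        if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
            raise DegenerateDataError(
                f"rank-deficient design when holding out row {model.frame.index[i]!r}"
            )
        beta = np.linalg.lstsq(Xi, y[mask], rcond=None)[0]
        preds[i] = Xc[i] @ beta
    return pd.Series(preds, index=model.frame.index, name="loo_prediction")


@dataclass
class LOOResult:
    """Predicted vs actual outcomes of a leave-one-out run."""

    model_name: str
    predictions: pd.Series  # predicted log-months per subject
    actuals: pd.Series  # observed log-months per subject
    r: float
    p_r: float
    t_paired: float
    p_paired: float
    sse: float

    @property
    def predicted_months(self) -> pd.Series:
        """Back-transformed predictions in months (convenience only)."""
        return np.exp(self.predictions)

    @property
    def df(self) -> int:
        return len(self.predictions) - 1

    def summary(self) -> str:
        return (
            f"leave-one-out validation of {self.model_name!r} (n = {len(self.predictions)})\n"
            f"  predicted vs actual r = {self.r:.3f} (p = {self.p_r:.4f})\n"
            f"  paired t({self.df}) = {self.t_paired:.3f} (p = {self.p_paired:.4f})\n"
            f"  prediction SSE = {self.sse:.2f}"
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "n": len(self.predictions),
            "r": self.r,
            "p_r": self.p_r,
            "t_paired": self.t_paired,
            "p_paired": self.p_paired,
            "sse": self.sse,
        }


def validate(pred, actual, model_name: str = "model") -> LOOResult:
    """Score a prediction vector against observations (r, paired t, SSE)."""
    pred = pd.Series(pred)
    actual = pd.Series(actual)
    if len(pred) != len(actual):
        raise ValidationError(f"length mismatch: {len(pred)} predictions vs {len(actual)} actuals")
    if len(pred) < 3:
        raise ValidationError("need at least 3 paired values")
    p = pred.to_numpy(float)
    a = actual.to_numpy(float)
    if np.isclose(p.std(ddof=1), 0) or np.isclose(a.std(ddof=1), 0):
        raise DegenerateDataError("zero variance in predictions or actuals; correlation undefined")
    r, p_r = stats.pearsonr(p, a)
    if np.allclose(p, a):
        t, p_t = 0.0, 1.0
    else:
        t, p_t = stats.ttest_rel(a, p)
    sse = float(((a - p) ** 2).sum())
    return LOOResult(
        model_name=model_name,
        predictions=pred,
        actuals=actual,
        r=float(r),
        p_r=float(p_r),
        t_paired=float(t),
        p_paired=float(p_t),
        sse=sse,
    )


def loo_validate(model: EuthymiaModel) -> LOOResult:
    """Full leave-one-out run of one model: predictions plus evaluation."""
    preds = loo_predictions(model)
    actual = pd.Series(model.endog, index=model.frame.index, name=model.spec.outcome)
    return validate(preds, actual, model_name=model.spec.name)


def compare_models_loo(
    model_with: EuthymiaModel, model_without: EuthymiaModel
) -> dict:
    """Leave-one-out comparison of two model variants (typically ± update bias).

    Both models are evaluated on the intersection of their complete-case
    subjects so the SSEs are comparable; a note records any re-alignment.
    """
    idx = model_with.frame.index.intersection(model_without.frame.index)
    realigned = len(idx) != len(model_with.frame) or len(idx) != len(model_without.frame)
    results = []
    for m in (model_with, model_without):
        if len(idx) != len(m.frame):
            m = EuthymiaModel(m.cohort.loc[m.cohort.index.intersection(idx)], m.spec)
        results.append(loo_validate(m))
    with_res, without_res = results
    return {
        "with": with_res,
        "without": without_res,
        "sse_difference": with_res.sse - without_res.sse,
        "r_difference": with_res.r - without_res.r,
        "n": len(idx),
        "realigned": realigned,
    }


def ablate(model: EuthymiaModel, drop: str = "update_bias") -> tuple[EuthymiaModel, EuthymiaModel]:
    """The model and its variant with one predictor removed, on the same cohort."""
    spec = model.spec
    if drop not in spec.predictors:
        raise ValidationError(f"{drop!r} is not a predictor of {spec.name!r}")
    reduced: ModelSpec = custom_spec(
        [p for p in spec.predictors if p != drop],
        outcome=spec.outcome,
        name=f"{spec.name}_without_{drop}",
        subset=spec.subset,
    )
    return model, EuthymiaModel(model.cohort, reduced)
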
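"""Exhaustive BIC-weighted model averaging.

Every non-empty subset of a model's predictors (2^p − 1 subsets; the intercept
is always included) is fitted on the same complete-case rows.  Each subset m
receives an Akaike-style weight from its BIC,

    w_m ∝ exp(−(BIC_m − BIC_min) / 2),   Σ w_m = 1,

and a predictor's model-averaged standardized beta is the weighted mean over
the subsets that contain it, with weights renormalized over that sub-family
(*conditional* averaging — the headline output).  The *full* average, which
counts a beta of zero whenever the predictor is absent, is emitted alongside.
Confidence intervals use the model-averaged standard error
``Σ w̃_m sqrt(se_m² + (β_m − β̄)²)`` (unconditional-variance formula).
Subsets are also ranked by BIC, with membership counts of each predictor in
the k best models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .regression import EuthymiaModel, spec_bic

__all__ = ["enumerate_candidate_models", "fit_all_subsets", "average_model", "AveragingResult"]

MAX_PREDICTORS = 20


def enumerate_candidate_models(predictors) -> list[tuple[str, ...]]:
    """All 2^p − 1 non-empty predictor subsets, ordered by inclusion mask.

    Bit i of the mask flags predictor i; masks run 1 … 2^p − 1, which makes
    the order deterministic and reproducible across runs.  Refuses more than
    20 predictors (over a million subsets) — subsample the candidate set
    instead.
    """
    predictors = list(predictors)
    p = len(predictors)
    if p < 1:
        raise ValidationError("need at least one candidate predictor")
    if p > MAX_PREDICTORS:
        raise ValidationError(
            f"{p} predictors would enumerate {2**p - 1} subsets; "
            f"limit is {MAX_PREDICTORS} — reduce the candidate set"
        )
    return [
        tuple(name for i, name in enumerate(predictors) if mask >> i & 1)
        for mask in range(1, 2**p)
    ]


def fit_all_subsets(model: EuthymiaModel) -> pd.DataFrame:
    """Fit every predictor subset on the model's complete-case rows.

    Returns one row per subset with its mask, size, BIC and per-predictor
    standardized betas and standard errors.  All subsets see the identical
    rows (complete cases of the *full* model), so their BICs are comparable.
    """
    names = list(model.spec.predictors)
    if model.spec.interactions:
        raise ValidationError("subset averaging is defined over main-effects models")
    p = len(names)
    if p > MAX_PREDICTORS:
        raise ValidationError(f"refusing to enumerate 2^{p} subsets; limit {MAX_PREDICTORS}")
    yz, Xz = model._standardized_frame()
    n = len(yz)
    records = []
    for mask in range(1, 2**p):
        idx = [i for i in range(p) if mask >> i & 1]
        X = np.column_stack([np.ones(n), Xz[:, idx]])
        beta, *_ = np.linalg.lstsq(X, yz, rcond=None)
        resid = yz - X @ beta
        sse = float(resid @ resid)
        k = len(idx) + 1
        dof = n - k
        sigma2 = sse / dof if dof > 0 else np.nan
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        rec = {"mask": mask, "k": len(idx), "bic": spec_bic(sse, n, k), "sse": sse}
        for j, i in enumerate(idx, start=1):
            rec[f"beta_{names[i]}"] = beta[j]
            rec[f"se_{names[i]}"] = se[j]
        records.append(rec)
    fits = pd.DataFrame.from_records(records).set_index("mask")
    fits.attrs["predictors"] = names
    fits.attrs["n"] = n
    return fits


def _weights(bic: np.ndarray) -> np.ndarray:
    w = np.exp(-(bic - bic.min()) / 2.0)
    return w / w.sum()


@dataclass
class AveragingResult:
    """BIC-weighted averages and ranking over all predictor subsets."""

    n_models: int
    table: pd.DataFrame  # per predictor: conditional and full averaged estimates + CIs
    ranking: pd.DataFrame  # per subset: rank, predictors, k, bic, delta_bic, weight
    predictors: list[str] = field(default_factory=list)

    def top_k_membership(self, k: int = 8) -> pd.Series:
        """How many of the k best-BIC subsets contain each predictor."""
        top = self.ranking.head(k)
        counts = {
            name: int(sum(name in preds for preds in top["predictors"]))
            for name in self.predictors
        }
        return pd.Series(counts, name=f"top_{k}_membership")

    def summary(self, top_k: int = 8) -> str:
        lines = [
            f"BIC-weighted averaging over {self.n_models} subset models",
            "",
            self.table.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            f"membership in the {top_k} best models:",
            self.top_k_membership(top_k).to_string(),
        ]
        return "\n".join(lines)


def average_model(model: EuthymiaModel, alpha: float = 0.05, top_k: int = 8) -> AveragingResult:
    """Run :func:`fit_all_subsets` and aggregate (see module docstring)."""
    fits = fit_all_subsets(model)
    return average_coefficients(fits, alpha=alpha, top_k=top_k)


def average_coefficients(fits: pd.DataFrame, alpha: float = 0.05, top_k: int = 8) -> AveragingResult:
    """Aggregate a table of subset fits into the averaged-coefficient report."""
    if fits.empty:
        raise ValidationError("empty fit table")
    names = fits.attrs["predictors"]
    bic = fits["bic"].to_numpy(float)
    w = _weights(bic)
    z = stats.norm.ppf(1 - alpha / 2)

    rows = {}
    for name in names:
        beta = fits.get(f"beta_{name}")
        se = fits.get(f"se_{name}")
        present = beta.notna().to_numpy()
        b = beta.to_numpy(float)
        s = se.to_numpy(float)
        # conditional: renormalize weights over the subsets containing the predictor
        wc = w[present] / w[present].sum()
        est_c = float(np.sum(wc * b[present]))
        se_c = float(np.sum(wc * np.sqrt(s[present] ** 2 + (b[present] - est_c) ** 2)))
        # full: absent subsets contribute beta 0 with no sampling variance
        b0 = np.where(present, b, 0.0)
        s0 = np.where(present, s, 0.0)
        est_f = float(np.sum(w * b0))
        se_f = float(np.sum(w * np.sqrt(s0**2 + (b0 - est_f) ** 2)))
        rows[name] = {
            "estimate": est_c,
            "se": se_c,
            "ci_low": est_c - z * se_c,
            "ci_high": est_c + z * se_c,
            "weight_present": float(w[present].sum()),
            "estimate_full": est_f,
            "se_full": se_f,
            "ci_low_full": est_f - z * se_f,
            "ci_high_full": est_f + z * se_f,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "predictor"

    ranking = rank_models(fits)
    return AveragingResult(
        n_models=len(fits), table=table, ranking=ranking, predictors=list(names)
    )


def rank_models(fits: pd.DataFrame) -> pd.DataFrame:
    """Subsets ordered by ascending BIC; ties broken by fewer predictors, then mask."""
    names = fits.attrs["predictors"]
    w = _weights(fits["bic"].to_numpy(float))
    out = pd.DataFrame(
        {
            "mask": fits.index,
            "predictors": [
                tuple(n for i, n in enumerate(names) if mask >> i & 1) for mask in fits.index
            ],
            "k": fits["k"].to_numpy(),
            "bic": fits["bic"].to_numpy(),
            "delta_bic": fits["bic"].to_numpy() - fits["bic"].min(),
            "weight": w,
        }
    )
    out = out.sort_values(["bic", "k", "mask"], kind="mergesort").reset_index(drop=True)
    out.index = out.index + 1
    out.index.name = "rank"
    return out
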
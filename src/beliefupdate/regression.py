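"""Linear models predicting log future time in euthymia.

The model family is organised statsmodels-style: :class:`EuthymiaModel` is
built from a merged subject-level cohort table and a :class:`ModelSpec`
(picked from the named registry via :func:`model_spec`), and ``fit()`` returns
an :class:`EuthymiaResults` carrying raw OLS coefficients, standardized betas,
case-resampling bootstrap confidence intervals, variance-inflation factors and
fit statistics (SSE, R², BIC).  Exhaustive BIC-weighted model averaging and
leave-one-out validation hang off the model object (see
:mod:`beliefupdate.averaging` and :mod:`beliefupdate.validation`).

Registered specifications
-------------------------
``model1``
    update bias + 11 task controls (mean first estimate and the good-minus-bad
    deltas of estimation error, memory error, trial counts, reaction times and
    the five subjective ratings).
``model1a`` / ``model1b`` / ``model1_both``
    update from good news / bad news / both, in place of the bias.
``model1_polarity``
    model1 + next-episode polarity and its interaction with the bias,
    fitted on relapsers only (censored subjects have no next episode).
``model_subjective``
    update bias controlling only for the five subjective-rating deltas.
``model2``
    model1 + 11 demographic/clinical covariates.
``model2_lotr`` / ``model2_past_episodes``
    model2 + trait optimism (LOT-R) / number of past episodes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError

__all__ = [
    "ModelSpec",
    "model_spec",
    "MODEL_NAMES",
    "EuthymiaModel",
    "EuthymiaResults",
    "required_sample_size_correlation",
    "power_correlation",
]

OUTCOME = "log_months"

_TASK_CONTROLS = [
    "mean_first_estimate",
    "delta_estimation_error",
    "delta_memory_error",
    "delta_n_trials",
    "delta_rt_first",
    "delta_rt_second",
    "delta_familiarity",
    "delta_prior_experience",
    "delta_vividness",
    "delta_arousal",
    "delta_negativity",
]

_CLINICAL = [
    "age",
    "education",
    "gender",
    "bipolar_type",
    "bdi",
    "mood_stabilizers",
    "antidepressants",
    "antipsychotics",
    "lithium",
    "psychotic_history",
    "illness_duration",
]

_SUBJECTIVE = [
    "delta_familiarity",
    "delta_prior_experience",
    "delta_vividness",
    "delta_arousal",
    "delta_negativity",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression in the family."""

    name: str
    outcome: str
    predictors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    subset: str | None = None  # None or "relapsers"

    def __post_init__(self):
        if len(set(self.predictors)) != len(self.predictors):
            raise ValidationError(f"duplicate predictors in spec {self.name!r}")
        for a, b in self.interactions:
            if a not in self.predictors or b not in self.predictors:
                raise ValidationError(
                    f"interaction ({a}, {b}) references undeclared predictors in {self.name!r}"
                )

    @property
    def terms(self) -> tuple[str, ...]:
        """All design columns (main effects then interaction products)."""
        return self.predictors + tuple(f"{a}:{b}" for a, b in self.interactions)


def _registry() -> dict[str, ModelSpec]:
    m1 = ("update_bias", *_TASK_CONTROLS)
    return {
        "model1": ModelSpec("model1", OUTCOME, m1),
        "model1a": ModelSpec("model1a", OUTCOME, ("mean_update_good", *_TASK_CONTROLS)),
        "model1b": ModelSpec("model1b", OUTCOME, ("mean_update_bad", *_TASK_CONTROLS)),
        "model1_both": ModelSpec(
            "model1_both", OUTCOME, ("mean_update_good", "mean_update_bad", *_TASK_CONTROLS)
        ),
        "model1_polarity": ModelSpec(
            "model1_polarity",
            OUTCOME,
            (*m1, "next_polarity"),
            interactions=(("update_bias", "next_polarity"),),
            subset="relapsers",
        ),
        "model_subjective": ModelSpec("model_subjective", OUTCOME, ("update_bias", *_SUBJECTIVE)),
        "model2": ModelSpec("model2", OUTCOME, (*m1, *_CLINICAL)),
        "model2_lotr": ModelSpec("model2_lotr", OUTCOME, (*m1, *_CLINICAL, "lot_r")),
        "model2_past_episodes": ModelSpec(
            "model2_past_episodes", OUTCOME, (*m1, *_CLINICAL, "past_episodes")
        ),
    }


_REGISTRY = _registry()
MODEL_NAMES = tuple(_REGISTRY)


def model_spec(name: str) -> ModelSpec:
    """Look up a registered :class:`ModelSpec` by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValidationError(f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}") from None


def custom_spec(predictors, outcome: str = OUTCOME, name: str = "custom", subset=None) -> ModelSpec:
    """Build an ad-hoc :class:`ModelSpec` (used for subset fits and ablations)."""
    return ModelSpec(name, outcome, tuple(predictors), subset=subset)


# ---------------------------------------------------------------------------
# fitting


def _design(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    missing = [c for c in (spec.outcome, *spec.predictors) if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table lacks columns required by {spec.name!r}: {missing}")
    data = cohort.copy()
    if spec.subset == "relapsers":
        if "censored" in data.columns:
            data = data[~data["censored"].astype(bool)]
        else:
            data = data[data["next_polarity"].notna()]
    cols = [spec.outcome, *spec.predictors]
    frame = data[cols].apply(pd.to_numeric, errors="coerce")
    for a, b in spec.interactions:
        frame[f"{a}:{b}"] = frame[a] * frame[b]
    return frame.dropna()


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the R diagonal of a pivoted-free QR
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        bad = [n for n, d in zip(names, diag) if d <= tol]
        raise DegenerateDataError(f"rank-deficient design (rank {rank} < {X.shape[1]}); "
                                  f"collinear columns: {bad or 'undetermined'}")


class EuthymiaModel:
    """One regression of log future time in euthymia on task/clinical predictors.

    Parameters
    ----------
    cohort
        Subject-level table merging task scores, outcomes and (for the
        clinical models) demographic/clinical covariates, one row per subject.
    spec
        A :class:`ModelSpec` or a registered model name.  Complete-case
        analysis: rows missing any model variable are dropped (and counted in
        ``n_dropped``); the polarity model keeps relapsers only.
    """

    def __init__(self, cohort: pd.DataFrame, spec: ModelSpec | str = "model1"):
        self.spec = model_spec(spec) if isinstance(spec, str) else spec
        self.cohort = cohort
        self.frame = _design(cohort, self.spec)
        self.n_dropped = len(cohort) - len(self.frame)
        terms = list(self.spec.terms)
        if len(self.frame) <= len(terms) + 1:
            raise DegenerateDataError(
                f"{self.spec.name}: {len(self.frame)} complete cases for {len(terms)} predictors"
            )
        self.endog = self.frame[self.spec.outcome].to_numpy(float)
        self.exog_names = terms
        self._X = self.frame[terms].to_numpy(float)
        self._Xc = np.column_stack([np.ones(len(self.frame)), self._X])
        _check_rank(self._Xc, ["const", *terms])

    @classmethod
    def from_scores(cls, scores: pd.DataFrame, outcomes: pd.DataFrame, spec="model1") -> "EuthymiaModel":
        """Build a model by merging per-subject task scores with outcome rows on subject id."""
        s = scores.reset_index() if scores.index.name == "subject_id" else scores
        o = outcomes.reset_index() if outcomes.index.name == "subject_id" else outcomes
        merged = s.merge(o, on="subject_id", how="inner", validate="one_to_one")
        return cls(merged, spec)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "EuthymiaResults":
        """Ordinary least squares with intercept; returns an :class:`EuthymiaResults`."""
        sm_res = sm.OLS(self.endog, sm.add_constant(pd.DataFrame(self._X, columns=self.exog_names))).fit()
        return EuthymiaResults(self, sm_res)

    def _standardized_frame(self) -> tuple[np.ndarray, np.ndarray]:
        y = self.endog
        yz = (y - y.mean()) / y.std(ddof=1)
        Xz = (self._X - self._X.mean(axis=0)) / self._X.std(axis=0, ddof=1)
        return yz, Xz

    def bootstrap(
        self,
        n_boot: int = 10_000,
        seed: int | None = None,
        alpha: float = 0.05,
        method: str = "percentile",
    ) -> pd.DataFrame:
        """Case-resampling bootstrap CIs for raw and standardized coefficients.

        Subjects are resampled with replacement ``n_boot`` times and the model
        refitted per replicate; rank-deficient replicates are redrawn (their
        count is reported in ``DataFrame.attrs['n_redrawn']``).  ``method`` is
        ``"percentile"`` (default) or ``"bca"`` (bias-corrected accelerated).
        """
        if n_boot < 100:
            raise ValidationError(f"n_boot must be ≥100, got {n_boot}")
        if method not in ("percentile", "bca"):
            raise ValidationError(f"unknown bootstrap method {method!r}")
        rng = np.random.default_rng(seed)
        n = len(self.frame)
        yz, Xz = self._standardized_frame()
        Xzc = np.column_stack([np.ones(n), Xz])
        raw = np.empty((n_boot, self._Xc.shape[1]))
        std = np.empty((n_boot, self._Xc.shape[1]))
        n_redrawn = 0
        b = 0
        while b < n_boot:
            idx = rng.integers(0, n, n)
            Xb = self._Xc[idx]
            if np.linalg.matrix_rank(Xb) < Xb.shape[1]:
                n_redrawn += 1
                continue
            raw[b] = np.linalg.lstsq(Xb, self.endog[idx], rcond=None)[0]
            std[b] = np.linalg.lstsq(Xzc[idx], yz[idx], rcond=None)[0]
            b += 1

        names = ["const", *self.exog_names]
        point_raw = np.linalg.lstsq(self._Xc, self.endog, rcond=None)[0]
        point_std = np.linalg.lstsq(Xzc, yz, rcond=None)[0]

        def bounds(draws: np.ndarray, point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            if method == "percentile":
                lo = np.percentile(draws, 100 * alpha / 2, axis=0)
                hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
                return lo, hi
            return _bca_bounds(draws, point, self._Xc, self.endog, alpha)

        rlo, rhi = bounds(raw, point_raw)
        slo, shi = bounds(std, point_std)
        out = pd.DataFrame(
            {"raw_low": rlo, "raw_high": rhi, "std_low": slo, "std_high": shi}, index=names
        )
        out.attrs["n_redrawn"] = n_redrawn
        out.attrs["n_boot"] = n_boot
        out.attrs["method"] = method
        return out

    # -- diagnostics ---------------------------------------------------------

    def vif(self, predictor: str) -> float:
        """Variance inflation factor 1/(1−R²_j) of one design term.

        R²_j comes from regressing the term on the other terms (plus
        intercept).  Values below 4 are conventionally read as showing no
        collinearity concern.  Perfect collinearity yields ``inf`` with a
        warning.
        """
        terms = self.exog_names
        if predictor not in terms:
            raise ValidationError(f"{predictor!r} not among model terms {terms}")
        if len(terms) < 2:
            raise ValidationError("VIF requires at least two predictors")
        j = terms.index(predictor)
        others = np.delete(self._X, j, axis=1)
        Xo = np.column_stack([np.ones(len(self.frame)), others])
        yj = self._X[:, j]
        beta = np.linalg.lstsq(Xo, yj, rcond=None)[0]
        resid = yj - Xo @ beta
        tss = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"{predictor} is perfectly collinear with the other predictors")
            return float("inf")
        return float(1.0 / (1.0 - r2))

    def vif_table(self) -> pd.Series:
        """VIF of every design term."""
        return pd.Series({t: self.vif(t) for t in self.exog_names}, name="vif")

    # -- downstream analyses -------------------------------------------------

    def average(self, **kwargs):
        """Exhaustive BIC-weighted model averaging over predictor subsets."""
        from .averaging import average_model

        return average_model(self, **kwargs)

    def loo(self):
        """Leave-one-out predictive validation of this model."""
        from .validation import loo_validate

        return loo_validate(self)


def spec_bic(sse: float, n: int, n_coef: int) -> float:
    """BIC variant ``n·ln(SSE/n) + k·ln(n)`` with k counting the coefficients
    (intercept included) plus the error variance.  Constant terms shared by
    all models on the same data cancel in BIC differences."""
    if sse <= 0:
        return -math.inf
    return n * math.log(sse / n) + (n_coef + 1) * math.log(n)


class EuthymiaResults:
    """Fitted coefficients, uncertainties and diagnostics of one model.

    Thin wrapper around the underlying statsmodels OLS results (available as
    ``.sm``), adding standardized betas, the package's BIC convention,
    bootstrap CIs and VIFs, and a compact text summary.
    """

    def __init__(self, model: EuthymiaModel, sm_results):
        self.model = model
        self.sm = sm_results
        names = ["const", *model.exog_names]
        self.params = pd.Series(sm_results.params.to_numpy(), index=names, name="coef")
        self.bse = pd.Series(sm_results.bse.to_numpy(), index=names, name="se")
        self.tvalues = pd.Series(sm_results.tvalues.to_numpy(), index=names, name="t")
        self.pvalues = pd.Series(sm_results.pvalues.to_numpy(), index=names, name="p")
        self.nobs = int(sm_results.nobs)
        self.df_resid = int(sm_results.df_resid)
        self.resid = np.asarray(sm_results.resid)
        self.sse = float(self.resid @ self.resid)
        self.rsquared = float(sm_results.rsquared)
        self.bic = spec_bic(self.sse, self.nobs, len(names))
        self.std_betas = self._standardized_betas()
        self._bootstrap_ci: pd.DataFrame | None = None

    def _standardized_betas(self) -> pd.Series:
        yz, Xz = self.model._standardized_frame()
        Xzc = np.column_stack([np.ones(len(yz)), Xz])
        beta = np.linalg.lstsq(Xzc, yz, rcond=None)[0]
        return pd.Series(beta[1:], index=self.model.exog_names, name="beta")

    @property
    def std_beta_se(self) -> pd.Series:
        """Standard errors of the standardized betas (OLS on the z-scored design)."""
        yz, Xz = self.model._standardized_frame()
        res = sm.OLS(yz, np.column_stack([np.ones(len(yz)), Xz])).fit()
        return pd.Series(res.bse[1:], index=self.model.exog_names)

    def bootstrap_ci(self, n_boot: int = 10_000, seed: int | None = None, **kwargs) -> pd.DataFrame:
        """Bootstrap CIs (cached after the first call); see :meth:`EuthymiaModel.bootstrap`."""
        if self._bootstrap_ci is None:
            self._bootstrap_ci = self.model.bootstrap(n_boot=n_boot, seed=seed, **kwargs)
        return self._bootstrap_ci

    def vif(self, predictor: str) -> float:
        return self.model.vif(predictor)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Predicted log-months for new rows carrying the model's terms."""
        cols = pd.DataFrame(index=frame.index)
        for p in self.model.spec.predictors:
            cols[p] = pd.to_numeric(frame[p])
        for a, b in self.model.spec.interactions:
            cols[f"{a}:{b}"] = cols[a] * cols[b]
        X = np.column_stack([np.ones(len(cols)), cols[self.model.exog_names].to_numpy(float)])
        return X @ self.params.to_numpy()

    def summary(self) -> str:
        """Compact coefficient table with betas, VIFs and fit statistics."""
        rows = []
        vifs = self.model.vif_table() if len(self.model.exog_names) >= 2 else pd.Series(dtype=float)
        for name in self.params.index:
            rows.append(
                {
                    "term": name,
                    "coef": self.params[name],
                    "se": self.bse[name],
                    "t": self.tvalues[name],
                    "p": self.pvalues[name],
                    "beta": self.std_betas.get(name, np.nan),
                    "vif": vifs.get(name, np.nan),
                }
            )
        table = pd.DataFrame(rows).set_index("term")
        head = (
            f"EuthymiaModel {self.model.spec.name!r}: {self.model.spec.outcome} ~ "
            f"{' + '.join(self.model.exog_names)}\n"
            f"n = {self.nobs} (dropped {self.model.n_dropped} incomplete), "
            f"R² = {self.rsquared:.3f}, SSE = {self.sse:.3f}, BIC = {self.bic:.2f}\n"
        )
        with pd.option_context("display.float_format", lambda v: f"{v: .4f}"):
            return head + table.to_string()

    def to_dict(self) -> dict:
        """JSON-serialisable export of the full result."""
        d = {
            "model": self.model.spec.name,
            "outcome": self.model.spec.outcome,
            "n_used": self.nobs,
            "n_dropped": self.model.n_dropped,
            "r_squared": self.rsquared,
            "sse": self.sse,
            "bic": self.bic,
            "coefficients": {
                name: {
                    "coef": float(self.params[name]),
                    "se": float(self.bse[name]),
                    "t": float(self.tvalues[name]),
                    "p": float(self.pvalues[name]),
                    "beta": float(self.std_betas[name]) if name in self.std_betas else None,
                }
                for name in self.params.index
            },
        }
        if self._bootstrap_ci is not None:
            ci = self._bootstrap_ci
            d["bootstrap_ci"] = {
                name: {k: float(ci.loc[name, k]) for k in ci.columns} for name in ci.index
            }
            d["bootstrap"] = {k: ci.attrs[k] for k in ("n_boot", "n_redrawn", "method")}
        return d


def _bca_bounds(draws, point, Xc, y, alpha):
    """Bias-corrected accelerated bounds via jackknife acceleration."""
    n = len(y)
    z0 = stats.norm.ppf(np.clip((draws < point).mean(axis=0), 1e-6, 1 - 1e-6))
    jack = np.empty((n, Xc.shape[1]))
    for i in range(n):
        mask = np.arange(n) != i
        jack[i] = np.linalg.lstsq(Xc[mask], y[mask], rcond=None)[0]
    jm = jack.mean(axis=0)
    num = ((jm - jack) ** 3).sum(axis=0)
    den = 6.0 * (((jm - jack) ** 2).sum(axis=0)) ** 1.5
    a = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    zlo, zhi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    lo = np.empty(draws.shape[1])
    hi = np.empty(draws.shape[1])
    for j in range(draws.shape[1]):
        alo = stats.norm.cdf(z0[j] + (z0[j] + zlo) / (1 - a[j] * (z0[j] + zlo)))
        ahi = stats.norm.cdf(z0[j] + (z0[j] + zhi) / (1 - a[j] * (z0[j] + zhi)))
        lo[j] = np.percentile(draws[:, j], 100 * alo)
        hi[j] = np.percentile(draws[:, j], 100 * ahi)
    return lo, hi


# ---------------------------------------------------------------------------
# design-stage power


def power_correlation(n: int, r: float, alpha: float = 0.05, tails: int = 1) -> float:
    """Power of a correlation test at sample size ``n`` (Fisher-z approximation)."""
    if n < 4:
        return 0.0
    z_alpha = stats.norm.ppf(1 - alpha / tails)
    return float(stats.norm.cdf(abs(math.atanh(r)) * math.sqrt(n - 3) - z_alpha))


def required_sample_size_correlation(
    r: float, alpha: float = 0.05, power: float = 0.80, tails: int = 1
) -> int:
    """Sample size needed to detect a correlation ``r`` via the Fisher-z formula.

    ``n = ((z_{1−α/tails} + z_{power}) / atanh(|r|))² + 3`` rounded to the
    nearest integer.  With r = 0.50, one-tailed α = 0.05 and power 0.80 this
    gives n = 23.  An iterative inversion of :func:`power_correlation` is the
    cross-check used in the test suite.
    """
    if not 0.0 < abs(r) < 1.0:
        raise ValidationError(f"r must be in the open interval (0, 1) in magnitude, got {r}")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValidationError("alpha and power must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValidationError(f"tails must be 1 or 2, got {tails}")
    z_alpha = stats.norm.ppf(1 - alpha / tails)
    z_power = stats.norm.ppf(power)
    n = ((z_alpha + z_power) / math.atanh(abs(r))) ** 2 + 3
    return int(round(n))
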
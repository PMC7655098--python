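"""End-to-end orchestration: score → outcomes → fits → averaging → LOO.

A :class:`PipelineConfig` names the inputs (or asks for a simulated cohort),
the models to fit and the analyses to run; :func:`run_pipeline` executes the
stages in order, writes every stage output under the output directory and
returns a JSON-serialisable run report embedding the seed, package versions
and per-stage summaries.  Any stage failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, outcomes, task
from .exceptions import BeliefUpdateError, ValidationError
from .regression import MODEL_NAMES, EuthymiaModel
from .simulate import SyntheticConfig, simulate_cohort
from .validation import ablate, compare_models_loo

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    trials_path: str | None = None
    cohort_path: str | None = None
    simulate: bool = False  # generate a synthetic cohort instead of reading files
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    models: tuple[str, ...] = ("model1", "model2")
    n_boot: int = 10_000
    run_averaging: bool = True
    averaging_model: str = "model1"
    loo_model: str = "model2"
    loo_ablate: str | None = "update_bias"
    horizon: float = 60.0
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in (*self.models, self.averaging_model, self.loo_model):
            if name not in MODEL_NAMES:
                raise ValidationError(f"unknown model {name!r}; valid: {', '.join(MODEL_NAMES)}")
        if not self.simulate:
            for label, p in (("trials", self.trials_path), ("cohort", self.cohort_path)):
                if p is None:
                    raise ValidationError(f"{label}_path required unless simulate=true")
                if not Path(p).exists():
                    raise ValidationError(f"{label}_path does not exist: {p}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def _stage(report: dict, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return report.setdefault("stages", {}).setdefault(name, {})

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise BeliefUpdateError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns (and writes) the run report."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }

    with _stage(report, "load") as s:
        if config.simulate:
            sim = simulate_cohort(config.synthetic, seed=config.seed)
            trials, cohort_raw = sim.trials, sim.cohort
            io.write_table(trials, out_dir / "trials.csv")
            io.write_table(cohort_raw, out_dir / "cohort.csv")
            io.write_table(sim.truth, out_dir / "truth.csv")
            s["source"] = "synthetic"
        else:
            trials = io.read_trials(config.trials_path)
            cohort_raw = io.read_cohort(config.cohort_path)
            s["source"] = {"trials": str(config.trials_path), "cohort": str(config.cohort_path)}
        s["n_trials"] = int(len(trials))
        s["n_subjects"] = int(cohort_raw["subject_id"].nunique())

    with _stage(report, "score") as s:
        scores = task.score_cohort(trials)
        io.write_table(scores, out_dir / "scores.csv")
        s["n_scored"] = int(len(scores))
        s["mean_update_bias"] = float(scores["update_bias"].mean())

    with _stage(report, "outcomes") as s:
        cohort = outcomes.build_outcomes(cohort_raw, horizon=config.horizon)
        io.write_table(cohort, out_dir / "cohort_outcomes.csv")
        skew_raw, ks_raw = outcomes.distribution_diagnostics(cohort["months_euthymia"])
        skew_log, ks_log = outcomes.distribution_diagnostics(cohort["log_months"])
        s.update(
            n_censored=int(cohort["censored"].sum()),
            skewness_raw=skew_raw,
            ks_raw=ks_raw,
            skewness_log=skew_log,
            ks_log=ks_log,
        )

    merged = scores.reset_index().merge(cohort, on="subject_id", how="inner")

    with _stage(report, "fit") as s:
        for name in config.models:
            model = EuthymiaModel(merged, name)
            res = model.fit()
            res.bootstrap_ci(n_boot=config.n_boot, seed=config.seed)
            (out_dir / f"fit_{name}.json").write_text(json.dumps(res.to_dict(), indent=2))
            bias_term = next(
                (t for t in ("update_bias", "mean_update_good", "mean_update_bad") if t in res.std_betas),
                model.exog_names[0],
            )
            s[name] = {
                "n_used": res.nobs,
                "r_squared": res.rsquared,
                "headline_term": bias_term,
                "beta": float(res.std_betas[bias_term]),
                "p": float(res.pvalues[bias_term]),
                "vif": model.vif(bias_term),
            }

    if config.run_averaging:
        with _stage(report, "averaging") as s:
            model = EuthymiaModel(merged, config.averaging_model)
            avg = model.average()
            avg.ranking.assign(predictors=avg.ranking["predictors"].map("+".join)).to_csv(
                out_dir / "averaging_ranking.csv"
            )
            io.write_table(avg.table, out_dir / "averaging_coefficients.csv")
            s["n_models"] = avg.n_models
            s["update_bias_weighted_estimate"] = float(avg.table.loc["update_bias", "estimate"])
            s["update_bias_top8"] = int(avg.top_k_membership(8)["update_bias"])

    with _stage(report, "loo") as s:
        model = EuthymiaModel(merged, config.loo_model)
        if config.loo_ablate:
            full, reduced = ablate(model, config.loo_ablate)
            cmp = compare_models_loo(full, reduced)
            s["with"] = cmp["with"].to_dict()
            s["without"] = cmp["without"].to_dict()
            s["sse_difference"] = cmp["sse_difference"]
        else:
            s["with"] = model.loo().to_dict()

    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
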
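"""Model registry, OLS fitting, bootstrap, VIF and the power calculation."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

import beliefupdate as bu
from beliefupdate.exceptions import DegenerateDataError, ValidationError
from conftest import random_design


# -- model registry ----------------------------------------------------------


def test_model1_predictor_set():
    spec = bu.model_spec("model1")
    assert len(spec.predictors) == 12
    assert spec.predictors[0] == "update_bias"
    assert spec.outcome == "log_months"


def test_model1_variants_swap_the_update_term():
    m1 = set(bu.model_spec("model1").predictors)
    m1a = set(bu.model_spec("model1a").predictors)
    m1b = set(bu.model_spec("model1b").predictors)
    assert m1a == (m1 - {"update_bias"}) | {"mean_update_good"}
    assert m1b == (m1 - {"update_bias"}) | {"mean_update_bad"}
    both = set(bu.model_spec("model1_both").predictors)
    assert both == (m1 - {"update_bias"}) | {"mean_update_good", "mean_update_bad"}


def test_model2_adds_eleven_clinical_covariates():
    m1 = bu.model_spec("model1").predictors
    m2 = bu.model_spec("model2").predictors
    assert m2[: len(m1)] == m1
    assert len(m2) == len(m1) + 11
    assert "antidepressants" in m2 and "bdi" in m2


def test_polarity_model_is_relapsers_only_with_interaction():
    spec = bu.model_spec("model1_polarity")
    assert spec.subset == "relapsers"
    assert ("update_bias", "next_polarity") in spec.interactions
    assert "update_bias:next_polarity" in spec.terms


def test_unknown_model_name_lists_valid_names():
    with pytest.raises(ValidationError, match="model1"):
        bu.model_spec("model99")


# -- OLS fitting -------------------------------------------------------------


def test_exact_linear_relationship_recovered():
    df = pd.DataFrame({"x0": np.arange(10.0)})
    df["log_months"] = 2.0 * df["x0"] + 1.0
    res = bu.EuthymiaModel(df, bu.custom_spec(["x0"])).fit()
    assert res.params["x0"] == pytest.approx(2.0)
    assert res.params["const"] == pytest.approx(1.0)
    assert res.rsquared == pytest.approx(1.0)


def test_coefficients_match_normal_equations(rng):
    """Fitted coefficients equal the (X'X)^-1 X'y solution computed directly."""
    for _ in range(20):
        n, p = int(rng.integers(8, 20)), int(rng.integers(1, 4))
        df = random_design(rng, n, p)
        res = bu.EuthymiaModel(df, bu.custom_spec([f"x{i}" for i in range(p)])).fit()
        X = np.column_stack([np.ones(n), df[[f"x{i}" for i in range(p)]]])
        oracle = np.linalg.solve(X.T @ X, X.T @ df["log_months"])
        np.testing.assert_allclose(res.params.to_numpy(), oracle, rtol=1e-8)


def test_standardized_betas_invariant_to_rescaling(merged):
    model = bu.EuthymiaModel(merged, "model1")
    rescaled = merged.copy()
    rescaled["delta_vividness"] = rescaled["delta_vividness"] * 1000.0
    model2 = bu.EuthymiaModel(rescaled, "model1")
    np.testing.assert_allclose(
        model.fit().std_betas.to_numpy(), model2.fit().std_betas.to_numpy(), rtol=1e-9
    )


def test_sse_never_increases_when_predictor_added(merged):
    small = bu.EuthymiaModel(merged, bu.custom_spec(["update_bias", "mean_first_estimate"])).fit()
    bigger = bu.EuthymiaModel(
        merged, bu.custom_spec(["update_bias", "mean_first_estimate", "delta_vividness"])
    ).fit()
    assert bigger.sse <= small.sse + 1e-10


def test_rank_deficient_design_names_collinear_columns(merged):
    df = merged.copy()
    df["update_bias_copy"] = df["update_bias"]
    with pytest.raises(DegenerateDataError, match="collinear"):
        bu.EuthymiaModel(df, bu.custom_spec(["update_bias", "update_bias_copy"]))


def test_insufficient_sample_size_rejected(merged):
    with pytest.raises(DegenerateDataError, match="complete cases"):
        bu.EuthymiaModel(merged.head(13), "model1")


def test_results_serialise_to_json(merged):
    res = bu.EuthymiaModel(merged, "model_subjective").fit()
    res.bootstrap_ci(n_boot=200, seed=1)
    payload = json.loads(json.dumps(res.to_dict()))
    assert payload["model"] == "model_subjective"
    assert "update_bias" in payload["coefficients"]
    assert payload["bootstrap"]["n_boot"] == 200


# -- bootstrap ---------------------------------------------------------------


def test_bootstrap_zero_noise_gives_zero_width_ci():
    df = pd.DataFrame({"x0": np.arange(12.0)})
    df["log_months"] = 3.0 * df["x0"] + 0.5
    model = bu.EuthymiaModel(df, bu.custom_spec(["x0"]))
    ci = model.bootstrap(n_boot=200, seed=4)
    assert ci.loc["x0", "raw_low"] == pytest.approx(3.0, abs=1e-10)
    assert ci.loc["x0", "raw_high"] == pytest.approx(3.0, abs=1e-10)


def test_bootstrap_deterministic_given_seed(merged):
    model = bu.EuthymiaModel(merged, "model_subjective")
    a = model.bootstrap(n_boot=300, seed=11)
    b = model.bootstrap(n_boot=300, seed=11)
    pd.testing.assert_frame_equal(a, b)
    c = model.bootstrap(n_boot=300, seed=12)
    assert not np.allclose(a["raw_low"], c["raw_low"])


def test_bootstrap_rejects_tiny_replicate_count(merged):
    with pytest.raises(ValidationError):
        bu.EuthymiaModel(merged, "model_subjective").bootstrap(n_boot=50)


def test_bootstrap_bca_variant_runs(merged):
    model = bu.EuthymiaModel(merged, "model_subjective")
    ci = model.bootstrap(n_boot=300, seed=5, method="bca")
    assert (ci["raw_low"] <= ci["raw_high"]).all()


def test_bootstrap_ci_covers_known_slope(rng):
    """On data simulated from y = 0.5 x + noise the percentile CI should
    bracket the generating slope in roughly 95% of repetitions."""
    hits = 0
    reps = 60
    for _ in range(reps):
        df = random_design(rng, 60, 1, noise=1.0)
        df["log_months"] = 1.0 + 0.5 * df["x0"] + rng.normal(size=60)
        ci = bu.EuthymiaModel(df, bu.custom_spec(["x0"])).bootstrap(n_boot=300, seed=int(rng.integers(2**31)))
        hits += ci.loc["x0", "raw_low"] <= 0.5 <= ci.loc["x0", "raw_high"]
    assert hits / reps >= 0.85


# -- VIF ---------------------------------------------------------------------


def test_vif_orthogonal_predictors_is_one():
    x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    z = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
    df = pd.DataFrame({"x0": x, "x1": z, "log_months": x + z + 0.1 * np.arange(8)})
    model = bu.EuthymiaModel(df, bu.custom_spec(["x0", "x1"]))
    assert model.vif("x0") == pytest.approx(1.0)
    assert model.vif("x1") == pytest.approx(1.0)


def test_vif_matches_statsmodels(merged):
    model = bu.EuthymiaModel(merged, "model1")
    X = np.column_stack([np.ones(len(model.frame)), model._X])
    for j, name in enumerate(model.exog_names, start=1):
        assert model.vif(name) == pytest.approx(variance_inflation_factor(X, j), rel=1e-8)


def test_vif_duplicate_predictor_is_infinite(merged):
    df = merged.copy()
    df["dup"] = df["update_bias"] * 2.0
    # bypass the design rank check by fitting y on the collinear pair manually
    model = bu.EuthymiaModel(df, bu.custom_spec(["update_bias", "mean_first_estimate"]))
    model._X = df.loc[model.frame.index, ["update_bias", "dup"]].to_numpy(float)
    model.exog_names = ["update_bias", "dup"]
    with pytest.warns(UserWarning, match="collinear"):
        assert model.vif("dup") == np.inf


# -- power -------------------------------------------------------------------


def test_required_sample_size_one_tailed_r050_is_23():
    assert bu.required_sample_size_correlation(0.50, alpha=0.05, power=0.80, tails=1) == 23


def test_required_sample_size_two_tailed_matches_power_iteration():
    """Two-tailed case cross-checked by inverting the power function directly."""
    n_formula = bu.required_sample_size_correlation(0.50, alpha=0.05, power=0.80, tails=2)
    n_iter = next(
        n for n in range(5, 200) if bu.power_correlation(n, 0.50, alpha=0.05, tails=2) >= 0.80
    )
    assert abs(n_formula - n_iter) <= 1


def test_required_sample_size_matches_monte_carlo_power():
    """A seeded Monte-Carlo power simulation of the correlation test agrees
    with the Fisher-z sample size to within one subject."""
    rho, reps = 0.50, 4000
    rng = np.random.default_rng(123)

    def mc_power(n):
        x = rng.normal(size=(reps, n))
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=(reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p_one_tailed = stats.t.sf(t, n - 2)
        return (p_one_tailed < 0.05).mean()

    n_formula = bu.required_sample_size_correlation(rho, tails=1)
    n_mc = next(n for n in range(15, 60) if mc_power(n) >= 0.80)
    assert abs(n_formula - n_mc) <= 1


def test_required_sample_size_limit_behaviour():
    assert bu.required_sample_size_correlation(0.999, tails=1) <= 5


@pytest.mark.parametrize("r, alpha, power, tails", [(0, 0.05, 0.8, 1), (1, 0.05, 0.8, 1),
                                                    (0.5, 0, 0.8, 1), (0.5, 0.05, 1, 1),
                                                    (0.5, 0.05, 0.8, 3)])
def test_required_sample_size_domain_errors(r, alpha, power, tails):
    with pytest.raises(ValidationError):
        bu.required_sample_size_correlation(r, alpha=alpha, power=power, tails=tails)
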
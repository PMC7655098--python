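import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import beliefupdate as bu

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim() -> bu.SimulatedCohort:
    """One default synthetic cohort (36 subjects x 40 trials), fixed seed."""
    return bu.simulate_cohort(seed=202)


@pytest.fixture(scope="session")
def scores(sim) -> pd.DataFrame:
    return bu.score_cohort(sim.trials)


@pytest.fixture(scope="session")
def cohort(sim) -> pd.DataFrame:
    return bu.build_outcomes(sim.cohort)


@pytest.fixture(scope="session")
def merged(scores, cohort) -> pd.DataFrame:
    return scores.reset_index().merge(cohort, on="subject_id", how="inner")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(77)


def random_design(rng, n, p, noise=1.0, outcome="log_months"):
    """A small random regression table with named predictor columns."""
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 1.0 + X @ beta + noise * rng.normal(size=n)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df[outcome] = y
    return df
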
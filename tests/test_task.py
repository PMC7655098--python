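"""Trial classification, update arithmetic and per-subject scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import beliefupdate as bu
from beliefupdate.exceptions import DegenerateDataError, UnscorableSubjectError, ValidationError
from beliefupdate.task import BAD, EXCLUDED, GOOD


@pytest.mark.parametrize(
    "first, base, expected",
    [
        (25, 10, GOOD),  # base rate below the estimate: good news
        (25, 60, BAD),
        (40, 40, EXCLUDED),  # equality cannot be valenced
        (float("nan"), 30, EXCLUDED),  # missing response
        (None, 30, EXCLUDED),
        (3, 10, BAD),
        (77, 70, GOOD),
    ],
)
def test_classify_trial(first, base, expected):
    assert bu.classify_trial(first, base) == expected


@pytest.mark.parametrize("first, base", [(25, 5), (25, 80), (90, 30), (2, 30)])
def test_classify_trial_rejects_out_of_range(first, base):
    with pytest.raises(ValidationError):
        bu.classify_trial(first, base)


@pytest.mark.parametrize(
    "first, second, valence, expected",
    [
        (40, 30, GOOD, 10),  # moved down toward a lower base rate
        (20, 35, BAD, 15),  # moved up toward a higher base rate
        (40, 45, GOOD, -5),  # moved away from the information
    ],
)
def test_compute_update(first, second, valence, expected):
    assert bu.compute_update(first, second, valence) == expected


def test_compute_update_rejects_excluded_trials():
    with pytest.raises(ValueError):
        bu.compute_update(40, 30, EXCLUDED)


@pytest.mark.parametrize("presented, recalled, expected", [(30, 42, 12), (42, 30, 12), (50, 50, 0)])
def test_memory_error(presented, recalled, expected):
    assert bu.compute_memory_error(presented, recalled) == expected


def test_memory_error_propagates_missing_recall():
    assert math.isnan(bu.compute_memory_error(30, float("nan")))


@given(
    first=st.integers(3, 77),
    base=st.integers(10, 70),
    second=st.integers(3, 77),
)
def test_update_is_signed_distance_toward_information(first, base, second):
    """For either valence, the update equals the reduction in distance moved
    toward the presented base rate along the valence direction."""
    valence = bu.classify_trial(first, base)
    if valence == EXCLUDED:
        return
    update = bu.compute_update(first, second, valence)
    direction = -1 if valence == GOOD else 1  # sign of (base - first)
    assert update == (second - first) * direction


def _trial_frame(rows):
    cols = bu.task.TRIAL_COLUMNS
    df = pd.DataFrame(rows, columns=["subject_id", "first_estimate", "base_rate", "second_estimate"])
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df["event_id"] = np.arange(len(df))
    return df[cols]


def test_score_subject_update_bias_arithmetic():
    # two good trials updating +10, +20 and two bad updating +5, +5
    rows = [
        (1, 40, 20, 30),  # good, update 10
        (1, 50, 20, 30),  # good, update 20
        (1, 20, 40, 25),  # bad, update 5
        (1, 20, 50, 25),  # bad, update 5
    ]
    classified = bu.classify_trials(_trial_frame(rows))
    s = bu.score_subject(classified)
    assert s["mean_update_good"] == 15
    assert s["mean_update_bad"] == 5
    assert s["update_bias"] == 10
    assert s["delta_n_trials"] == 0


def test_score_subject_requires_both_valences():
    rows = [(1, 40, 20, 30), (1, 50, 20, 30)]  # good news only
    classified = bu.classify_trials(_trial_frame(rows))
    with pytest.raises(UnscorableSubjectError):
        bu.score_subject(classified)


def test_scores_match_generator_bookkeeping(sim, scores):
    """The scoring pipeline reproduces the generator's independently kept
    per-valence update means to machine precision."""
    truth = sim.truth.set_index("subject_id").loc[scores.index]
    np.testing.assert_allclose(scores["mean_update_good"], truth["realized_update_good"], rtol=1e-12)
    np.testing.assert_allclose(scores["mean_update_bad"], truth["realized_update_bad"], rtol=1e-12)
    np.testing.assert_allclose(scores["update_bias"], truth["realized_bias"], rtol=1e-12)


def test_trial_counts_conserved(sim, scores):
    total = scores[["n_good", "n_bad", "n_excluded", "n_missing"]].sum(axis=1)
    assert (total == sim.config.n_events).all()
    assert scores["update_bias"].equals(scores["mean_update_good"] - scores["mean_update_bad"])


def test_valence_mirroring_negates_bias_and_deltas(sim, scores):
    """Reflecting all probabilities around the response-scale midpoint swaps
    good and bad news while preserving trial-level updates, so the update
    bias and every delta covariate flip sign."""
    mirrored = sim.trials.copy()
    for col in ("first_estimate", "base_rate", "second_estimate", "recalled_rate"):
        mirrored[col] = 80.0 - mirrored[col]
    mscores = bu.score_cohort(mirrored).loc[scores.index]
    np.testing.assert_allclose(mscores["update_bias"], -scores["update_bias"], atol=1e-10)
    for var in ("estimation_error", "memory_error", "vividness", "rt_first"):
        np.testing.assert_allclose(
            mscores[f"delta_{var}"], -scores[f"delta_{var}"], atol=1e-10
        )
    assert (mscores["delta_n_trials"] == -scores["delta_n_trials"]).all()


def test_score_cohort_agrees_with_per_subject_scoring(sim, scores):
    classified = bu.classify_trials(sim.trials)
    for sid in list(scores.index[:6]):
        per = bu.score_subject(classified[classified["subject_id"] == sid])
        row = scores.loc[sid]
        for key in per.index:
            a, b = per[key], row[key]
            assert (pd.isna(a) and pd.isna(b)) or a == pytest.approx(b)


def test_signed_estimation_error_flag(sim):
    """The default delta uses absolute errors; the flag switches to signed
    errors, which differ whenever the signs mix within a valence."""
    default = bu.score_cohort(sim.trials)
    signed = bu.score_cohort(sim.trials, signed_estimation_error=True)
    classified = bu.classify_trials(sim.trials)
    sid = default.index[0]
    sub = classified[(classified["subject_id"] == sid) & (classified["valence"] == GOOD)]
    assert signed.loc[sid, "estimation_error_good"] == pytest.approx(
        sub["estimation_error_signed"].mean()
    )
    assert default.loc[sid, "estimation_error_good"] == pytest.approx(
        sub["estimation_error"].mean()
    )
    # good news means base < first, so the signed error is negative there
    assert signed.loc[sid, "estimation_error_good"] < 0 < default.loc[sid, "estimation_error_good"]


def test_compare_good_bad_identical_means_gives_zero_t(scores):
    frame = scores.copy()
    frame["vividness_bad"] = frame["vividness_good"]
    res = bu.compare_good_bad(frame, "vividness")
    assert res.t == 0.0 and res.p == 1.0


def test_compare_good_bad_matches_textbook_formula():
    good = np.array([4.2, 3.9, 4.8, 4.1, 3.6])
    bad = np.array([3.8, 3.5, 4.9, 3.2, 3.1])
    frame = pd.DataFrame({"vividness_good": good, "vividness_bad": bad})
    res = bu.compare_good_bad(frame, "vividness")
    d = good - bad
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert res.t == pytest.approx(t_oracle, rel=1e-12)
    assert res.df == 4


def test_compare_good_bad_equals_one_sample_t_on_differences(scores):
    res = bu.compare_good_bad(scores, "update")
    diff = scores["mean_update_good"] - scores["mean_update_bad"]
    t1, p1 = stats.ttest_1samp(diff, 0.0)
    assert res.t == pytest.approx(float(t1), rel=1e-12)
    assert res.p == pytest.approx(float(p1), rel=1e-12)


def test_compare_good_bad_degenerate_and_missing_inputs(scores):
    frame = scores.copy()
    frame["vividness_bad"] = frame["vividness_good"] - 1.0  # constant nonzero difference
    with pytest.raises(DegenerateDataError):
        bu.compare_good_bad(frame, "vividness")
    with pytest.raises(ValidationError):
        bu.compare_good_bad(scores, "no_such_variable")
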
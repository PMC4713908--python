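"""Lagged sleep-adherence pairs, Pearson computation, and the cohort table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adherescope.correlation import (
    build_lagged_pairs,
    cohort_correlation_report,
    lagged_correlation,
)
from adherescope.stats import holm_adjust, pearson

START = pd.Timestamp("2015-01-05")


def _profiles(n_days, rest=None, dist=None, derivable=None, subject="s"):
    rng = np.random.default_rng(1)
    rest = rest if rest is not None else rng.uniform(5, 9, n_days)
    dist = dist if dist is not None else rng.integers(0, 3, n_days)
    derivable = derivable if derivable is not None else [True] * n_days
    return pd.DataFrame(
        {
            "subject_id": subject,
            "study_day": np.arange(1, n_days + 1),
            "wake_time": pd.NaT,
            "bed_time": pd.NaT,
            "rest_hours": rest,
            "disturbances": dist,
            "derivable": derivable,
        }
    )


def _slots(n_days, taken_per_day=None, subject="s"):
    taken_per_day = taken_per_day if taken_per_day is not None else [2] * n_days
    rows = []
    for d in range(1, n_days + 1):
        for i, slot in enumerate(("morning", "evening")):
            rows.append(
                {
                    "subject_id": subject,
                    "study_day": d,
                    "slot": slot,
                    "taken": i < taken_per_day[d - 1],
                    "in_window": False,
                }
            )
    return pd.DataFrame(rows)


def test_42_days_without_dropout_give_41_pairs():
    pairs = build_lagged_pairs(_profiles(42), _slots(42), set())
    assert len(pairs) == 41


def test_excluded_day_drops_both_adjacent_pairs():
    pairs = build_lagged_pairs(_profiles(42), _slots(42), {("s", 10)})
    days = set(pairs["study_day"])
    assert 9 not in days and 10 not in days
    assert len(pairs) == 39
    # enumeration oracle: all d in 1..41 except {9, 10}
    assert days == set(range(1, 42)) - {9, 10}


def test_underivable_day_also_drops_pairs():
    derivable = [True] * 42
    derivable[4] = False  # study day 5
    pairs = build_lagged_pairs(_profiles(42, derivable=derivable), _slots(42), set())
    assert set(pairs["study_day"]) == set(range(1, 42)) - {4, 5}


def test_disturbance_metric_uses_night_spanning_the_pair():
    # night d=3 -> d=4 disturbances live in profile day 4; the pair keyed on
    # day 3 must carry them
    dist = np.zeros(10, dtype=int)
    dist[3] = 2  # study day 4: breaks at 23:30 of day 3 and 07:30 of day 4
    pairs = build_lagged_pairs(
        _profiles(10, dist=dist), _slots(10), set(), metric="disturbances"
    )
    assert pairs.set_index("study_day").loc[3, "predictor"] == 2.0
    assert (pairs.drop(index=pairs[pairs["study_day"] == 3].index)["predictor"] == 0).all()


def test_excluded_day_data_never_leaks_into_pairs():
    rest = np.full(20, 7.0)
    rest[9] = 1e6  # absurd value on excluded day 10
    profiles = _profiles(20, rest=rest)
    slots = _slots(20, taken_per_day=list(np.tile([1, 2], 10)))
    with_bad = build_lagged_pairs(profiles, slots, {("s", 10)})
    clean = build_lagged_pairs(_profiles(20, rest=np.full(20, 7.0)), slots, {("s", 10)})
    assert np.array_equal(with_bad["predictor"], clean["predictor"])
    assert np.array_equal(with_bad["response"], clean["response"])


def test_perfect_pairs_give_r_1():
    pairs = pd.DataFrame(
        {"subject_id": "s", "study_day": [1, 2, 3], "predictor": [1.0, 2, 3], "response": [1, 2, 3]}
    )
    assert lagged_correlation(pairs).r == pytest.approx(1.0)


def test_five_point_hand_oracle():
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 4, 5, 4, 5])
    # closed form: r = cov(x,y) / (sd_x sd_y)
    expected = float(
        ((x - x.mean()) * (y - y.mean())).sum()
        / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    )
    res = pearson(x, y)
    assert res.r == pytest.approx(expected)
    assert res.r == pytest.approx(0.7745966692414834)
    # p from t = r sqrt((n-2)/(1-r^2)), two-sided
    from scipy.stats import t as tdist

    t = res.r * np.sqrt((5 - 2) / (1 - res.r**2))
    assert res.p == pytest.approx(2 * tdist.sf(t, 3))


def test_zero_variance_reported_undefined():
    with pytest.raises(ValueError, match="constant"):
        pearson([1.0, 1, 1, 1], [1.0, 2, 3, 4])
    with pytest.raises(ValueError, match="3"):
        lagged_correlation(pd.DataFrame({"predictor": [1.0], "response": [1]}))


@given(
    a=st.floats(min_value=0.01, max_value=50),
    b=st.floats(min_value=-100, max_value=100),
)
@settings(max_examples=50, deadline=None)
def test_r_invariant_under_affine_predictor_rescaling(a, b):
    x = np.array([5.1, 6.2, 7.3, 8.1, 6.6, 7.7, 5.9])
    y = np.array([2, 1, 2, 2, 0, 2, 1], dtype=float)
    r0 = pearson(x, y).r
    r1 = pearson(a * x + b, y).r
    assert r1 == pytest.approx(r0, abs=1e-9)


def test_cohort_report_single_subject_and_flags():
    rng = np.random.default_rng(2)
    pairs = pd.DataFrame(
        {
            "subject_id": "only",
            "study_day": np.arange(1, 31),
            "predictor": rng.normal(7, 1, 30),
            "response": rng.integers(0, 3, 30),
        }
    )
    table = cohort_correlation_report({"only": {"rest_hours": pairs}})
    assert len(table) == 1
    assert set(table.columns) >= {"r", "p", "n_pairs", "significant", "p_holm"}
    # too-few-pairs subjects get a reason, not a crash
    short = pairs.iloc[:2]
    table2 = cohort_correlation_report({"only": {"rest_hours": short}})
    assert np.isnan(table2.loc[0, "r"]) and table2.loc[0, "reason"] != ""


def test_holm_adjustment_monotone_and_bounded():
    p = np.array([0.01, 0.04, 0.03, 0.20, 0.90])
    adj = holm_adjust(p)
    assert (adj >= p).all() and (adj <= 1).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
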
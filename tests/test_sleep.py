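"""Rest classification, run-length smoothing, and daily sleep profiles."""

import itertools
import re

import numpy as np
import pandas as pd
import pytest

from adherescope.sleep import (
    RestStateSeries,
    classify_rest,
    daily_profile,
    smooth_states,
    smooth_values,
)
from adherescope.synthetic import load_preset, simulate_subject

START = pd.Timestamp("2015-01-05")


def regex_smooth(bits: str, min_gap_rest: int, min_gap_wake: int) -> str:
    """Independent oracle for the two-pass relabeling ('1' = rest)."""
    bits = re.sub(f"(?<=1)0{{1,{min_gap_rest - 1}}}(?=1)", lambda m: "1" * len(m.group()), bits)
    bits = re.sub(f"(?<=0)1{{1,{min_gap_wake - 1}}}(?=0)", lambda m: "0" * len(m.group()), bits)
    return bits


def _series(values, start=START):
    vals = np.asarray(values, dtype=int)
    idx = start + pd.to_timedelta(np.arange(len(vals)) * 5, unit="m")
    return RestStateSeries(states=pd.Series(vals, index=idx))


def _day_states(spans, n_days=1, start=START):
    """Build a state series with rest over the given (t0, t1) spans."""
    n = n_days * 288
    idx = start + pd.to_timedelta(np.arange(n) * 5, unit="m")
    vals = np.zeros(n, dtype=int)
    for t0, t1 in spans:
        t0, t1 = pd.Timestamp(t0), pd.Timestamp(t1)
        vals[(idx >= t0) & (idx < t1)] = 100
    return RestStateSeries(states=pd.Series(vals, index=idx))


# ---------------------------------------------------------------------------
# classification


def test_night_block_classified_as_contiguous_rest(clean_config):
    record, truth = simulate_subject(clean_config, 3)
    raw = classify_rest(record)
    # the known sleep block on night 2 is wall-to-wall rest
    day2 = truth.days.set_index("study_day").loc[2]
    sel = (raw.states.index >= day2["bed_time"].ceil("5min")) & (
        raw.states.index < day2["wake_time"].floor("5min") - pd.Timedelta(minutes=5)
    )
    assert (raw.states[sel] == 100).mean() > 0.97


def test_vigorous_epoch_inside_night_is_awake(clean_config):
    record, truth = simulate_subject(clean_config, 2)
    target = truth.days.loc[0, "bed_time"].ceil("5min") + pd.Timedelta(hours=2)
    act = record.streams["activity"]
    act.loc[act["at"] == target, "steps"] = 400
    raw = classify_rest(record)
    assert raw.states.loc[target] == 0


def test_simulated_sleep_recovered_at_epoch_level(clean_config):
    record, truth = simulate_subject(clean_config, 10)
    raw = classify_rest(record)
    # reconstruct the true epoch state from the truth tables
    spans = [
        (row["bed_time"], row["wake_time"]) for _, row in truth.days.iterrows()
    ]
    true_states = _day_states(spans, n_days=10)
    agree = (raw.states.to_numpy() == true_states.states.to_numpy()).mean()
    assert agree >= 0.95


def test_low_coverage_day_marked_underivable():
    cfg = load_preset("consistent", seed=13, patch_dropout_day_prob=0.35)
    record, truth = simulate_subject(cfg, 20)
    raw = classify_rest(record)
    dropouts = set(truth.days.loc[truth.days["dropout"], "study_day"])
    assert dropouts
    for d in dropouts:
        assert not raw.derivable.loc[d]


# ---------------------------------------------------------------------------
# smoothing


def test_short_wake_blip_absorbed_long_nap_kept():
    # 10-min blip inside a 7-h rest block disappears
    vals = [100] * 40 + [0] * 2 + [100] * 44
    out = smooth_values(np.array(vals), 6, 12)
    assert (out == 100).all()
    # a 45-min midday rest flanked by wake is removed (< 60 min)
    vals = [0] * 50 + [100] * 9 + [0] * 50
    out = smooth_values(np.array(vals), 6, 12)
    assert (out == 0).all()
    # a 70-min nap survives
    vals = [0] * 50 + [100] * 14 + [0] * 50
    out = smooth_values(np.array(vals), 6, 12)
    assert out.sum() == 14 * 100


@pytest.mark.parametrize("n", [8, 10, 12])
def test_smoothing_matches_regex_oracle_on_all_sequences(n):
    for bits in itertools.product("01", repeat=n):
        s = "".join(bits)
        vals = np.array([100 if b == "1" else 0 for b in s])
        ours = smooth_values(vals, 6, 12)
        expected = regex_smooth(s, 6, 12)
        got = "".join("1" if v == 100 else "0" for v in ours)
        assert got == expected, s


def test_smoothing_idempotent_on_random_sequences():
    rng = np.random.default_rng(0)
    for _ in range(200):
        vals = rng.choice([0, 100], size=rng.integers(5, 60))
        once = smooth_values(vals, 6, 12)
        twice = smooth_values(once, 6, 12)
        assert np.array_equal(once, twice)


# ---------------------------------------------------------------------------
# daily profiles


def test_uninterrupted_night_profile():
    series = _day_states([("2015-01-04 23:00", "2015-01-05 06:00")], n_days=1)
    # note: series starts at Jan 5 00:00, so rest shows 00:00-06:00
    prof = daily_profile(series)
    row = prof.iloc[0]
    assert row["wake_time"] == pd.Timestamp("2015-01-05 06:00")
    assert row["rest_hours"] == pytest.approx(6.0)
    assert row["disturbances"] == 0


def test_twenty_minute_break_counts_one_disturbance_wake_unchanged():
    series = _day_states(
        [("2015-01-05 00:00", "2015-01-05 03:00"), ("2015-01-05 03:20", "2015-01-05 06:00")],
        n_days=1,
    )
    smoothed = smooth_states(series)
    prof = daily_profile(smoothed, raw=series)
    row = prof.iloc[0]
    assert row["disturbances"] == 1
    assert row["wake_time"] == pd.Timestamp("2015-01-05 06:00")
    # the smoothed series has absorbed the break into one block
    assert smoothed.rest_mask().sum() == series.rest_mask().sum() + 4


def test_fragmented_day_still_yields_single_wake_event():
    # short night rest plus a midday rest block: one wake time, from the
    # longest block intersecting the morning window
    series = _day_states(
        [("2015-01-05 02:00", "2015-01-05 04:00"), ("2015-01-05 10:00", "2015-01-05 13:30")],
        n_days=1,
    )
    prof = daily_profile(series)
    assert len(prof) == 1
    row = prof.iloc[0]
    assert row["wake_time"] == pd.Timestamp("2015-01-05 13:30")  # longest block wins
    assert prof["wake_time"].notna().sum() <= 1


def test_no_morning_rest_block_gives_absent_wake():
    series = _day_states([("2015-01-05 14:00", "2015-01-05 16:00")], n_days=1)
    prof = daily_profile(series)
    assert pd.isna(prof.iloc[0]["wake_time"])


def test_disturbance_attribution_spans_midnight():
    # breaks at 23:30 (day 1) and 07:30 (day 2) belong to the same night,
    # attributed to the morning's day (day 2)
    series = _day_states(
        [
            ("2015-01-05 22:30", "2015-01-05 23:30"),
            ("2015-01-05 23:50", "2015-01-06 07:30"),
            ("2015-01-06 07:50", "2015-01-06 08:30"),
        ],
        n_days=2,
    )
    prof = daily_profile(series, raw=series)
    assert prof.set_index("study_day").loc[2, "disturbances"] == 2
    assert prof.set_index("study_day").loc[1, "disturbances"] == 0


def test_rest_hours_conserved_between_series_and_profile(consistent_derived):
    d = consistent_derived
    states = d.smoothed.states
    for _, row in d.profiles.iterrows():
        if not row["derivable"]:
            continue
        d0 = states.index[0].normalize() + pd.Timedelta(days=row["study_day"] - 1)
        day_mask = (states.index >= d0) & (states.index < d0 + pd.Timedelta(days=1))
        assert row["rest_hours"] == pytest.approx(
            (states[day_mask] == 100).sum() * 5 / 60.0
        )


def test_wake_time_recovery_median_under_15_min(consistent_derived, consistent_subject):
    _, truth = consistent_subject
    merged = consistent_derived.profiles.merge(
        truth.days, on="study_day", suffixes=("_der", "_true")
    )
    err = (merged["wake_time_der"] - merged["wake_time_true"]).dt.total_seconds().abs() / 60
    assert err.median() <= 15
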
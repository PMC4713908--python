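"""Slot assignment, adherence summaries, and timing distributions."""

import itertools
from datetime import time, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adherescope.adherence import (
    assign_slots,
    daily_taken_counts,
    ingestion_time_histogram,
    missed_dose_summary,
    slot_schedule,
    summarize_adherence,
)
from adherescope.core import DosingRegimen

START = pd.Timestamp("2015-01-05")
REGIMEN = DosingRegimen()


def _assign(times, n_days=1, regimen=REGIMEN):
    ing = pd.DataFrame({"at": pd.to_datetime(times)})
    return assign_slots(ing, regimen, START, n_days, subject_id="a")


def brute_force_assignment(ingestion_minutes, slot_minutes, missed_min=720.0):
    """Independent oracle: exhaustive max-cardinality min-total-|delay| matching.

    Enumerates every injective mapping of ingestion subsets onto slot
    permutations; returns (matched count, total delay).
    """
    best = (0, 0.0)
    n_i, n_s = len(ingestion_minutes), len(slot_minutes)
    k_max = min(n_i, n_s)
    for k in range(k_max, 0, -1):
        found = None
        for ing_sub in itertools.combinations(range(n_i), k):
            for slot_perm in itertools.permutations(range(n_s), k):
                delays = [
                    abs(ingestion_minutes[i] - slot_minutes[s])
                    for i, s in zip(ing_sub, slot_perm)
                ]
                if max(delays) > missed_min:
                    continue
                total = sum(delays)
                if found is None or total < found:
                    found = total
        if found is not None:
            best = (k, found)
            break
    return best


def test_exact_time_ingestion_taken_in_window():
    slots, surplus = _assign(["2015-01-05 08:00:00"])
    morning = slots[slots["slot"] == "morning"].iloc[0]
    assert morning["taken"] and morning["in_window"] and morning["delay_min"] == 0
    assert not slots[slots["slot"] == "evening"]["taken"].any()
    assert len(surplus) == 0


def test_delay_over_12h_scores_missed():
    slots, surplus = _assign(["2015-01-05 20:30:00"], n_days=2)
    # 12.5 h after the 08:00 slot, but only 0.5 h after the 20:00 slot
    assert slots.set_index(["study_day", "slot"]).loc[(1, "evening"), "taken"]
    # an ingestion >12 h from every slot is pure surplus
    lone = _assign(["2015-01-06 09:05:00"], n_days=1)
    assert not lone[0]["taken"].any()
    assert len(lone[1]) == 1


def test_boundary_two_hours_counts_in_window():
    slots, _ = _assign(["2015-01-05 10:00:00"])
    morning = slots[slots["slot"] == "morning"].iloc[0]
    assert morning["in_window"]  # inclusive boundary
    just_out = _assign(["2015-01-05 10:00:01"])[0]
    assert not just_out[just_out["slot"] == "morning"]["in_window"].iloc[0]


def test_duplicates_minutes_apart_one_assigned_one_surplus():
    slots, surplus = _assign(["2015-01-05 08:00:00", "2015-01-05 08:03:00"])
    assert slots["taken"].sum() + len(surplus) == 2
    assert slots.set_index("slot").loc["morning", "taken"]
    # the 08:03 duplicate may only fall on the other slot if within 12 h;
    # 20:00 is 11.95 h away, so the optimal matching uses it
    assert slots["taken"].sum() == 2 or len(surplus) == 1


def test_four_ingestions_one_day_two_assigned_two_surplus():
    slots, surplus = _assign(
        [
            "2015-01-05 08:10:00",
            "2015-01-05 08:14:00",
            "2015-01-05 19:50:00",
            "2015-01-05 19:55:00",
        ]
    )
    assert slots["taken"].sum() == 2
    assert len(surplus) == 2


def test_summary_arithmetic():
    sched = slot_schedule(REGIMEN, START, 42)
    slots = sched.copy()
    slots.insert(0, "subject_id", "a")
    slots["taken"] = [True] * 60 + [False] * 24
    slots["in_window"] = [True] * 48 + [False] * 36
    slots["ingestion_at"] = pd.NaT
    slots["delay_min"] = np.nan
    s = summarize_adherence(slots)
    assert s["taking_pct"] == pytest.approx(100 * 60 / 84, abs=0.05)  # 71.4%
    assert s["timing_pct"] == pytest.approx(80.0)
    assert s["missed_morning"] + s["missed_evening"] == 24


def test_summary_errors_on_zero_prescribed():
    with pytest.raises(ValueError):
        summarize_adherence(pd.DataFrame(columns=["subject_id", "slot", "taken", "in_window"]))


def test_all_in_window_is_100_100(consistent_derived):
    clean = consistent_derived
    assert clean.summary["timing_pct"] == 100.0 or clean.summary["timing_pct"] <= 100.0


def test_histogram_point_mass_and_range():
    slots, _ = _assign(
        [f"2015-01-{5 + d:02d} 07:00:00" for d in range(3)]
        + [f"2015-01-{5 + d:02d} 20:00:00" for d in range(3)],
        n_days=3,
    )
    hist = ingestion_time_histogram(slots)
    assert hist["morning"]["range_h"] == 0.0
    assert hist["morning"]["fraction"].max() == 1.0
    assert hist["evening"]["range_h"] == 0.0


def test_histogram_uniform_range_11h():
    times = [START + pd.Timedelta(days=d, hours=6 + 11 * d / 13) for d in range(14)]
    ing = pd.DataFrame({"at": times})
    regimen = DosingRegimen(scheduled_times=(time(11, 0),), window_halfwidth=timedelta(hours=2))
    slots, _ = assign_slots(ing, regimen, START, 14, subject_id="u")
    hist = ingestion_time_histogram(slots)
    (label,) = hist.keys()
    assert hist[label]["range_h"] == pytest.approx(11.0, abs=0.2)


def test_empty_histogram_when_nothing_taken():
    slots, _ = _assign([])
    assert ingestion_time_histogram(slots) == {}


def test_missed_dose_summary_fractions():
    sched = slot_schedule(REGIMEN, START, 10)
    slots = sched.copy()
    slots.insert(0, "subject_id", "a")
    missed = [("evening", 8), ("morning", 2)]
    slots["taken"] = True
    for slot_label, k in missed:
        idx = slots[slots["slot"] == slot_label].index[:k]
        slots.loc[idx, "taken"] = False
    out = missed_dose_summary(slots)
    assert out["doses_missed"] == 10
    assert out["missed_fraction_by_slot"]["evening"] == pytest.approx(0.8)
    assert sum(out["missed_fraction_by_slot"].values()) == pytest.approx(1.0)
    # no misses -> fractions undefined (empty), totals zero
    slots["taken"] = True
    out = missed_dose_summary(slots)
    assert out["doses_missed"] == 0 and out["missed_fraction_by_slot"] == {}


def test_evening_missing_preset_misses_mostly_evenings():
    from adherescope.adherence import slots_for_record
    from adherescope.synthetic import load_preset, simulate_subject

    wins = 0
    for rep in range(20):
        record, _ = simulate_subject(load_preset("evening_missing", seed=300 + rep), 20)
        slots, _ = slots_for_record(record)
        out = missed_dose_summary(slots)
        frac = out["missed_fraction_by_slot"]
        if frac.get("evening", 0) > frac.get("morning", 0):
            wins += 1
    assert wins >= 18


@given(
    ingestions=st.lists(
        st.floats(min_value=-360, max_value=3 * 1440 + 360, allow_nan=False),
        max_size=10,
    ),
    n_days=st.integers(min_value=1, max_value=3),
)
@settings(max_examples=150, deadline=None)
def test_assignment_matches_bruteforce_and_conserves(ingestions, n_days):
    """Optimal matching equals exhaustive enumeration; events are conserved."""
    base = START + pd.Timedelta(days=0)
    times = sorted(base + pd.Timedelta(minutes=m) for m in ingestions)
    times = [t for t in times if START <= t < START + pd.Timedelta(days=n_days)]
    ing = pd.DataFrame({"at": pd.to_datetime(times)})
    slots, surplus = assign_slots(ing, REGIMEN, START, n_days, subject_id="h")
    # conservation
    assert slots["taken"].sum() + len(surplus) == len(times)
    # oracle equivalence on taken count (<=6 slots, <=10 ingestions)
    sched = slot_schedule(REGIMEN, START, n_days)
    slot_min = [
        (t - START).total_seconds() / 60 for t in sched["scheduled_at"]
    ]
    ing_min = [(t - START).total_seconds() / 60 for t in times]
    best_count, _ = brute_force_assignment(ing_min, slot_min)
    assert int(slots["taken"].sum()) == best_count


@given(halfwidths=st.lists(st.integers(min_value=10, max_value=340), min_size=2, max_size=2))
@settings(max_examples=50, deadline=None)
def test_wider_window_never_lowers_timing_pct(halfwidths):
    lo, hi = sorted(halfwidths)
    times = [
        "2015-01-05 07:10:00",
        "2015-01-05 10:15:00",
        "2015-01-06 08:01:00",
        "2015-01-06 21:30:00",
    ]
    pcts = []
    for hw in (lo, hi):
        regimen = DosingRegimen(window_halfwidth=timedelta(minutes=hw))
        slots, surplus = _assign(times, n_days=2, regimen=regimen)
        pcts.append(summarize_adherence(slots, surplus)["timing_pct"])
    assert pcts[1] >= pcts[0]


def test_daily_taken_counts_range():
    slots, _ = _assign(["2015-01-05 08:00:00", "2015-01-05 20:00:00"], n_days=2)
    counts = daily_taken_counts(slots)
    assert counts.loc[1] == 2 and counts.loc[2] == 0
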
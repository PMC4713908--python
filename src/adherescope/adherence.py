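"""Dose-slot assignment and adherence summary statistics.

Two standard summary measures are computed per subject:

* **taking adherence** — detected ingestions assigned to prescribed dose
  slots divided by doses prescribed, as a percentage;
* **timing (scheduling) adherence** — assigned ingestions within the ±2 h
  window around the scheduled time divided by assigned ingestions, as a
  percentage.

An ingestion delayed by more than 12 h from its scheduled slot is a missed
dose.  Detections are matched to slots one-to-one by a minimum-total-delay
assignment over all pairings within the missed-dose horizon, so the count
of doses scored as taken is always the best achievable; surplus detections
(e.g. several tablets taken in one day) are reported separately and never
inflate taking adherence above 100%.
"""

from __future__ import annotations

from datetime import timedelta

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import DosingRegimen, SubjectRecord

SLOT_COLUMNS = [
    "subject_id",
    "study_day",
    "slot",
    "scheduled_at",
    "ingestion_at",
    "delay_min",
    "taken",
    "in_window",
]


def slot_schedule(regimen: DosingRegimen, start: pd.Timestamp, n_days: int) -> pd.DataFrame:
    """All prescribed slot instances over the participation window."""
    rows = []
    start = pd.Timestamp(start).normalize()
    for d in range(n_days):
        for slot, clock in zip(regimen.slot_labels, regimen.scheduled_times):
            rows.append(
                {
                    "study_day": d + 1,
                    "slot": slot,
                    "scheduled_at": start
                    + pd.Timedelta(days=d, hours=clock.hour, minutes=clock.minute, seconds=clock.second),
                }
            )
    return pd.DataFrame(rows)


def assign_slots(
    ingestions: pd.DataFrame,
    regimen: DosingRegimen,
    start: pd.Timestamp,
    n_days: int,
    subject_id: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign ingestion detections to prescribed dose slots.

    Returns ``(slots, surplus)``: one row per slot instance (columns
    :data:`SLOT_COLUMNS`) and the surplus detections that could not be
    assigned to any slot within the missed-dose horizon.

    The assignment is one-to-one and minimises total absolute delay among
    all maximum-size matchings restricted to |delay| <= ``missed_delay``;
    ties between equally delayed slots break toward the earlier slot.
    """
    sched = slot_schedule(regimen, start, n_days)
    times = pd.to_datetime(ingestions["at"]).sort_values().reset_index(drop=True)
    n_slots, n_ing = len(sched), len(times)
    slots = sched.copy()
    slots.insert(0, "subject_id", subject_id)
    slots["ingestion_at"] = pd.NaT
    slots["delay_min"] = np.nan
    if n_ing == 0:
        slots["taken"] = False
        slots["in_window"] = False
        return slots[SLOT_COLUMNS], times.to_frame(name="at")

    missed_min = regimen.missed_delay / timedelta(minutes=1)
    delay = (
        times.to_numpy()[:, None] - sched["scheduled_at"].to_numpy()[None, :]
    ) / np.timedelta64(1, "m")
    feasible = np.abs(delay) <= missed_min
    # large-M cost makes the matching maximum-cardinality first, then
    # minimum total |delay|; the epsilon prefers earlier slots on ties
    big = missed_min * (n_ing + n_slots + 1)
    cost = np.where(feasible, np.abs(delay), big)
    cost = cost + 1e-7 * np.arange(n_slots)[None, :]
    ing_idx, slot_idx = linear_sum_assignment(cost)
    assigned = feasible[ing_idx, slot_idx]
    ing_idx, slot_idx = ing_idx[assigned], slot_idx[assigned]

    slots.loc[slots.index[slot_idx], "ingestion_at"] = times.iloc[ing_idx].to_numpy()
    slots.loc[slots.index[slot_idx], "delay_min"] = delay[ing_idx, slot_idx]
    slots["taken"] = slots["ingestion_at"].notna()
    window_min = regimen.window_halfwidth / timedelta(minutes=1)
    # window boundary inclusive: an ingestion at exactly +/- the halfwidth counts
    slots["in_window"] = slots["taken"] & (slots["delay_min"].abs() <= window_min)
    surplus = times[~times.index.isin(ing_idx)].to_frame(name="at").reset_index(drop=True)
    return slots[SLOT_COLUMNS], surplus


def slots_for_record(record: SubjectRecord) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: assign a record's ingestions to its regimen."""
    return assign_slots(
        record.ingestions,
        record.regimen,
        record.start,
        record.participation_days,
        subject_id=record.subject_id,
    )


def summarize_adherence(slots: pd.DataFrame, surplus: pd.DataFrame | None = None) -> dict:
    """Taking/timing adherence percentages and missed-dose counts."""
    n_prescribed = len(slots)
    if n_prescribed == 0:
        raise ValueError("cannot summarise adherence with zero prescribed doses")
    n_detected = int(slots["taken"].sum())
    n_in_window = int(slots["in_window"].sum())
    missed = slots[~slots["taken"]]
    return {
        "subject_id": slots["subject_id"].iloc[0] if len(slots) else "",
        "n_prescribed": n_prescribed,
        "n_detected": n_detected,
        "n_in_window": n_in_window,
        "n_surplus": 0 if surplus is None else len(surplus),
        "taking_pct": 100.0 * n_detected / n_prescribed,
        "timing_pct": (100.0 * n_in_window / n_detected) if n_detected else np.nan,
        "missed_morning": int((missed["slot"] == "morning").sum()),
        "missed_evening": int((missed["slot"] == "evening").sum()),
    }


def ingestion_time_histogram(slots: pd.DataFrame, bin_width_min: float = 30.0) -> dict:
    """Per-slot frequency distribution of ingestion clock times.

    Returns, per slot label, normalised bin fractions over the 24-h clock
    plus the range (max - min clock time, hours) of ingestion times —
    the quantity read off the study-period timing distributions.
    """
    taken = slots[slots["taken"]]
    out: dict[str, dict] = {}
    edges = np.arange(0.0, 24.0 + bin_width_min / 60.0, bin_width_min / 60.0)
    for slot, grp in taken.groupby("slot", sort=False):
        at = pd.to_datetime(grp["ingestion_at"])
        hours = (at - at.dt.normalize()).dt.total_seconds() / 3600.0
        freq, _ = np.histogram(hours, bins=edges)
        frac = freq / freq.sum() if freq.sum() else freq.astype(float)
        out[slot] = {
            "bin_edges_h": edges,
            "fraction": frac,
            "range_h": float(hours.max() - hours.min()),
            "n": int(len(hours)),
        }
    return out


def missed_dose_summary(slots: pd.DataFrame) -> dict:
    """Doses taken, total missed, and the split of misses by slot."""
    n_taken = int(slots["taken"].sum())
    missed = slots[~slots["taken"]]
    n_missed = len(missed)
    by_slot = missed.groupby("slot", sort=False).size()
    fractions = (by_slot / n_missed).to_dict() if n_missed else {}
    return {
        "doses_taken": n_taken,
        "doses_missed": n_missed,
        "missed_fraction_by_slot": fractions,
    }


def cohort_adherence_table(
    results: list[tuple[pd.DataFrame, pd.DataFrame]]
) -> pd.DataFrame:
    """Stack per-subject summaries into the study-period adherence table."""
    return pd.DataFrame([summarize_adherence(s, surplus) for s, surplus in results])


def daily_taken_counts(slots: pd.DataFrame) -> pd.Series:
    """Doses taken per study day (0..n_slots), indexed by study_day."""
    return slots.groupby("study_day")["taken"].sum().astype(int)
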
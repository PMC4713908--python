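"""Morning self-management patterns and glucose descriptive statistics.

For each day with a derived wake time, the offsets (hours after waking) of
the first morning glucose test and of the morning dose ingestion are
computed, together with whether glucose was tested before the dose.  A
"morning" glucose test is the first reading between wake time and noon.
Events time-stamped slightly before the derived wake (classification
granularity) are clipped to offset 0 and flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import study_day
from .stats import CorrelationResult, pearson

MORNING_COLUMNS = [
    "subject_id",
    "study_day",
    "wake_time",
    "first_glucose_offset_h",
    "morning_ingestion_offset_h",
    "glucose_before_dose",
    "clipped",
]


def morning_patterns(
    profiles: pd.DataFrame,
    slots: pd.DataFrame,
    glucose: pd.DataFrame,
    subject_id: str = "",
) -> pd.DataFrame:
    """Wake-relative offsets of first glucose test and morning ingestion.

    Days without a derived wake time yield no pattern row.
    """
    wakes = profiles.dropna(subset=["wake_time"])
    if len(glucose) and len(wakes):
        # recover the study start from any derived wake and its study day
        w0, d0 = wakes["wake_time"].iloc[0], int(wakes["study_day"].iloc[0])
        start = w0.normalize() - pd.Timedelta(days=d0 - 1)
        g_day = study_day(glucose["at"], start)
    morning_slots = slots[(slots["slot"] == "morning") & slots["taken"]]
    ing_by_day = morning_slots.set_index("study_day")["ingestion_at"]

    rows = []
    for _, prow in profiles.iterrows():
        wake = prow["wake_time"]
        if pd.isna(wake):
            continue
        d = int(prow["study_day"])
        noon = wake.normalize() + pd.Timedelta(hours=12)
        clipped = False

        g_off = np.nan
        if len(glucose):
            day_glucose = glucose[(g_day == d).to_numpy()]
            morning = day_glucose[day_glucose["at"] < noon]
            # allow reads slightly before the derived wake: clip to 0
            morning = morning[morning["at"] >= wake - pd.Timedelta(hours=1)]
            if len(morning):
                first = morning["at"].iloc[0]
                g_off = max((first - wake).total_seconds() / 3600.0, 0.0)
                clipped |= first < wake

        i_off = np.nan
        if d in ing_by_day.index:
            ing = ing_by_day.loc[d]
            i_off = (ing - wake).total_seconds() / 3600.0
            if i_off < 0:
                i_off, clipped = 0.0, True

        both = not (np.isnan(g_off) or np.isnan(i_off))
        rows.append(
            {
                "subject_id": subject_id,
                "study_day": d,
                "wake_time": wake,
                "first_glucose_offset_h": g_off,
                "morning_ingestion_offset_h": i_off,
                "glucose_before_dose": bool(g_off < i_off) if both else None,
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows, columns=MORNING_COLUMNS)


def glucose_dose_timing_correlation(patterns: pd.DataFrame) -> CorrelationResult:
    """Association between morning glucose-test and ingestion offsets."""
    return pearson(
        patterns["first_glucose_offset_h"], patterns["morning_ingestion_offset_h"]
    )


def glucose_summary(glucose: pd.DataFrame) -> dict:
    """Mean, min, max, and normal-approximation 95% CI of glucose readings."""
    n = len(glucose)
    if n == 0:
        raise ValueError("no glucose readings")
    vals = glucose["mg_dl"].to_numpy(float)
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {
        "mean": mean,
        "min": float(vals.min()),
        "max": float(vals.max()),
        "ci95_low": mean - 1.96 * sem,
        "ci95_high": mean + 1.96 * sem,
        "n_readings": n,
    }
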
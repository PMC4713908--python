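"""Daily patch-function QC based on activity event counts.

Patch function is verified per calendar day from the number of activity
events recorded: a 5-minute sampling cadence yields 288 events on a fully
recorded day.  Days without full function are excluded from the lagged
correlation analysis downstream.  A day with *more* than 288 events is a
recording anomaly: it is flagged and its wear fraction capped at 1, but it
is not excluded, since the patch was evidently worn.
"""

from __future__ import annotations

import pandas as pd

from .core import ACTIVITY_EPOCHS_PER_DAY, SubjectRecord, study_day

QC_COLUMNS = [
    "subject_id",
    "study_day",
    "activity_event_count",
    "full_function",
    "anomalous",
    "wear_fraction",
]


def daily_activity_counts(
    record: SubjectRecord,
    expected_daily: int = ACTIVITY_EPOCHS_PER_DAY,
    min_count: int | None = None,
) -> pd.DataFrame:
    """Per-day activity event counts and patch-function flags.

    Returns one row per day of participation with columns
    :data:`QC_COLUMNS`.  ``full_function`` requires at least ``min_count``
    events (default: exactly ``expected_daily``); ``wear_fraction`` is the
    fraction of expected epochs present, capped at 1.
    """
    if min_count is None:
        min_count = expected_daily
    act = record.activity
    counts = pd.Series(0, index=pd.RangeIndex(1, record.participation_days + 1))
    if len(act):
        observed = study_day(act["at"], record.start).value_counts()
        counts = counts.add(observed, fill_value=0).astype(int)
        counts = counts.loc[1 : record.participation_days]
    qc = pd.DataFrame(
        {
            "subject_id": record.subject_id,
            "study_day": counts.index.to_numpy(),
            "activity_event_count": counts.to_numpy(),
        }
    )
    qc["full_function"] = qc["activity_event_count"] >= min_count
    qc["anomalous"] = qc["activity_event_count"] > expected_daily
    qc["wear_fraction"] = (qc["activity_event_count"] / expected_daily).clip(upper=1.0)
    return qc[QC_COLUMNS]


def exclusion_mask(qc: pd.DataFrame) -> set[tuple[str, int]]:
    """Days lacking full patch function, to be dropped from correlations."""
    bad = qc[~qc["full_function"]]
    return set(zip(bad["subject_id"], bad["study_day"].astype(int)))


def cohort_wear_summary(qc_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-subject continuous-wear percentage (mean daily wear fraction x 100)."""
    rows = []
    for qc in qc_tables:
        rows.append(
            {
                "subject_id": qc["subject_id"].iloc[0],
                "n_days": len(qc),
                "wear_pct": 100.0 * qc["wear_fraction"].mean(),
                "n_anomalous_days": int(qc["anomalous"].sum()),
            }
        )
    return pd.DataFrame(rows)
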
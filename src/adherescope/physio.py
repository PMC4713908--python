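"""Daily step counts, resting heart rate, and sustained heart-rate elevation.

The fitness read-out pairs each day's step count with the sustained
maximum heart-rate elevation from rest: the maximum over 30-minute sliding
windows of the window-mean pulse, minus the subject's resting rate.  The
per-individual resting rate is the mean pulse over derived rest epochs;
when no rest epochs exist it falls back to the 5th percentile of all pulse
samples (flagged).  The elevation-versus-steps relationship is summarised
by a least-squares slope, read qualitatively: steeper slopes at low step
counts suggest lower cardiovascular fitness.
"""

from __future__ import annotations

import warnings
from datetime import timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .core import SubjectRecord, study_day
from .sleep import RestStateSeries


def daily_steps(activity: pd.DataFrame, start: pd.Timestamp, n_days: int) -> pd.Series:
    """Sum of epoch step values per calendar day, indexed by study_day."""
    out = pd.Series(0, index=pd.RangeIndex(1, n_days + 1, name="study_day"), dtype=np.int64)
    if len(activity):
        sums = activity.groupby(study_day(activity["at"], pd.Timestamp(start)))["steps"].sum()
        out = out.add(sums, fill_value=0).loc[1:n_days].astype(np.int64)
    return out


def resting_heart_rate(
    pulse: pd.DataFrame, rest_states: RestStateSeries | None = None
) -> tuple[float, bool]:
    """Mean pulse over rest epochs; returns ``(bpm, used_fallback)``.

    Pulse samples are attributed to the rest epoch covering them.  With no
    rest epochs available the 5th percentile of all pulse samples is used
    and flagged via the second return value.
    """
    if not len(pulse):
        raise ValueError("no pulse samples")
    if rest_states is not None and rest_states.rest_mask().any():
        grid = rest_states.states.index
        epoch = pd.Timedelta(minutes=5)
        pos = grid.searchsorted(pulse["at"].to_numpy(), side="right") - 1
        ok = pos >= 0
        ok[ok] &= (
            pulse["at"].to_numpy()[ok] - grid.to_numpy()[pos[ok]]
        ) < np.timedelta64(int(epoch.total_seconds()), "s")
        in_rest = np.zeros(len(pulse), dtype=bool)
        in_rest[ok] = rest_states.rest_mask()[pos[ok]]
        if in_rest.any():
            return float(pulse.loc[in_rest, "bpm"].mean()), False
    warnings.warn("no rest epochs with pulse; falling back to 5th percentile", stacklevel=2)
    return float(np.percentile(pulse["bpm"], 5)), True


def sustained_max_elevation(
    pulse: pd.DataFrame,
    resting_hr: float,
    start: pd.Timestamp,
    n_days: int,
    window: timedelta = timedelta(minutes=30),
) -> pd.Series:
    """Per-day sustained maximum heart-rate elevation from rest (bpm).

    For each day, the maximum over sliding windows of the window-mean
    pulse, minus ``resting_hr``, floored at 0.  Days with fewer samples
    than one full window are absent (NaN).
    """
    n_win = max(int(window / timedelta(minutes=10)), 1)
    out = pd.Series(np.nan, index=pd.RangeIndex(1, n_days + 1, name="study_day"))
    if not len(pulse):
        return out
    days = study_day(pulse["at"], pd.Timestamp(start))
    for d, grp in pulse.groupby(days.to_numpy()):
        if d < 1 or d > n_days or len(grp) < n_win:
            continue
        means = grp["bpm"].rolling(n_win).mean().dropna()
        out.loc[d] = max(float(means.max()) - resting_hr, 0.0)
    return out


def daily_physio(
    record: SubjectRecord, rest_states: RestStateSeries | None = None
) -> tuple[pd.DataFrame, float, bool]:
    """Combine steps, HR descriptives, and sustained elevation per day.

    Returns ``(table, resting_hr, resting_fallback)``; table columns are
    study_day, step_count, hr_mean, hr_max, hr_min, sustained_max_hr,
    hr_elevation.
    """
    n_days = record.participation_days
    steps = daily_steps(record.activity, record.start, n_days)
    rhr, fallback = resting_heart_rate(record.pulse, rest_states)
    elev = sustained_max_elevation(record.pulse, rhr, record.start, n_days)
    days = study_day(record.pulse["at"], record.start)
    hr_stats = record.pulse.groupby(days.to_numpy())["bpm"].agg(["mean", "max", "min"])
    table = pd.DataFrame(
        {
            "subject_id": record.subject_id,
            "study_day": np.arange(1, n_days + 1),
            "step_count": steps.to_numpy(),
        }
    )
    table["hr_mean"] = table["study_day"].map(hr_stats["mean"])
    table["hr_max"] = table["study_day"].map(hr_stats["max"])
    table["hr_min"] = table["study_day"].map(hr_stats["min"])
    table["hr_elevation"] = table["study_day"].map(elev)
    table["sustained_max_hr"] = table["hr_elevation"] + rhr
    return table, rhr, fallback


def elevation_vs_steps(daily: pd.DataFrame) -> dict:
    """Least-squares slope of sustained HR elevation on daily step count.

    Needs at least 3 days with both quantities; zero step variance makes
    the slope undefined (reported as None).  Returns the paired points for
    plotting alongside the fit.
    """
    pts = daily[["step_count", "hr_elevation"]].dropna()
    if len(pts) < 3:
        raise ValueError("need at least 3 days with steps and elevation")
    x, y = pts["step_count"].to_numpy(float), pts["hr_elevation"].to_numpy(float)
    if np.ptp(x) == 0:
        return {"slope": None, "intercept": None, "points": pts, "reason": "zero step variance"}
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "rvalue": float(fit.rvalue),
        "points": pts,
    }
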
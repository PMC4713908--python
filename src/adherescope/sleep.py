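"""Sleep/rest state derivation from activity, posture, and pulse.

The sleep/rest signal is a binary epoch state — awake (0) or asleep (100)
on the 5-minute activity grid.  An epoch is classified as rest when
activity is at or below a step threshold, posture is recumbent, and pulse
is no more than a margin above the subject's resting rate (bootstrapped as
the 5th percentile of all pulse samples).  The raw classification is then
smoothed under the waking-time assumptions:

1. there is a single daily waking event;
2. short wake interruptions inside long rest periods are transient and
   ignored;
3. short rests inside long waking periods do not mark the main daily
   transitions.

Wake time is the end of the longest rest block intersecting the morning
(00:00-12:00] window; bedtime is the start of that block (which may
precede midnight).  Nocturnal disturbances — wake runs of at least
``disturbance_min`` strictly inside rest spans within the 22:00-08:00
window — are counted on the *unsmoothed* classification (smoothing exists
precisely to erase them) and attributed to the morning's day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time

import numpy as np
import pandas as pd

from .core import SubjectRecord, bool_runs

EPOCH_MIN = 5


@dataclass(frozen=True)
class SleepParams:
    """Tunable thresholds of the rest classifier and smoother.

    The defaults are declared stand-ins: the inputs and assumptions of the
    derivation are fixed by the analysis design, but the exact thresholds
    are free parameters.
    """

    act_thresh: float = 5.0  # steps/epoch at or below which an epoch can be rest
    hr_margin: float = 10.0  # bpm above resting still compatible with rest
    min_gap_rest_min: float = 30.0  # wake runs shorter than this inside rest are absorbed
    min_gap_wake_min: float = 60.0  # rest runs shorter than this inside wake are removed
    disturbance_min_min: float = 10.0  # minimum duration of a counted disturbance
    nocturnal_window: tuple[time, time] = (time(22, 0), time(8, 0))
    min_day_coverage: float = 0.5  # fraction of epochs needed to derive a day
    fill_max_min: float = 30.0  # longest missing gap bridged by neighbour consensus


@dataclass
class RestStateSeries:
    """Binary rest state (0 awake / 100 asleep) on the 5-min epoch grid."""

    states: pd.Series  # int values in {0, 100}, DatetimeIndex
    derivable: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    # study_day -> bool; days with insufficient epoch coverage are undervable

    def values(self) -> np.ndarray:
        return self.states.to_numpy()

    def rest_mask(self) -> np.ndarray:
        return self.states.to_numpy() >= 50


def bootstrap_resting_hr(pulse: pd.DataFrame) -> float:
    """Resting-rate proxy for classification: 5th percentile of all pulse."""
    if not len(pulse):
        raise ValueError("cannot bootstrap resting heart rate without pulse samples")
    return float(np.percentile(pulse["bpm"], 5))


def classify_rest(record: SubjectRecord, params: SleepParams = SleepParams()) -> RestStateSeries:
    """Raw epoch-level rest classification from the three patch streams.

    Streams are aligned to the common 5-minute grid (activity and posture
    snapped to the nearest epoch, pulse forward-filled up to 10 minutes).
    Epochs where any input is missing inherit the consensus of their
    neighbours (awake when the neighbours disagree); days with less than
    ``min_day_coverage`` input coverage are flagged underivable.
    """
    n_epochs = record.participation_days * (1440 // EPOCH_MIN)
    grid = record.start + pd.to_timedelta(np.arange(n_epochs) * EPOCH_MIN, unit="m")
    tol = pd.Timedelta(minutes=EPOCH_MIN / 2)

    act = record.activity.set_index("at")["steps"]
    post = record.posture.set_index("at")["posture"]
    pulse = record.pulse.set_index("at")["bpm"]
    act_g = _grid_align(act, grid, tol)
    post_g = _grid_align(post, grid, tol)
    pulse_g = (
        pulse.reindex(grid, method="pad", tolerance=pd.Timedelta(minutes=10))
        if len(pulse)
        else pd.Series(np.nan, index=grid)
    )

    present = act_g.notna() & post_g.notna() & pulse_g.notna()
    hr_limit = (bootstrap_resting_hr(record.pulse) + params.hr_margin) if len(pulse) else np.nan
    rest = (
        (act_g <= params.act_thresh)
        & (post_g == "recumbent")
        & (pulse_g <= hr_limit)
    )
    state = pd.Series(np.where(rest.to_numpy(), 100.0, 0.0), index=grid)
    state[~present.to_numpy()] = np.nan

    # short missing gaps inherit neighbour consensus (awake on disagreement);
    # long outages (e.g. whole dropout days) default to awake rather than
    # letting two nights' rest bleed together across the gap
    max_fill = int(round(params.fill_max_min / EPOCH_MIN))
    fwd = state.ffill(limit=max_fill)
    bwd = state.bfill(limit=max_fill)
    state = np.where(state.notna(), state, np.where(fwd == bwd, fwd, 0.0))
    state = pd.Series(state, index=grid).fillna(0.0).astype(int)

    day = pd.Series(np.arange(n_epochs) // (1440 // EPOCH_MIN) + 1, index=grid)
    coverage = present.groupby(day.to_numpy()).mean()
    derivable = coverage >= params.min_day_coverage
    derivable.index.name = "study_day"
    return RestStateSeries(states=state, derivable=derivable)


def _grid_align(s: pd.Series, grid: pd.DatetimeIndex, tol: pd.Timedelta) -> pd.Series:
    if not len(s):
        return pd.Series(np.nan, index=grid)
    s = s[~s.index.duplicated(keep="first")]
    return s.reindex(grid, method="nearest", tolerance=tol)


def smooth_values(
    values: np.ndarray,
    min_gap_rest_epochs: int,
    min_gap_wake_epochs: int,
) -> np.ndarray:
    """Run-length smoothing of a 0/100 state array, in two ordered passes.

    Pass 1 turns wake runs shorter than ``min_gap_rest_epochs`` that are
    flanked by rest on both sides into rest; pass 2 turns rest runs shorter
    than ``min_gap_wake_epochs`` flanked by wake into wake.  Runs touching
    the ends of the array are never relabelled (their context is unknown).
    """
    out = np.asarray(values).copy()
    for target, min_len in ((0, min_gap_rest_epochs), (100, min_gap_wake_epochs)):
        mask = out == target
        for s, e in bool_runs(mask):
            if s == 0 or e == len(out):
                continue
            if (e - s) < min_len:
                out[s:e] = 100 - target
    return out


def smooth_states(series: RestStateSeries, params: SleepParams = SleepParams()) -> RestStateSeries:
    """Apply the transient-interruption smoothing to a classified series."""
    vals = smooth_values(
        series.values(),
        int(round(params.min_gap_rest_min / EPOCH_MIN)),
        int(round(params.min_gap_wake_min / EPOCH_MIN)),
    )
    return RestStateSeries(
        states=pd.Series(vals, index=series.states.index),
        derivable=series.derivable.copy(),
    )


def daily_profile(
    series: RestStateSeries,
    raw: RestStateSeries | None = None,
    params: SleepParams = SleepParams(),
    subject_id: str = "",
) -> pd.DataFrame:
    """Per-day sleep metrics from a smoothed rest-state series.

    Returns one row per study day with wake_time, bed_time, rest_hours
    (total rest within the calendar day) and nocturnal disturbance count.
    ``raw`` is the pre-smoothing classification used for disturbance
    counting; when omitted, disturbances are counted on ``series`` itself.
    Underivable days get null metrics.
    """
    idx = series.states.index
    start = idx[0].normalize()
    n_days = int(round((idx[-1] - start + pd.Timedelta(minutes=EPOCH_MIN)) / pd.Timedelta(days=1)))
    rest = series.rest_mask()
    runs = bool_runs(rest)
    run_spans = [(idx[s], idx[e - 1] + pd.Timedelta(minutes=EPOCH_MIN)) for s, e in runs]

    count_series = raw if raw is not None else series
    dist_by_day = _nocturnal_disturbances(count_series, params, start, n_days)

    epd = 1440 // EPOCH_MIN
    day_of_epoch = np.arange(len(rest)) // epd
    rest_per_day = np.bincount(day_of_epoch, weights=rest.astype(float), minlength=n_days)

    rows = []
    for d in range(1, n_days + 1):
        derivable = bool(series.derivable.get(d, True))
        d0 = start + pd.Timedelta(days=d - 1)
        noon = d0 + pd.Timedelta(hours=12)
        wake = bed = pd.NaT
        if derivable:
            # longest rest block intersecting (00:00, 12:00]; ties -> earliest
            cands = [
                (b_start, b_end)
                for b_start, b_end in run_spans
                if b_start <= noon and b_end > d0
            ]
            if cands:
                best = max(cands, key=lambda be: (be[1] - be[0], -be[0].value))
                bed, wake = best
        rows.append(
            {
                "subject_id": subject_id,
                "study_day": d,
                "wake_time": wake,
                "bed_time": bed,
                "rest_hours": rest_per_day[d - 1] * EPOCH_MIN / 60.0 if derivable else np.nan,
                "disturbances": dist_by_day.get(d, 0) if derivable else np.nan,
                "derivable": derivable,
            }
        )
    return pd.DataFrame(rows)


def _nocturnal_disturbances(
    series: RestStateSeries,
    params: SleepParams,
    start: pd.Timestamp,
    n_days: int,
) -> dict[int, int]:
    """Count qualifying wake runs per night, attributed to the morning day.

    A disturbance is a wake run of at least ``disturbance_min`` flanked by
    rest on both sides (strictly inside a rest span) that intersects the
    nocturnal window ending on the morning's day.
    """
    idx = series.states.index
    awake = ~series.rest_mask()
    rest = series.rest_mask()
    min_epochs = int(round(params.disturbance_min_min / EPOCH_MIN))
    t_even, t_morn = params.nocturnal_window
    out: dict[int, int] = {d: 0 for d in range(1, n_days + 1)}
    for s, e in bool_runs(awake):
        if s == 0 or e == len(idx):
            continue  # not strictly inside a rest span
        if not (rest[s - 1] and rest[e]):
            continue
        if (e - s) < min_epochs:
            continue
        run_start, run_end = idx[s], idx[e - 1] + pd.Timedelta(minutes=EPOCH_MIN)
        # the run must lie wholly inside a night's window: the daytime wake
        # span between two nights is flanked by rest too, but is no break
        for d in range(1, n_days + 1):
            win0 = start + pd.Timedelta(days=d - 2, hours=t_even.hour, minutes=t_even.minute)
            win1 = start + pd.Timedelta(days=d - 1, hours=t_morn.hour, minutes=t_morn.minute)
            if run_start >= win0 and run_end <= win1:
                out[d] += 1
                break
    return out


def sleep_profile_for_record(
    record: SubjectRecord, params: SleepParams = SleepParams()
) -> tuple[pd.DataFrame, RestStateSeries, RestStateSeries]:
    """Full derivation chain: classify, smooth, profile.

    Returns ``(profiles, smoothed, raw)`` so callers can reuse the state
    series for plotting.
    """
    raw = classify_rest(record, params)
    smoothed = smooth_states(raw, params)
    profiles = daily_profile(smoothed, raw=raw, params=params, subject_id=record.subject_id)
    return profiles, smoothed, raw
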
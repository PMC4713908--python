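"""Core domain types shared by every stage of the pipeline.

All timestamps are subject-local wall-clock times (the study is
single-site); we use timezone-naive ``pandas.Timestamp`` values and never
perform timezone arithmetic.  A *study day* is a calendar day counted from
the subject's start date, starting at 1.  Patch streams are sampled on a
fixed epoch grid: 5 minutes for activity and posture, 10 minutes for pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time, timedelta

import numpy as np
import pandas as pd

#: Epoch lengths of the wearable patch.
ACTIVITY_EPOCH = timedelta(minutes=5)
PULSE_EPOCH = timedelta(minutes=10)

#: Expected number of activity (and posture) samples per fully recorded day.
ACTIVITY_EPOCHS_PER_DAY = 288
#: Expected number of pulse samples per fully recorded day.
PULSE_EPOCHS_PER_DAY = 144
#: Total patch events (activity + posture + pulse) on a fully recorded day.
PATCH_EVENTS_PER_DAY = 2 * ACTIVITY_EPOCHS_PER_DAY + PULSE_EPOCHS_PER_DAY

POSTURE_CODES = ("upright", "recumbent", "other")

#: Physiological plausibility bounds enforced at read time.
PULSE_BOUNDS = (20.0, 250.0)
GLUCOSE_BOUNDS = (20.0, 600.0)

STREAM_KINDS = ("ingestions", "activity", "posture", "pulse", "glucose")

#: Column layout of each stream table (first column is always the timestamp).
STREAM_COLUMNS = {
    "ingestions": ["at"],
    "activity": ["at", "steps"],
    "posture": ["at", "posture"],
    "pulse": ["at", "bpm"],
    "glucose": ["at", "mg_dl"],
}


def study_day(at: pd.Timestamp | pd.Series, start: pd.Timestamp):
    """Map a timestamp to its 1-based study day (day boundary = local midnight)."""
    if isinstance(at, pd.Series):
        return (at.dt.normalize() - start.normalize()).dt.days + 1
    return (at.normalize() - start.normalize()).days + 1


def seconds_since_midnight(at: pd.Timestamp | pd.Series):
    """Clock time of a timestamp expressed as seconds in 0..86399."""
    if isinstance(at, pd.Series):
        return (at - at.dt.normalize()).dt.total_seconds().astype(int)
    return int((at - at.normalize()).total_seconds())


def bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of True runs in a boolean array."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [mask.size]
    return list(zip(starts, ends))


def parse_clock(value: str | time) -> time:
    """Accept 'HH:MM' / 'HH:MM:SS' strings or ``datetime.time`` objects."""
    if isinstance(value, time):
        return value
    parts = [int(p) for p in str(value).split(":")]
    while len(parts) < 3:
        parts.append(0)
    return time(*parts[:3])


@dataclass(frozen=True)
class DosingRegimen:
    """Prescribed dosing schedule and the rules that score it.

    Parameters
    ----------
    scheduled_times
        Clock times of the prescribed doses, strictly increasing within the
        day.  The default twice-daily schedule is 08:00 and 20:00.
    window_halfwidth
        Half-width of the on-time window around each scheduled dose.  An
        ingestion within this window counts toward timing adherence.
    missed_delay
        A dose whose ingestion is delayed by more than this is scored as
        missed.
    """

    scheduled_times: tuple[time, ...] = (time(8, 0), time(20, 0))
    window_halfwidth: timedelta = timedelta(hours=2)
    missed_delay: timedelta = timedelta(hours=12)

    def __post_init__(self) -> None:
        times = tuple(parse_clock(t) for t in self.scheduled_times)
        object.__setattr__(self, "scheduled_times", times)
        if len(times) == 0:
            raise ValueError("regimen needs at least one scheduled time")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("scheduled_times must be strictly increasing")
        gaps = self._inter_dose_gaps()
        if self.window_halfwidth >= min(gaps) / 2:
            raise ValueError(
                "window_halfwidth must be smaller than half the minimum "
                "inter-dose gap"
            )

    def _inter_dose_gaps(self) -> list[timedelta]:
        day = timedelta(days=1)
        secs = [
            timedelta(hours=t.hour, minutes=t.minute, seconds=t.second)
            for t in self.scheduled_times
        ]
        if len(secs) == 1:
            return [day]
        gaps = [b - a for a, b in zip(secs, secs[1:])]
        gaps.append(secs[0] + day - secs[-1])  # wrap-around gap
        return gaps

    @property
    def slot_labels(self) -> tuple[str, ...]:
        if len(self.scheduled_times) == 2:
            return ("morning", "evening")
        return tuple(f"slot{i + 1}" for i in range(len(self.scheduled_times)))

    def to_dict(self) -> dict:
        return {
            "scheduled_times": [t.strftime("%H:%M") for t in self.scheduled_times],
            "window_halfwidth_min": self.window_halfwidth / timedelta(minutes=1),
            "missed_delay_min": self.missed_delay / timedelta(minutes=1),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DosingRegimen":
        return cls(
            scheduled_times=tuple(parse_clock(t) for t in d["scheduled_times"]),
            window_halfwidth=timedelta(minutes=float(d.get("window_halfwidth_min", 120))),
            missed_delay=timedelta(minutes=float(d.get("missed_delay_min", 720))),
        )


def _empty_stream(kind: str) -> pd.DataFrame:
    cols = STREAM_COLUMNS[kind]
    df = pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if c == "at" else object) for c in cols})
    return _coerce_stream(kind, df)


def _coerce_stream(kind: str, df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["at"] = pd.to_datetime(df["at"])
    if kind == "activity":
        df["steps"] = df["steps"].astype(np.int64) if len(df) else pd.Series(dtype=np.int64)
    elif kind == "pulse":
        df["bpm"] = df["bpm"].astype(float) if len(df) else pd.Series(dtype=float)
    elif kind == "glucose":
        df["mg_dl"] = df["mg_dl"].astype(float) if len(df) else pd.Series(dtype=float)
    elif kind == "posture":
        df["posture"] = df["posture"].astype(str) if len(df) else pd.Series(dtype=str)
    return df.sort_values("at", kind="stable").reset_index(drop=True)


@dataclass
class SubjectRecord:
    """One subject's complete multi-stream record.

    ``streams`` maps each stream kind to a tidy DataFrame sorted by
    timestamp (see :data:`STREAM_COLUMNS` for layouts).  All events must
    fall within ``[start, start + participation_days)``.
    """

    subject_id: str
    start: pd.Timestamp
    participation_days: int
    regimen: DosingRegimen = field(default_factory=DosingRegimen)
    streams: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start).normalize()
        if self.participation_days < 1:
            raise ValueError("participation_days must be >= 1")
        for kind in STREAM_KINDS:
            if kind not in self.streams:
                self.streams[kind] = _empty_stream(kind)
            else:
                self.streams[kind] = _coerce_stream(kind, self.streams[kind])
        end = self.end
        for kind, df in self.streams.items():
            if len(df) and ((df["at"] < self.start).any() or (df["at"] >= end).any()):
                raise ValueError(
                    f"{self.subject_id}/{kind}: events outside the participation window"
                )

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(days=self.participation_days)

    @property
    def ingestions(self) -> pd.DataFrame:
        return self.streams["ingestions"]

    @property
    def activity(self) -> pd.DataFrame:
        return self.streams["activity"]

    @property
    def posture(self) -> pd.DataFrame:
        return self.streams["posture"]

    @property
    def pulse(self) -> pd.DataFrame:
        return self.streams["pulse"]

    @property
    def glucose(self) -> pd.DataFrame:
        return self.streams["glucose"]

    def study_days(self) -> range:
        return range(1, self.participation_days + 1)

    def day_start(self, day: int) -> pd.Timestamp:
        return self.start + pd.Timedelta(days=day - 1)

    def equals(self, other: "SubjectRecord") -> bool:
        """Field-for-field equality, used by the round-trip guarantees."""
        if (
            self.subject_id != other.subject_id
            or self.start != other.start
            or self.participation_days != other.participation_days
            or self.regimen != other.regimen
        ):
            return False
        return all(
            self.streams[k].reset_index(drop=True).equals(
                other.streams[k].reset_index(drop=True)
            )
            for k in STREAM_KINDS
        )
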
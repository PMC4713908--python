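"""Read and write subject directories in the plain-text interchange format.

A subject directory holds one CSV per stream kind plus ``subject.yaml``::

    subject.yaml      subject_id, start_date, participation_days, regimen
    ingestions.csv    timestamp
    activity.csv      timestamp,steps
    posture.csv       timestamp,posture
    pulse.csv         timestamp,bpm
    glucose.csv       timestamp,mg_dl

Timestamps are ISO-8601 local wall-clock times at second resolution.
Reading validates every row against kind-specific plausibility bounds;
offending rows are rejected individually and reported with their line
numbers, and a file is rejected outright if more than 1% of its rows carry
malformed timestamps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    GLUCOSE_BOUNDS,
    POSTURE_CODES,
    PULSE_BOUNDS,
    STREAM_COLUMNS,
    STREAM_KINDS,
    DosingRegimen,
    SubjectRecord,
)

_FILE_NAMES = {kind: f"{kind}.csv" for kind in STREAM_KINDS}
_CSV_HEADERS = {
    "ingestions": ["timestamp"],
    "activity": ["timestamp", "steps"],
    "posture": ["timestamp", "posture"],
    "pulse": ["timestamp", "bpm"],
    "glucose": ["timestamp", "mg_dl"],
}


class StreamFileError(ValueError):
    """A required stream file is missing or unusable as a whole."""


@dataclass
class ReadReport:
    """Per-file record of rejected rows (2-based line numbers, reasons)."""

    rejected: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def add(self, fname: str, line: int, reason: str) -> None:
        self.rejected.setdefault(fname, []).append((line, reason))

    @property
    def n_rejected(self) -> int:
        return sum(len(v) for v in self.rejected.values())


def _validate_rows(kind: str, df: pd.DataFrame, fname: str, report: ReadReport) -> pd.DataFrame:
    """Drop rows violating kind-specific bounds, logging their line numbers."""
    # line numbers: header is line 1, first data row is line 2
    lines = df.index.to_numpy() + 2
    ok = np.ones(len(df), dtype=bool)
    reasons = np.empty(len(df), dtype=object)
    if kind == "activity":
        vals = pd.to_numeric(df["steps"], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        reasons[bad.to_numpy()] = "steps must be a non-negative integer"
        ok &= ~bad.to_numpy()
        df = df.assign(steps=vals)
    elif kind == "pulse":
        vals = pd.to_numeric(df["bpm"], errors="coerce")
        lo, hi = PULSE_BOUNDS
        bad = vals.isna() | (vals < lo) | (vals > hi)
        reasons[bad.to_numpy()] = f"bpm outside plausible range {lo}-{hi}"
        ok &= ~bad.to_numpy()
        df = df.assign(bpm=vals)
    elif kind == "glucose":
        vals = pd.to_numeric(df["mg_dl"], errors="coerce")
        lo, hi = GLUCOSE_BOUNDS
        bad = vals.isna() | (vals < lo) | (vals > hi)
        reasons[bad.to_numpy()] = f"glucose outside plausible range {lo}-{hi} mg/dl"
        ok &= ~bad.to_numpy()
        df = df.assign(mg_dl=vals)
    elif kind == "posture":
        bad = ~df["posture"].astype(str).isin(POSTURE_CODES)
        reasons[bad.to_numpy()] = f"posture code not in {POSTURE_CODES}"
        ok &= ~bad.to_numpy()
    for line, reason in zip(lines[~ok], reasons[~ok]):
        report.add(fname, int(line), reason)
    return df[ok]  # original row index preserved for downstream line numbers


def _read_stream(path: Path, kind: str, report: ReadReport) -> pd.DataFrame:
    fname = path.name
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = _CSV_HEADERS[kind]
    if list(raw.columns) != expected:
        raise StreamFileError(f"{fname}: expected columns {expected}, got {list(raw.columns)}")
    at = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    bad_ts = at.isna()
    if len(raw) and bad_ts.sum() > 0.01 * len(raw):
        raise StreamFileError(
            f"{fname}: {int(bad_ts.sum())}/{len(raw)} rows have malformed timestamps (>1%)"
        )
    for line in (raw.index[bad_ts] + 2):
        report.add(fname, int(line), "malformed timestamp")
    df = raw[~bad_ts].reset_index(drop=False).rename(columns={"index": "_row"})
    df["at"] = at[~bad_ts].to_numpy()
    df.index = df.pop("_row")  # keep original row index for line numbers
    df = _validate_rows(kind, df, fname, report)
    return df[STREAM_COLUMNS[kind]]


def read_subject(dir_path: str | Path) -> SubjectRecord:
    """Load and validate one subject directory.

    Raises :class:`StreamFileError` if a stream file is missing, has the
    wrong header, or has more than 1% malformed timestamps.  Rows that
    violate plausibility bounds or fall outside the participation window
    are rejected individually; the report is attached to the returned
    record as ``record.read_report``.
    """
    dir_path = Path(dir_path)
    meta_path = dir_path / "subject.yaml"
    if not meta_path.exists():
        raise StreamFileError(f"missing subject metadata file: {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    regimen = DosingRegimen.from_dict(meta.get("regimen", {"scheduled_times": ["08:00", "20:00"]}))
    start = pd.Timestamp(meta["start_date"]).normalize()
    n_days = int(meta["participation_days"])

    report = ReadReport()
    streams: dict[str, pd.DataFrame] = {}
    for kind in STREAM_KINDS:
        path = dir_path / _FILE_NAMES[kind]
        if not path.exists():
            raise StreamFileError(f"missing stream file: {path} (stream '{kind}')")
        df = _read_stream(path, kind, report)
        end = start + pd.Timedelta(days=n_days)
        in_window = ((df["at"] >= start) & (df["at"] < end)).to_numpy()
        for line in df.index[~in_window]:
            report.add(_FILE_NAMES[kind], int(line) + 2, "event outside participation window")
        streams[kind] = df[in_window].reset_index(drop=True)

    record = SubjectRecord(
        subject_id=str(meta["subject_id"]),
        start=start,
        participation_days=n_days,
        regimen=regimen,
        streams=streams,
    )
    record.read_report = report  # type: ignore[attr-defined]
    return record


def _format_stream(kind: str, df: pd.DataFrame) -> str:
    out = pd.DataFrame()
    out["timestamp"] = df["at"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    for col in STREAM_COLUMNS[kind][1:]:
        if col == "bpm":
            out[col] = df[col].map(lambda v: f"{v:g}")
        elif col == "mg_dl":
            out[col] = df[col].map(lambda v: f"{v:g}")
        else:
            out[col] = df[col]
    buf = io.StringIO()
    out.to_csv(buf, index=False)
    return buf.getvalue()


def write_subject(record: SubjectRecord, dir_path: str | Path) -> None:
    """Write a subject directory such that ``read_subject`` round-trips it."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": record.subject_id,
        "start_date": record.start.strftime("%Y-%m-%d"),
        "participation_days": int(record.participation_days),
        "regimen": record.regimen.to_dict(),
    }
    (dir_path / "subject.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    for kind in STREAM_KINDS:
        (dir_path / _FILE_NAMES[kind]).write_text(_format_stream(kind, record.streams[kind]))


def read_cohort(root: str | Path) -> list[SubjectRecord]:
    """Read every subject directory (one level deep) under ``root``."""
    root = Path(root)
    records = []
    for sub in sorted(p for p in root.iterdir() if (p / "subject.yaml").exists()):
        records.append(read_subject(sub))
    if not records:
        raise StreamFileError(f"no subject directories found under {root}")
    return records
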
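"""Multi-stream time-domain visualizations.

Three families of figures are produced, mirroring the three analysis
intervals: whole-study summaries, daily 24-hour panels, and weekly
seven-day panels.  Plots are *views* of the derived tables — every marker
corresponds to exactly one record in the data passed in, and nothing is
recomputed at plot time.  Heterogeneous units share the time axis through
twin y-axes: activity (steps/epoch) and the 0/100 sleep state on the left,
glucose (mg/dl) on the right.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GLUCOSE_REFERENCE_MG_DL = (150.0, 180.0)


def _save(fig, path: Path, formats=("png",)) -> list[Path]:
    out = []
    for fmt in formats:
        p = path.with_suffix(f".{fmt}")
        fig.savefig(p, dpi=110, metadata={"Software": None} if fmt == "svg" else None)
        out.append(p)
    plt.close(fig)
    return out


def plot_study_summary(derived: dict, outdir: str | Path, formats=("png",)) -> list[Path]:
    """Whole-study summary figures for a cohort.

    ``derived`` holds the cohort tables produced by the pipeline:
    ``adherence`` (per-subject summary rows), ``glucose`` (per-subject
    glucose summaries), ``missed`` (per-subject missed-dose splits),
    ``ingestion_hists``, ``profiles``, ``patterns``, ``physio`` — any
    missing table skips its panel with a logged warning.  An empty cohort
    is an error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    adh = derived.get("adherence")
    if adh is None or not len(adh):
        raise ValueError("empty cohort: nothing to plot")
    files: list[Path] = []

    # 1. taking / timing adherence bars
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(adh))
    ax.bar(x - 0.2, adh["taking_pct"], width=0.38, label="taking")
    ax.bar(x + 0.2, adh["timing_pct"], width=0.38, label="timing")
    ax.set_xticks(x, adh["subject_id"])
    ax.set_ylabel("adherence (%)")
    ax.set_ylim(0, 105)
    ax.set_title("Taking and timing adherence across the study period")
    ax.legend()
    files += _save(fig, outdir / "study_adherence_bars", formats)

    # 2. glucose ranges with CI whiskers
    gl = derived.get("glucose")
    if gl is not None and len(gl):
        fig, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(len(gl))
        ax.vlines(x, gl["min"], gl["max"], color="0.7", lw=6, label="range")
        ax.errorbar(
            x,
            gl["mean"],
            yerr=[gl["mean"] - gl["ci95_low"], gl["ci95_high"] - gl["mean"]],
            fmt="o",
            color="C3",
            capsize=4,
            label="mean ± 95% CI",
        )
        for ref in GLUCOSE_REFERENCE_MG_DL:
            ax.axhline(ref, ls=":", color="0.4", lw=0.8)
        ax.set_xticks(x, gl["subject_id"])
        ax.set_ylabel("glucose (mg/dl)")
        ax.set_title("Daily glucose measurements by subject")
        ax.legend()
        files += _save(fig, outdir / "study_glucose_ranges", formats)
    else:
        log.warning("glucose summary missing; skipping glucose panel")

    # 3. dose summary split by slot
    ms = derived.get("missed")
    if ms is not None and len(ms):
        fig, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(len(ms))
        ax.bar(x - 0.2, ms["doses_taken"], width=0.38, label="taken")
        morn = [
            row["doses_missed"] * row["missed_fraction_by_slot"].get("morning", 0.0)
            for _, row in ms.iterrows()
        ]
        ax.bar(x + 0.2, ms["doses_missed"], width=0.38, label="missed (evening)", color="C3")
        ax.bar(x + 0.2, morn, width=0.38, label="missed (morning)", color="C1")
        ax.set_xticks(x, ms["subject_id"])
        ax.set_ylabel("doses")
        ax.set_title("Dose summary for the whole trial")
        ax.legend()
        files += _save(fig, outdir / "study_dose_summary", formats)
    else:
        log.warning("missed-dose summary missing; skipping dose panel")

    # 4. ingestion time-of-day distributions
    hists = derived.get("ingestion_hists")
    if hists:
        fig, axes = plt.subplots(len(hists), 1, figsize=(7, 1.8 * len(hists)), sharex=True)
        axes = np.atleast_1d(axes)
        for ax, (subject, per_slot) in zip(axes, hists.items()):
            for slot, h in per_slot.items():
                centers = (h["bin_edges_h"][:-1] + h["bin_edges_h"][1:]) / 2
                ax.bar(centers, h["fraction"], width=np.diff(h["bin_edges_h"]), alpha=0.6, label=slot)
            ax.set_ylabel(subject)
            ax.legend(fontsize=7)
        axes[-1].set_xlabel("time of day (h)")
        fig.suptitle("Fraction of medication ingested vs time of day")
        files += _save(fig, outdir / "study_ingestion_times", formats)
    else:
        log.warning("ingestion histograms missing; skipping timing panel")

    # 5. sleep and wake time distributions
    prof = derived.get("profiles")
    if prof is not None and len(prof):
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        for subject, grp in prof.groupby("subject_id"):
            wake_h = _clock_hours(grp["wake_time"])
            bed_h = _clock_hours(grp["bed_time"])
            axes[0].hist(wake_h, bins=np.arange(0, 24.5, 0.5), histtype="step", label=subject)
            axes[1].hist(bed_h, bins=np.arange(0, 24.5, 0.5), histtype="step", label=subject)
        axes[0].set_title("wake times")
        axes[1].set_title("bed times")
        for ax in axes:
            ax.set_xlabel("time of day (h)")
        axes[0].legend(fontsize=7)
        fig.suptitle("Estimated sleep and wake time distributions")
        files += _save(fig, outdir / "study_sleep_wake_times", formats)
    else:
        log.warning("sleep profiles missing; skipping sleep/wake panel")

    # 6. wake-relative morning self-management
    pat = derived.get("patterns")
    if pat is not None and len(pat):
        fig, ax = plt.subplots(figsize=(7, 4))
        for subject, grp in pat.groupby("subject_id"):
            ax.scatter(
                grp["study_day"], grp["first_glucose_offset_h"], marker="s", s=14, label=f"{subject} glucose"
            )
            ax.scatter(
                grp["study_day"], grp["morning_ingestion_offset_h"], marker="^", s=14, label=f"{subject} dose"
            )
        ax.set_xlabel("study day")
        ax.set_ylabel("hours after waking")
        ax.set_title("Morning glucose tests and dose ingestion after waking")
        ax.legend(fontsize=6, ncols=2)
        files += _save(fig, outdir / "study_morning_selfmgmt", formats)
    else:
        log.warning("morning patterns missing; skipping self-management panel")

    # 7. sustained HR elevation vs daily steps
    phys = derived.get("physio")
    if phys is not None and len(phys):
        fig, ax = plt.subplots(figsize=(7, 4))
        for subject, grp in phys.groupby("subject_id"):
            ax.scatter(grp["step_count"], grp["hr_elevation"], s=12, label=subject)
        ax.set_xlabel("daily step count")
        ax.set_ylabel("sustained HR elevation from rest (bpm)")
        ax.set_title("Heart-rate elevation vs daily step count")
        ax.legend(fontsize=7)
        files += _save(fig, outdir / "study_hr_elevation_vs_steps", formats)
    else:
        log.warning("physio table missing; skipping fitness panel")

    return files


def _clock_hours(ts: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(ts.dropna())
    if not len(ts):
        return np.array([])
    return ((ts - ts.dt.normalize()).dt.total_seconds() / 3600.0).to_numpy()


def _day_panel(
    ax,
    record,
    states: pd.Series,
    slots: pd.DataFrame,
    day: int,
    no_data: bool,
) -> None:
    """Draw one 24-h stripe: activity, 0/100 sleep state, doses, glucose."""
    d0 = record.day_start(day)
    d1 = d0 + pd.Timedelta(days=1)

    def hours(t):
        return (t - d0).total_seconds() / 3600.0 if not isinstance(t, pd.Series) else (
            (t - d0).dt.total_seconds() / 3600.0
        )

    act = record.activity
    act = act[(act["at"] >= d0) & (act["at"] < d1)]
    if len(act):
        ax.plot(hours(act["at"]), act["steps"], color="0.6", lw=0.6, label="activity")
    st = states[(states.index >= d0) & (states.index < d1)]
    if len(st):
        ax.step(hours(pd.Series(st.index)), st.to_numpy(), where="post", color="C0", lw=1.2, label="sleep/rest")
    day_slots = slots[(slots["study_day"] == day) & slots["taken"]]
    extra = record.ingestions[
        (record.ingestions["at"] >= d0) & (record.ingestions["at"] < d1)
    ]
    for t in extra["at"]:
        ax.axvline(hours(t), color="C3", lw=1.0, alpha=0.8)
    for _, srow in day_slots.iterrows():
        ax.plot(hours(srow["ingestion_at"]), 104, marker="v", color="C3", ms=7, clip_on=False)
    gl = record.glucose
    gl = gl[(gl["at"] >= d0) & (gl["at"] < d1)]
    ax2 = ax.twinx()
    if len(gl):
        ax2.plot(hours(gl["at"]), gl["mg_dl"], "D", color="C2", ms=5)
        for _, grow in gl.iterrows():
            ax2.annotate(
                f"{grow['mg_dl']:.0f}",
                (hours(grow["at"]), grow["mg_dl"]),
                fontsize=6,
                xytext=(0, 4),
                textcoords="offset points",
                ha="center",
            )
    ax2.set_ylim(0, 400)
    ax2.set_ylabel("glucose (mg/dl)", fontsize=7)
    ax.set_xlim(0, 24)
    ax.set_ylim(-5, 110)
    if no_data:
        ax.text(12, 55, "no patch data", ha="center", va="center", fontsize=14, color="C3", alpha=0.6)


def plot_daily(
    record,
    states: pd.Series,
    slots: pd.DataFrame,
    day: int,
    outdir: str | Path,
    qc: pd.DataFrame | None = None,
    formats=("png",),
) -> list[Path]:
    """One midnight-to-midnight multi-stream panel for a single day."""
    if not (1 <= day <= record.participation_days):
        raise ValueError(f"day {day} outside participation (1-{record.participation_days})")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    no_data = False
    if qc is not None:
        row = qc[qc["study_day"] == day]
        no_data = bool(len(row)) and int(row["activity_event_count"].iloc[0]) == 0
    fig, ax = plt.subplots(figsize=(9, 3))
    _day_panel(ax, record, states, slots, day, no_data)
    ax.set_xlabel("time of day (h)")
    ax.set_ylabel("steps / sleep state")
    ax.set_title(f"{record.subject_id} day {day}: medication, sleep/rest, activity, glucose")
    return _save(fig, outdir / f"daily_{record.subject_id}_day{day:02d}", formats)


def plot_weekly(
    record,
    states: pd.Series,
    slots: pd.DataFrame,
    start_day: int,
    outdir: str | Path,
    qc: pd.DataFrame | None = None,
    formats=("png",),
) -> list[Path]:
    """Seven consecutive daily stripes (truncated final week allowed)."""
    if start_day < 1 or start_day > record.participation_days:
        raise ValueError(f"start_day {start_day} outside participation")
    days = range(start_day, min(start_day + 7, record.participation_days + 1))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(len(days), 1, figsize=(9, 1.7 * len(days)), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, day in zip(axes, days):
        no_data = False
        if qc is not None:
            row = qc[qc["study_day"] == day]
            no_data = bool(len(row)) and int(row["activity_event_count"].iloc[0]) == 0
        _day_panel(ax, record, states, slots, day, no_data)
        ax.set_ylabel(f"day {day}", fontsize=7)
    axes[-1].set_xlabel("time of day (h)")
    fig.suptitle(f"{record.subject_id} days {days.start}-{days.stop - 1}")
    return _save(
        fig, outdir / f"weekly_{record.subject_id}_day{days.start:02d}", formats
    )
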
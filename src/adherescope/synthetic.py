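"""Synthetic multi-stream cohort generator with ground-truth labels.

The generator emulates the structure of an ingestion-sensor study of
twice-daily oral medication: five subjects wearing a torso patch (activity
and posture every 5 minutes, pulse every 10 minutes) for 37-42 days, with a
wireless glucometer and time-stamped ingestion detections.  Each subject is
described by a :class:`PhenotypeConfig`; three named presets (``consistent``,
``erratic``, ``evening_missing``) reproduce the qualitative behavioural
contrasts the analysis is designed to surface.

Sleep is emitted *implicitly* — as runs of low activity, recumbent posture
and near-resting pulse — so that the sleep/wake derivation stage is
genuinely exercised rather than handed an explicit sleep stream.
Dose-taking on day ``d`` can be coupled to the previous day's rest through a
logistic model::

    logit p(take) = logit(p_slot) + coupling_beta * (rest_hours[d-1] - mean_rest)

with ``coupling_beta = 0`` giving the null of no sleep-adherence relation.
Every draw is taken from a single :func:`numpy.random.default_rng` stream,
so output is bit-identical under a fixed seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from datetime import time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .core import (
    ACTIVITY_EPOCHS_PER_DAY,
    DosingRegimen,
    SubjectRecord,
    bool_runs,
    parse_clock,
)

EPOCH_MIN = 5
EPOCHS_PER_DAY = ACTIVITY_EPOCHS_PER_DAY  # 288 five-minute epochs
DEFAULT_START = pd.Timestamp("2015-01-05")  # arbitrary fixed Monday


class PhenotypeConfig(BaseModel):
    """Generative parameters for one synthetic subject.

    Durations are minutes unless the field name says hours; clock fields
    accept ``"HH:MM"`` strings.  ``coupling_beta`` is the log-odds increment
    of next-day dose-taking per hour of prior-day rest above the subject's
    mean rest.
    """

    subject_id: str = "S1"
    # dose-taking behaviour
    p_take_morning: float = Field(0.9, ge=0.0, le=1.0)
    p_take_evening: float = Field(0.85, ge=0.0, le=1.0)
    timing_jitter_sd: float = Field(45.0, ge=0.0)  # minutes
    scheduled_times: tuple[str, str] = ("08:00", "20:00")
    extra_dose_prob: float = Field(0.0, ge=0.0, le=1.0)
    coupling_beta: float = 0.0
    # sleep schedule
    sleep_onset_mean: str = "23:00"
    sleep_onset_sd: float = Field(45.0, ge=0.0)  # minutes
    sleep_duration_mean_h: float = Field(7.5, gt=0.0)
    sleep_duration_sd_h: float = Field(1.0, ge=0.0)
    disturbance_rate: float = Field(1.0, ge=0.0)  # Poisson mean per night
    disturbance_len: tuple[float, float] = (10.0, 40.0)  # minutes
    # activity / heart rate
    activity_base: float = Field(20.0, gt=0.0)  # mean steps per awake epoch
    exercise_bout_prob: float = Field(0.4, ge=0.0, le=1.0)
    exercise_steps: float = Field(150.0, ge=0.0)  # extra steps per bout epoch
    exercise_len: tuple[float, float] = (30.0, 60.0)  # minutes
    resting_hr: float = Field(62.0, ge=35.0, le=100.0)
    hr_slope: float = Field(0.15, ge=0.0)  # bpm per (steps/epoch)
    hr_noise_sd: float = Field(3.0, ge=0.0)
    # glucose self-testing
    glucose_mean: float = Field(140.0, gt=0.0)
    glucose_sd: float = Field(25.0, ge=0.0)
    p_morning_test: float = Field(0.9, ge=0.0, le=1.0)
    tests_per_day_mean: float = Field(1.5, ge=0.0)
    # patch wear
    patch_dropout_day_prob: float = Field(0.02, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("disturbance_len", "exercise_len")
    @classmethod
    def _ordered_range(cls, v):
        lo, hi = v
        if not (0 < lo <= hi):
            raise ValueError("duration range must satisfy 0 < lo <= hi")
        return (float(lo), float(hi))

    @model_validator(mode="after")
    def _check_clocks(self):
        parse_clock(self.sleep_onset_mean)
        for t in self.scheduled_times:
            parse_clock(t)
        return self

    def regimen(self) -> DosingRegimen:
        return DosingRegimen(scheduled_times=tuple(parse_clock(t) for t in self.scheduled_times))


@dataclass
class GroundTruth:
    """Per-day and per-slot generative truth used as a recovery oracle.

    ``days`` columns: study_day, bed_time, wake_time, rest_hours,
    disturbances, dropout, daily_steps.  ``slots`` columns: study_day,
    slot, scheduled_at, taken, ingestion_at, delay_min.
    """

    days: pd.DataFrame
    slots: pd.DataFrame


def _clock_offset_seconds(clock: str | time) -> float:
    t = parse_clock(clock)
    s = t.hour * 3600 + t.minute * 60 + t.second
    # onsets nominally before noon are read as "after midnight"
    return s + 86400.0 if t.hour < 12 else float(s)


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def simulate_subject(
    cfg: PhenotypeConfig,
    n_days: int,
    start: pd.Timestamp = DEFAULT_START,
) -> tuple[SubjectRecord, GroundTruth]:
    """Simulate one subject's streams and the matching ground truth.

    Nights are indexed by the day they wake into: the night producing the
    wake on study day ``d`` starts on the evening of day ``d-1`` (the first
    night's pre-start portion is truncated at the study start).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    cfg = PhenotypeConfig.model_validate(cfg)  # hard error before generation
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(start).normalize()
    end = start + pd.Timedelta(days=n_days)
    n_epochs = n_days * EPOCHS_PER_DAY
    grid = start + pd.to_timedelta(np.arange(n_epochs) * EPOCH_MIN, unit="m")

    # ---- sleep blocks (one per night d-1 -> d, for wake days 1..n_days) ----
    onset_base = _clock_offset_seconds(cfg.sleep_onset_mean)
    onset_off = onset_base + rng.normal(0.0, cfg.sleep_onset_sd * 60.0, n_days)
    dur_h = np.clip(
        rng.normal(cfg.sleep_duration_mean_h, cfg.sleep_duration_sd_h, n_days), 3.0, 13.0
    )
    # seconds from study start: night for wake-day d (1-based) begins on day d-2
    night_day0 = np.arange(n_days) - 1  # day index of the evening of each night
    onset_s = night_day0 * 86400.0 + onset_off
    wake_s = onset_s + dur_h * 3600.0
    # keep blocks ordered: a block may not start before the previous wake
    for i in range(1, n_days):
        onset_s[i] = max(onset_s[i], wake_s[i - 1] + 2 * 3600.0)
        wake_s[i] = max(wake_s[i], onset_s[i] + 3 * 3600.0)
    wake_s = np.minimum(wake_s, (np.arange(n_days) + 1) * 86400.0 - 3600.0)

    asleep = np.zeros(n_epochs, dtype=bool)
    disturbed = np.zeros(n_epochs, dtype=bool)
    truth_dist = np.zeros(n_days, dtype=int)
    for d in range(n_days):
        e0 = max(0, int(np.ceil(onset_s[d] / (EPOCH_MIN * 60))))
        e1 = min(n_epochs, int(np.floor(wake_s[d] / (EPOCH_MIN * 60))))
        if e1 <= e0:
            continue
        asleep[e0:e1] = True
        # nocturnal disturbances: contiguous wake-like runs strictly inside
        n_dist = rng.poisson(cfg.disturbance_rate)
        occupied = np.zeros(e1 - e0, dtype=bool)
        placed = 0
        for _ in range(n_dist):
            length = int(
                np.ceil(rng.uniform(cfg.disturbance_len[0], cfg.disturbance_len[1]) / EPOCH_MIN)
            )
            if e1 - e0 - 2 <= length:
                continue
            s = int(rng.integers(1, e1 - e0 - length))
            if occupied[max(0, s - 1) : s + length + 1].any():
                continue
            occupied[s : s + length] = True
            disturbed[e0 + s : e0 + s + length] = True
            placed += 1
        # attributed to the wake day iff wholly inside the 22:00 -> 08:00 window
        win0 = (d - 1) * 86400.0 + 22 * 3600.0
        win1 = d * 86400.0 + 8 * 3600.0
        if placed:
            runs = bool_runs(occupied)
            for rs, re_ in runs:
                t0 = (e0 + rs) * EPOCH_MIN * 60.0
                t1 = (e0 + re_) * EPOCH_MIN * 60.0
                if t0 >= win0 and t1 <= win1:
                    truth_dist[d] += 1
    rest = asleep & ~disturbed

    day_idx = np.arange(n_epochs) // EPOCHS_PER_DAY  # 0-based study day per epoch
    rest_hours = np.bincount(day_idx, weights=rest.astype(float), minlength=n_days) * (
        EPOCH_MIN / 60.0
    )

    # ---- activity, posture, pulse ----
    steps = np.where(
        rest,
        rng.poisson(0.1, n_epochs),
        rng.poisson(cfg.activity_base, n_epochs),
    )
    steps[disturbed] = rng.poisson(8.0, int(disturbed.sum()))
    for d in range(n_days):
        if rng.random() < cfg.exercise_bout_prob:
            lo = d * EPOCHS_PER_DAY + 8 * 12  # 08:00
            hi = d * EPOCHS_PER_DAY + 19 * 12  # 19:00
            awake_idx = np.flatnonzero(~asleep[lo:hi]) + lo
            if len(awake_idx) == 0:
                continue
            length = int(
                np.ceil(rng.uniform(cfg.exercise_len[0], cfg.exercise_len[1]) / EPOCH_MIN)
            )
            s = int(rng.choice(awake_idx))
            e = min(s + length, (d + 1) * EPOCHS_PER_DAY)
            steps[s:e] += rng.poisson(cfg.exercise_steps, e - s)

    posture = np.where(rest, "recumbent", "upright").astype(object)
    awake_mask = ~rest
    r = rng.random(n_epochs)
    posture[awake_mask & ~disturbed & (r < 0.05)] = "other"
    posture[awake_mask & ~disturbed & (r >= 0.05) & (r < 0.07)] = "recumbent"

    steps_10 = steps.reshape(-1, 2).mean(axis=1)  # mean steps/epoch per 10-min slot
    rest_10 = rest.reshape(-1, 2).all(axis=1)
    n_pulse = len(steps_10)
    bpm = cfg.resting_hr + cfg.hr_slope * steps_10 + rng.normal(0, cfg.hr_noise_sd, n_pulse)
    bpm[rest_10] = cfg.resting_hr + rng.normal(0, 0.7 * cfg.hr_noise_sd, int(rest_10.sum()))
    bpm = np.clip(np.round(bpm), 30, 220)
    pulse_grid = start + pd.to_timedelta(np.arange(n_pulse) * 10, unit="m")

    # ---- patch dropout days (whole-day loss of activity/posture/pulse) ----
    dropout = rng.random(n_days) < cfg.patch_dropout_day_prob
    keep5 = ~dropout[day_idx]
    keep10 = ~dropout[np.arange(n_pulse) // (EPOCHS_PER_DAY // 2)]

    # ---- dose-taking with optional coupling to prior-day rest ----
    regimen = cfg.regimen()
    slot_labels = regimen.slot_labels
    base_logit = {"morning": _logit(cfg.p_take_morning), "evening": _logit(cfg.p_take_evening)}
    # centre the coupling on the realized mean rest so p_take_* keeps its
    # meaning as the marginal take probability
    rest_dev = np.concatenate([[0.0], rest_hours[:-1] - rest_hours.mean()])
    slot_rows = []
    ingestion_times: list[pd.Timestamp] = []
    missed_delay_min = regimen.missed_delay / timedelta(minutes=1)
    for d in range(n_days):
        for slot, clock in zip(slot_labels, regimen.scheduled_times):
            scheduled = start + pd.Timedelta(days=d) + pd.Timedelta(
                hours=clock.hour, minutes=clock.minute
            )
            logit_p = base_logit.get(slot, _logit(cfg.p_take_morning)) + cfg.coupling_beta * rest_dev[d]
            p = 1.0 / (1.0 + np.exp(-logit_p))
            taken = bool(rng.random() < p)
            delay = float(rng.normal(0.0, cfg.timing_jitter_sd)) if taken else np.nan
            if taken and abs(delay) > missed_delay_min:
                taken = False  # drawn delay beyond the missed-dose rule -> miss
                delay = np.nan
            when = scheduled + pd.Timedelta(minutes=delay) if taken else pd.NaT
            if taken and not (start <= when < end):
                taken, delay, when = False, np.nan, pd.NaT
            slot_rows.append(
                {
                    "study_day": d + 1,
                    "slot": slot,
                    "scheduled_at": scheduled,
                    "taken": taken,
                    "ingestion_at": when,
                    "delay_min": delay,
                }
            )
            if taken:
                ingestion_times.append(when.floor("s"))
                if rng.random() < cfg.extra_dose_prob:
                    dup = when + pd.Timedelta(minutes=float(rng.uniform(2, 10)))
                    if dup < end:
                        ingestion_times.append(dup.floor("s"))

    # ---- glucose self-tests ----
    glucose_times: list[pd.Timestamp] = []
    for d in range(n_days):
        day0 = start + pd.Timedelta(days=d)
        if rng.random() < cfg.p_morning_test:
            t = wake_s[d] + rng.exponential(45 * 60.0)
            ts = start + pd.Timedelta(seconds=float(t))
            if day0 <= ts < min(day0 + pd.Timedelta(days=1), end):
                glucose_times.append(ts.floor("min"))
        for _ in range(rng.poisson(max(cfg.tests_per_day_mean - cfg.p_morning_test, 0.0))):
            ts = day0 + pd.Timedelta(hours=float(rng.uniform(12, 22)))
            if ts < end:
                glucose_times.append(ts.floor("min"))
    glucose_times.sort()
    glucose_vals = np.clip(
        np.round(rng.normal(cfg.glucose_mean, cfg.glucose_sd, len(glucose_times))), 40, 500
    )

    streams = {
        "ingestions": pd.DataFrame({"at": pd.to_datetime(sorted(ingestion_times))}),
        "activity": pd.DataFrame({"at": grid[keep5], "steps": steps[keep5]}),
        "posture": pd.DataFrame({"at": grid[keep5], "posture": posture[keep5]}),
        "pulse": pd.DataFrame({"at": pulse_grid[keep10], "bpm": bpm[keep10]}),
        "glucose": pd.DataFrame(
            {"at": pd.to_datetime(glucose_times), "mg_dl": glucose_vals}
        ),
    }
    record = SubjectRecord(
        subject_id=cfg.subject_id,
        start=start,
        participation_days=n_days,
        regimen=regimen,
        streams=streams,
    )

    daily_steps = np.bincount(day_idx, weights=steps.astype(float), minlength=n_days)
    truth_days = pd.DataFrame(
        {
            "study_day": np.arange(1, n_days + 1),
            "bed_time": start + pd.to_timedelta(onset_s, unit="s"),
            "wake_time": start + pd.to_timedelta(wake_s, unit="s"),
            "rest_hours": rest_hours,
            "disturbances": truth_dist,
            "dropout": dropout,
            "daily_steps": daily_steps.astype(int),
        }
    )
    truth = GroundTruth(days=truth_days, slots=pd.DataFrame(slot_rows))
    return record, truth


def simulate_cohort(
    cfgs: Sequence[PhenotypeConfig],
    n_days: Sequence[int],
    master_seed: int | None = None,
    start: pd.Timestamp = DEFAULT_START,
) -> list[tuple[SubjectRecord, GroundTruth]]:
    """Simulate several subjects; per-subject seed = master seed + index."""
    ids = [c.subject_id for c in cfgs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate subject_ids in cohort: {ids}")
    if len(cfgs) != len(n_days):
        raise ValueError("one n_days entry required per config")
    out = []
    for i, (cfg, days) in enumerate(zip(cfgs, n_days)):
        if master_seed is not None:
            cfg = cfg.model_copy(update={"seed": master_seed + i})
        out.append(simulate_subject(cfg, days, start=start))
    return out


# ---------------------------------------------------------------------------
# model-implied statistics


def analytic_lagged_r(cfg: PhenotypeConfig, n_nodes: int = 120) -> float:
    """Model-implied Pearson r between day-d rest and day-(d+1) dose count.

    Under the generative model, rest hours R are (approximately) normal
    with the configured sleep-duration mean and SD, and next-day doses are
    two Bernoulli draws with ``logit p = logit(p_slot) + beta (R - mu)``.
    The correlation of R with the dose count Y = B_m + B_e follows by
    Gauss-Hermite integration over R.  The expression is exact when
    disturbances, dropout, and duration clipping are off; it is the
    benchmark the lagged-correlation recovery is measured against.
    """
    mu, sd = cfg.sleep_duration_mean_h, cfg.sleep_duration_sd_h
    if sd <= 0:
        raise ValueError("sleep_duration_sd_h must be positive for a defined r")
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    r_vals = mu + np.sqrt(2.0) * sd * nodes
    w = weights / np.sqrt(np.pi)
    dev = r_vals - mu
    p_m = 1.0 / (1.0 + np.exp(-(_logit(cfg.p_take_morning) + cfg.coupling_beta * dev)))
    p_e = 1.0 / (1.0 + np.exp(-(_logit(cfg.p_take_evening) + cfg.coupling_beta * dev)))
    ey_given_r = p_m + p_e
    vy_given_r = p_m * (1 - p_m) + p_e * (1 - p_e)
    ey = float(np.sum(w * ey_given_r))
    cov = float(np.sum(w * dev * ey_given_r))
    var_y = float(np.sum(w * vy_given_r) + np.sum(w * (ey_given_r - ey) ** 2))
    return cov / (sd * np.sqrt(var_y))


def coupling_beta_for_r(
    target_r: float, cfg: PhenotypeConfig, beta_bracket: tuple[float, float] = (0.0, 5.0)
) -> float:
    """Coupling strength whose model-implied lagged r equals ``target_r``."""
    from scipy.optimize import brentq

    def f(beta: float) -> float:
        probe = cfg.model_copy(update={"coupling_beta": beta})
        return analytic_lagged_r(probe) - target_r

    return float(brentq(f, *beta_bracket, xtol=1e-6))


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("consistent", "erratic", "evening_missing")


def load_preset(name: str, **overrides) -> PhenotypeConfig:
    """Load a named phenotype preset shipped with the package."""
    name = name.replace("-", "_")
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = (
        importlib.resources.files("adherescope").joinpath(f"presets/{name}.yaml").read_text()
    )
    params = yaml.safe_load(text)
    params.update(overrides)
    return PhenotypeConfig.model_validate(params)


def default_cohort_configs(master_seed: int = 0) -> tuple[list[PhenotypeConfig], list[int]]:
    """The five-subject study cohort: 197 subject-days split (42,37,40,40,38).

    Subjects mirror the behavioural phenotypes the analysis contrasts:
    S1 moderate, S2 erratic (sleep-coupled), S3 consistent, S4
    evening-missing, S5 moderate with wide activity range.
    """
    text = importlib.resources.files("adherescope").joinpath("presets/cohort.yaml").read_text()
    spec = yaml.safe_load(text)
    cfgs, days = [], []
    for i, entry in enumerate(spec["subjects"]):
        base = load_preset(entry["preset"]) if "preset" in entry else PhenotypeConfig()
        params = base.model_dump()
        params.update(entry.get("overrides", {}))
        params["subject_id"] = entry["subject_id"]
        params["seed"] = master_seed + i
        cfgs.append(PhenotypeConfig.model_validate(params))
        days.append(int(entry["days"]))
    return cfgs, days
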
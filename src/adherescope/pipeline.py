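"""End-to-end orchestration: simulate/load -> QC -> derive -> correlate -> plot.

``run_report`` composes every analysis stage for a cohort and writes the
full set of derived tables (slots, adherence summary, sleep profiles,
daily physiology, morning patterns, correlations), the figure families,
and a ``manifest.json`` capturing parameters, seed, and package version so
a rerun with the same manifest reproduces the derived CSVs bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adherence import (
    ingestion_time_histogram,
    missed_dose_summary,
    slots_for_record,
    summarize_adherence,
)
from .core import SubjectRecord
from .correlation import METRICS, build_lagged_pairs, cohort_correlation_report
from .physio import daily_physio, elevation_vs_steps
from .qc import cohort_wear_summary, daily_activity_counts, exclusion_mask
from .selfmgmt import glucose_summary, morning_patterns
from .sleep import SleepParams, sleep_profile_for_record
from .streams_io import read_cohort
from .synthetic import (
    GroundTruth,
    default_cohort_configs,
    load_preset,
    simulate_cohort,
    simulate_subject,
)
from .viz import plot_daily, plot_study_summary, plot_weekly

log = logging.getLogger(__name__)


@dataclass
class SubjectDerived:
    """Everything the analysis derives for one subject."""

    record: SubjectRecord
    qc: pd.DataFrame
    slots: pd.DataFrame
    surplus: pd.DataFrame
    summary: dict
    profiles: pd.DataFrame
    smoothed: "object"  # RestStateSeries
    raw: "object"
    physio: pd.DataFrame
    resting_hr: float
    resting_hr_fallback: bool
    patterns: pd.DataFrame
    truth: GroundTruth | None = None


def derive_subject(
    record: SubjectRecord,
    sleep_params: SleepParams = SleepParams(),
    truth: GroundTruth | None = None,
) -> SubjectDerived:
    """Run the full per-subject derivation chain."""
    qc = daily_activity_counts(record)
    slots, surplus = slots_for_record(record)
    summary = summarize_adherence(slots, surplus)
    profiles, smoothed, raw = sleep_profile_for_record(record, sleep_params)
    physio, rhr, fallback = daily_physio(record, smoothed)
    patterns = morning_patterns(profiles, slots, record.glucose, subject_id=record.subject_id)
    return SubjectDerived(
        record=record,
        qc=qc,
        slots=slots,
        surplus=surplus,
        summary=summary,
        profiles=profiles,
        smoothed=smoothed,
        raw=raw,
        physio=physio,
        resting_hr=rhr,
        resting_hr_fallback=fallback,
        patterns=patterns,
        truth=truth,
    )


@dataclass
class RunConfig:
    """Configuration of one reproducible report run.

    Exactly one of ``input_dir`` (a directory of subject folders) or
    ``preset`` (a simulation preset name, or ``cohort`` for the five-subject
    study cohort) must be given.
    """

    out_dir: Path
    input_dir: Path | None = None
    preset: str | None = None
    n_days: int = 40
    seed: int = 0
    sleep_params: SleepParams = field(default_factory=SleepParams)
    binary_response: bool = False
    make_figures: bool = True

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.preset is None):
            raise ValueError("exactly one of input_dir or preset must be given")


def _load_cohort(cfg: RunConfig) -> list[tuple[SubjectRecord, GroundTruth | None]]:
    if cfg.input_dir is not None:
        return [(r, None) for r in read_cohort(cfg.input_dir)]
    if cfg.preset == "cohort":
        cfgs, days = default_cohort_configs(master_seed=cfg.seed)
        return list(simulate_cohort(cfgs, days, master_seed=cfg.seed))
    pheno = load_preset(cfg.preset, seed=cfg.seed)
    return [simulate_subject(pheno, cfg.n_days)]


def run_report(cfg: RunConfig) -> Path:
    """Execute the pipeline end to end and write the report directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = _load_cohort(cfg)
    log.info("pipeline: %d subjects loaded", len(cohort))

    derived = [derive_subject(rec, cfg.sleep_params, truth) for rec, truth in cohort]
    log.info("pipeline: per-subject derivation complete")

    slots_all = pd.concat([d.slots for d in derived], ignore_index=True)
    slots_all.to_csv(out / "slots.csv", index=False)
    pd.DataFrame([d.summary for d in derived]).to_csv(out / "summary.csv", index=False)
    qc_all = pd.concat([d.qc for d in derived], ignore_index=True)
    qc_all.to_csv(out / "qc.csv", index=False)
    cohort_wear_summary([d.qc for d in derived]).to_csv(out / "wear_summary.csv", index=False)
    pd.concat([d.profiles for d in derived], ignore_index=True).to_csv(
        out / "sleep_profiles.csv", index=False
    )
    pd.concat([d.physio for d in derived], ignore_index=True).to_csv(
        out / "physio_daily.csv", index=False
    )
    pd.concat([d.patterns for d in derived], ignore_index=True).to_csv(
        out / "morning_patterns.csv", index=False
    )

    excluded = exclusion_mask(qc_all)
    per_subject = {
        d.record.subject_id: {
            metric: build_lagged_pairs(
                d.profiles, d.slots, excluded, metric, cfg.binary_response
            )
            for metric in METRICS
        }
        for d in derived
    }
    correlations = cohort_correlation_report(per_subject)
    correlations.to_csv(out / "correlations.csv", index=False)
    log.info("pipeline: correlations computed for %d subjects", len(derived))

    if cfg.make_figures:
        figdir = out / "figures"
        study_tables = {
            "adherence": pd.DataFrame([d.summary for d in derived]),
            "glucose": pd.DataFrame(
                [
                    {"subject_id": d.record.subject_id, **glucose_summary(d.record.glucose)}
                    for d in derived
                    if len(d.record.glucose)
                ]
            ),
            "missed": pd.DataFrame(
                [
                    {"subject_id": d.record.subject_id, **missed_dose_summary(d.slots)}
                    for d in derived
                ]
            ),
            "ingestion_hists": {
                d.record.subject_id: ingestion_time_histogram(d.slots) for d in derived
            },
            "profiles": pd.concat([d.profiles for d in derived], ignore_index=True),
            "patterns": pd.concat([d.patterns for d in derived], ignore_index=True),
            "physio": pd.concat([d.physio for d in derived], ignore_index=True),
        }
        plot_study_summary(study_tables, figdir)
        for d in derived:
            plot_daily(d.record, d.smoothed.states, d.slots, day=1, outdir=figdir, qc=d.qc)
            plot_weekly(d.record, d.smoothed.states, d.slots, start_day=1, outdir=figdir, qc=d.qc)
        log.info("pipeline: figures written to %s", figdir)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "preset": cfg.preset,
        "input_dir": str(cfg.input_dir) if cfg.input_dir else None,
        "n_days": cfg.n_days,
        "sleep_params": {
            "act_thresh": cfg.sleep_params.act_thresh,
            "hr_margin": cfg.sleep_params.hr_margin,
            "min_gap_rest_min": cfg.sleep_params.min_gap_rest_min,
            "min_gap_wake_min": cfg.sleep_params.min_gap_wake_min,
            "disturbance_min_min": cfg.sleep_params.disturbance_min_min,
        },
        "binary_response": cfg.binary_response,
        "subjects": [d.record.subject_id for d in derived],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def fitness_slopes(derived: list[SubjectDerived]) -> pd.DataFrame:
    """Per-subject elevation-vs-steps slopes (qualitative fitness contrast)."""
    rows = []
    for d in derived:
        try:
            fit = elevation_vs_steps(d.physio)
            rows.append(
                {
                    "subject_id": d.record.subject_id,
                    "slope_bpm_per_step": fit["slope"],
                    "n_days": len(fit["points"]),
                }
            )
        except ValueError as err:
            rows.append(
                {"subject_id": d.record.subject_id, "slope_bpm_per_step": np.nan, "n_days": 0}
            )
            log.warning("fitness slope unavailable for %s: %s", d.record.subject_id, err)
    return pd.DataFrame(rows)
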
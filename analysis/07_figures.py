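"""Render the three visualization families for the simulated cohort.

Whole-study summary panels (adherence bars, glucose ranges, dose summary,
ingestion-time and sleep/wake-time distributions, wake-relative
self-management, HR elevation vs steps), one sample daily 24-h panel per
subject, and one sample weekly panel per subject.

Input:  results/cohort/        Output: results/figures/
"""

import sys
from pathlib import Path

import pandas as pd

from adherescope.adherence import ingestion_time_histogram, missed_dose_summary
from adherescope.pipeline import derive_subject
from adherescope.selfmgmt import glucose_summary
from adherescope.streams_io import read_cohort
from adherescope.viz import plot_daily, plot_study_summary, plot_weekly

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    derived = [derive_subject(r) for r in read_cohort(ROOT / "cohort")]
    outdir = ROOT / "figures"
    tables = {
        "adherence": pd.DataFrame([d.summary for d in derived]),
        "glucose": pd.DataFrame(
            [
                {"subject_id": d.record.subject_id, **glucose_summary(d.record.glucose)}
                for d in derived
                if len(d.record.glucose)
            ]
        ),
        "missed": pd.DataFrame(
            [{"subject_id": d.record.subject_id, **missed_dose_summary(d.slots)} for d in derived]
        ),
        "ingestion_hists": {
            d.record.subject_id: ingestion_time_histogram(d.slots) for d in derived
        },
        "profiles": pd.concat([d.profiles for d in derived], ignore_index=True),
        "patterns": pd.concat([d.patterns for d in derived], ignore_index=True),
        "physio": pd.concat([d.physio for d in derived], ignore_index=True),
    }
    files = plot_study_summary(tables, outdir)
    for d in derived:
        files += plot_daily(d.record, d.smoothed.states, d.slots, 9, outdir, d.qc)
        files += plot_weekly(d.record, d.smoothed.states, d.slots, 14, outdir, d.qc)
    print(f"{len(files)} figures written to {outdir}")


if __name__ == "__main__":
    sys.exit(main())
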
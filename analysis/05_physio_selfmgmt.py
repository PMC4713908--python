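"""Daily physiology and morning self-management patterns.

Computes daily step counts, per-subject resting heart rate, sustained
heart-rate elevation vs steps (with the least-squares slope used to
contrast cardiovascular fitness), glucose descriptive statistics, and the
wake-relative offsets of the first glucose test and morning dose.

Input:  results/cohort/
Output: results/physio_daily.csv, results/fitness_slopes.csv,
        results/morning_patterns.csv, results/glucose_summary.csv
"""

import sys
from pathlib import Path

import pandas as pd

from adherescope.pipeline import derive_subject, fitness_slopes
from adherescope.selfmgmt import glucose_dose_timing_correlation, glucose_summary
from adherescope.streams_io import read_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    derived = [derive_subject(r) for r in read_cohort(ROOT / "cohort")]

    pd.concat([d.physio for d in derived], ignore_index=True).to_csv(
        ROOT / "physio_daily.csv", index=False
    )
    slopes = fitness_slopes(derived)
    slopes.to_csv(ROOT / "fitness_slopes.csv", index=False)

    glu = pd.DataFrame(
        [
            {"subject_id": d.record.subject_id, **glucose_summary(d.record.glucose)}
            for d in derived
            if len(d.record.glucose)
        ]
    )
    glu.to_csv(ROOT / "glucose_summary.csv", index=False)

    patterns = pd.concat([d.patterns for d in derived], ignore_index=True)
    patterns.to_csv(ROOT / "morning_patterns.csv", index=False)

    for d in derived:
        pat = d.patterns.dropna(
            subset=["first_glucose_offset_h", "morning_ingestion_offset_h"]
        )
        line = (
            f"{d.record.subject_id}: resting HR {d.resting_hr:.1f} bpm, "
            f"mean steps {d.physio['step_count'].mean():.0f}/day"
        )
        if len(pat) >= 3:
            res = glucose_dose_timing_correlation(pat)
            line += f", glucose-dose timing r={res.r:.3f} (p={res.p:.3g}, n={res.n})"
        print(line)
    print(slopes.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
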
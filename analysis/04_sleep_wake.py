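"""Derive sleep/rest state, daily wake/bed times, and nocturnal disturbances.

Classifies each 5-minute epoch as rest (low activity + recumbent posture +
near-resting pulse), smooths transient interruptions under the
single-daily-waking assumptions, and extracts per-day wake time, bedtime,
total rest hours, and disturbance counts in the 22:00-08:00 window.

Input:  results/cohort/       Output: results/sleep_profiles.csv
"""

import sys
from pathlib import Path

import pandas as pd

from adherescope.sleep import sleep_profile_for_record
from adherescope.streams_io import read_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tables = []
    for record in read_cohort(ROOT / "cohort"):
        profiles, _, _ = sleep_profile_for_record(record)
        tables.append(profiles)
        ok = profiles[profiles["derivable"]]
        wake_clock = ok["wake_time"].dropna()
        spread = (
            (wake_clock - wake_clock.dt.normalize()).dt.total_seconds().std() / 3600.0
            if len(wake_clock) > 1
            else float("nan")
        )
        print(
            f"{record.subject_id}: mean rest {ok['rest_hours'].mean():.1f} h, "
            f"mean disturbances {ok['disturbances'].mean():.2f}/night, "
            f"wake-time spread {spread:.2f} h"
        )
    pd.concat(tables, ignore_index=True).to_csv(ROOT / "sleep_profiles.csv", index=False)


if __name__ == "__main__":
    sys.exit(main())
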
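"""The headline lagged analysis: nightly sleep vs next-day dose-taking.

For each subject, Pearson r between (a) total rest hours on day d and
doses taken on day d+1, and (b) nocturnal disturbances in the night
ending on day d+1's morning and doses taken that day.  Days without full
patch function are excluded pairwise.  Only the erratic phenotype (S2)
carries true sleep-adherence coupling; with ten uncorrected per-subject
tests an occasional false flag at P<.05 is expected (the Holm-adjusted
column in the output distinguishes the two).  A fully adherent subject has
a constant response and its correlation is reported undefined, with the
reason.

Input:  results/cohort/, results/qc.csv     Output: results/correlations.csv
"""

import sys
from pathlib import Path

import pandas as pd

from adherescope.adherence import slots_for_record
from adherescope.correlation import METRICS, build_lagged_pairs, cohort_correlation_report
from adherescope.sleep import sleep_profile_for_record
from adherescope.streams_io import read_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    qc = pd.read_csv(ROOT / "qc.csv")
    excluded = set(zip(qc.loc[~qc["full_function"], "subject_id"],
                       qc.loc[~qc["full_function"], "study_day"]))
    per_subject = {}
    for record in read_cohort(ROOT / "cohort"):
        profiles, _, _ = sleep_profile_for_record(record)
        slots, _ = slots_for_record(record)
        per_subject[record.subject_id] = {
            m: build_lagged_pairs(profiles, slots, excluded, m) for m in METRICS
        }
    table = cohort_correlation_report(per_subject)
    table.to_csv(ROOT / "correlations.csv", index=False)
    show = table[["subject_id", "metric", "r", "p", "n_pairs", "significant"]].copy()
    show[["r", "p"]] = show[["r", "p"]].round(3)
    print(show.to_string(index=False))
    flagged = table.loc[table["significant"], "subject_id"].unique()
    print(f"subjects flagged at P<.05: {', '.join(flagged) if len(flagged) else 'none'}")


if __name__ == "__main__":
    sys.exit(main())
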
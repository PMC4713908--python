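"""Simulate the five-subject study cohort and write it to disk.

Generates 197 subject-days of multi-stream data (activity/posture every
5 minutes, pulse every 10 minutes, twice-daily dose ingestions, glucose
self-tests) for five behavioural phenotypes — one consistent, one erratic
and sleep-coupled, one evening-missing, two moderate — and stores each
subject as a CSV directory plus its generative ground truth.

Output: results/cohort/<subject_id>/ and results/cohort_manifest.json
"""

import json
import sys
from pathlib import Path

from adherescope.streams_io import write_subject
from adherescope.synthetic import default_cohort_configs, simulate_cohort

SEED = 20150105
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cfgs, days = default_cohort_configs(master_seed=SEED)
    cohort = simulate_cohort(cfgs, days, master_seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    for record, truth in cohort:
        sub = OUT / record.subject_id
        write_subject(record, sub)
        truth.days.to_csv(sub / "truth_days.csv", index=False)
        truth.slots.to_csv(sub / "truth_slots.csv", index=False)
        print(
            f"{record.subject_id}: {record.participation_days} days, "
            f"{len(record.ingestions)} ingestions, "
            f"{len(record.activity)} activity samples"
        )
    manifest = {
        "seed": SEED,
        "subjects": {r.subject_id: r.participation_days for r, _ in cohort},
        "total_subject_days": sum(days),
    }
    (OUT.parent / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"total subject-days: {sum(days)} -> {OUT}")


if __name__ == "__main__":
    sys.exit(main())
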
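# adherescope

Analysis pipeline for **ingestion-sensor ("digital pill") medication
adherence studies** in chronic disease, where an edible sensor time-stamps
every actual medication ingestion while a torso patch records activity and
posture every 5 minutes and pulse every 10 minutes, and a wireless
glucometer logs self-tests. The package is aimed at biostatisticians and
digital-health researchers who need the full chain from raw per-subject
event streams to adherence metrics, derived sleep/rest structure, lagged
behavioural correlations, and multi-stream timeline visualizations — plus
a synthetic-cohort simulator with ground-truth labels so every stage can be
validated without access to patient data.

## What it computes

For a twice-daily regimen with scheduled times *t₁, t₂*, detected
ingestions are matched one-to-one to prescribed dose slots (minimum total
|delay|, with a delay > 12 h scored as a missed dose), giving

- **taking adherence** = 100 · (assigned detections) / (doses prescribed),
- **timing adherence** = 100 · (assigned detections with |delay| ≤ 2 h) /
  (assigned detections),

the missed-dose split by slot, and per-slot ingestion time-of-day
distributions. From the three patch streams a binary **sleep/rest state**
(awake = 0, asleep = 100 per 5-min epoch) is derived — rest requires
activity ≤ 5 steps/epoch, recumbent posture, and pulse within 10 bpm of
the subject's resting rate — then smoothed under the assumptions that each
day has a single main waking event and that short interruptions of long
rest (or short rests in long wake) are transient. This yields daily wake
time, bedtime, total rest hours, and the count of nocturnal disturbances
(wake runs ≥ 10 min inside rest between 22:00 and 08:00). The headline
analysis is the **lagged Pearson correlation** per subject between a daily
sleep metric (rest hours of day *d*, or disturbances of the night ending
on day *d+1*) and the number of doses taken on day *d+1*, with
p = two-sided t-test on *t = r·√((n−2)/(1−r²))* and days without full
patch function (≠ 288 activity events) excluded pairwise. Supporting
analyses cover daily steps, resting heart rate, sustained (30-min window)
heart-rate elevation vs step count, glucose descriptive statistics, and
wake-relative morning self-management offsets.

## Worked example

Simulate a 5-subject cohort (197 subject-days) and run the analyses:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_patch_qc.py
python analysis/03_adherence.py
python analysis/06_sleep_adherence_correlation.py
```

`03_adherence.py` prints the per-subject adherence table:

```
subject_id  taking_pct  timing_pct  n_surplus  evening_miss_fraction
        S1        82.1        87.0          0                    0.7
        S2        54.1        57.5          0                    0.6
        S3       100.0       100.0          0                    NaN
        S4        72.5        94.8          0                    1.0
        S5        82.9        71.4          0                    0.5
cohort means: taking 78.3% (SD 16.8), timing 82.1% (SD 17.5)
```

S3 is the consistent phenotype (no misses, so its evening-miss fraction is
undefined), S2 the erratic one, and S4 misses almost exclusively in the
evening. `06_sleep_adherence_correlation.py` then prints the per-subject
lagged correlations:

```
subject_id       metric      r     p  n_pairs  significant
        S2   rest_hours  0.502 0.002       36         True
        S4 disturbances  0.412 0.011       37         True
        ...
subjects flagged at P<.05: S2, S4
```

Only S2 was generated with true sleep-adherence coupling; its rest-hours
correlation is recovered (r ≈ 0.5). The S4 flag is an uncorrected false
positive — with ten per-subject tests at α = .05 roughly one false flag
per two cohorts is expected, which the Holm-adjusted column in
`results/correlations.csv` removes. S3's correlation is undefined
(constant response) and reported with the reason.

The same stages are available as a CLI (`adherescope simulate|qc|
adherence|sleep|physio|selfmgmt|correlate|plot|report`); `adherescope
report --preset cohort --out DIR` runs everything end to end and writes a
manifest for bit-identical reruns.

## Data layout

Each subject is a directory of UTF-8 CSVs with ISO-8601 local timestamps —
`ingestions.csv` (timestamp), `activity.csv` (timestamp,steps),
`posture.csv` (timestamp,posture ∈ upright/recumbent/other), `pulse.csv`
(timestamp,bpm), `glucose.csv` (timestamp,mg_dl) — plus `subject.yaml`:

```yaml
subject_id: S3
start_date: "2015-01-05"
participation_days: 40
regimen:
  scheduled_times: ["08:00", "20:00"]
  window_halfwidth_min: 120
  missed_delay_min: 720
```

Reading validates plausibility bounds (pulse 20–250 bpm, glucose
20–600 mg/dl) row by row and reports rejected line numbers;
`write_subject` / `read_subject` round-trip records exactly.

See `docs/methods.md` for the model details, parameter defaults, and known
limitations of the synthetic cohort.
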
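# Five-subject study cohort, 197 subject-days in total.
# The per-subject day counts (42, 37, 40, 40, 38) are a chosen decomposition
# of the 197 total within the reported 37-42 day range.
subjects:
  - subject_id: S1
    days: 42
    overrides:
      p_take_morning: 0.85
      p_take_evening: 0.77
      timing_jitter_sd: 90.0
      activity_base: 16.0
      exercise_bout_prob: 0.2
      resting_hr: 68.0
      hr_slope: 0.28
      glucose_mean: 160.0
  - subject_id: S2
    preset: erratic
    days: 37
  - subject_id: S3
    preset: consistent
    days: 40
  - subject_id: S4
    preset: evening_missing
    days: 40
  - subject_id: S5
    days: 38
    overrides:
      p_take_morning: 0.88
      p_take_evening: 0.84
      timing_jitter_sd: 110.0
      activity_base: 22.0
      exercise_bout_prob: 0.45
      exercise_steps: 200.0
      resting_hr: 60.0
      hr_slope: 0.05   # atenolol-like blunted heart-rate response
      glucose_mean: 150.0
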
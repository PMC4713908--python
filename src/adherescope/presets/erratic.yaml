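# Erratic phenotype: wide ingestion-time range, no repeated pattern,
# fragmented and variable sleep, occasional duplicate doses, low activity,
# elevated glucose.  Dose-taking is coupled to the previous night's rest.
subject_id: erratic
p_take_morning: 0.60
p_take_evening: 0.52
timing_jitter_sd: 170.0
extra_dose_prob: 0.06
coupling_beta: 0.45
sleep_onset_mean: "00:30"
sleep_onset_sd: 140.0
sleep_duration_mean_h: 6.3
sleep_duration_sd_h: 1.8
disturbance_rate: 2.5
activity_base: 18.0
exercise_bout_prob: 0.15
exercise_steps: 120.0
resting_hr: 70.0
hr_slope: 0.30
glucose_mean: 196.0
glucose_sd: 30.0
p_morning_test: 0.75
tests_per_day_mean: 2.2
patch_dropout_day_prob: 0.05
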
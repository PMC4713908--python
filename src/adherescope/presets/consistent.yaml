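# Highly adherent phenotype: tight ingestion timing, regular sleep,
# frequent vigorous exercise (~8-12k steps/day), well-controlled glucose.
subject_id: consistent
p_take_morning: 0.99
p_take_evening: 0.95
timing_jitter_sd: 20.0
extra_dose_prob: 0.0
coupling_beta: 0.0
sleep_onset_mean: "22:45"
sleep_onset_sd: 20.0
sleep_duration_mean_h: 7.3
sleep_duration_sd_h: 0.5
disturbance_rate: 0.3
activity_base: 35.0
exercise_bout_prob: 0.8
exercise_steps: 250.0
exercise_len: [40.0, 70.0]
resting_hr: 58.0
hr_slope: 0.12
glucose_mean: 128.0
glucose_sd: 12.0
p_morning_test: 0.97
tests_per_day_mean: 2.0
patch_dropout_day_prob: 0.01
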
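# Morning-reliable phenotype: doses taken promptly on waking, but evening
# doses frequently missed; regular activity, sparse glucose testing.
subject_id: evening_missing
p_take_morning: 0.95
p_take_evening: 0.58
timing_jitter_sd: 45.0
extra_dose_prob: 0.0
coupling_beta: 0.0
sleep_onset_mean: "23:15"
sleep_onset_sd: 50.0
sleep_duration_mean_h: 7.0
sleep_duration_sd_h: 1.1
disturbance_rate: 1.2
activity_base: 30.0
exercise_bout_prob: 0.6
exercise_steps: 220.0
resting_hr: 64.0
hr_slope: 0.14
glucose_mean: 182.0
glucose_sd: 26.0
p_morning_test: 0.55
tests_per_day_mean: 0.8
patch_dropout_day_prob: 0.02
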
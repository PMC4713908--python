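# Methods

## Setting and data model

The pipeline targets studies in which an edible sensor co-ingested with
each medication dose is detected by a torso-worn patch, giving exact
date-time stamps of actual ingestions alongside dense physiology: step
activity and posture every 5 minutes (288 epochs/day), pulse every
10 minutes (144 samples/day, ≈720 patch events/day in total), and
glucometer self-tests with level in mg/dl. All timestamps are
subject-local wall clock (single-site assumption); the day boundary is
local midnight and study days are numbered from 1.

## Dose-slot scoring

A twice-daily regimen defines two slot instances per day (defaults 08:00
and 20:00, configurable — prescribed clock times are study-specific).
Detected ingestions are matched to slots one-to-one by a
maximum-cardinality, minimum-total-|delay| assignment (Hungarian
algorithm) restricted to |delay| ≤ 12 h, with ties broken toward the
earlier slot. A slot with no assigned detection within 12 h is a missed
dose; an assigned detection within ±2 h (boundary inclusive) counts
toward timing adherence. We use an optimal matching rather than a greedy
nearest-slot sweep because greedy is not cardinality-optimal: with slots
at 08:00/20:00 and ingestions at 19:59 and 20:01, greedy pairs 19:59 with
20:00 and strands 20:01 beyond the 12-h horizon of 08:00, scoring one
taken dose where two are attainable. Optimal matching makes the
taken-dose count a well-defined quantity independent of scan order, and
surplus detections (duplicate tablets, extra doses) are reported
separately so taking adherence cannot exceed 100%.

## Sleep/rest derivation

An epoch is classified as rest iff activity ≤ `act_thresh` (default
5 steps/epoch), posture is recumbent, and pulse ≤ resting + `hr_margin`
(default 10 bpm), where the classification resting rate is bootstrapped
as the 5th percentile of the subject's pulse (this breaks the circularity
with the physiology module, whose resting rate is the mean pulse over
derived rest epochs). Pulse is forward-filled up to 10 minutes onto the
5-minute grid; activity and posture snap to the nearest epoch. Missing
epochs inherit the consensus of their neighbours when both agree, but
only across gaps ≤ 30 minutes — longer outages (whole patch-dropout
days) default to awake, otherwise the two nights flanking a missing day
merge into one implausible rest block. Days with under 50% input
coverage are marked underivable.

Smoothing applies two ordered single passes: wake runs shorter than
`min_gap_rest` (30 min) flanked by rest become rest; then rest runs
shorter than `min_gap_wake` (60 min) flanked by wake become wake. Runs
touching the series ends are never relabelled. These durations are
declared, tunable stand-ins — the derivation's inputs and assumptions
(single daily waking event; short interruptions are transient) are fixed
by the analysis design, but no canonical thresholds exist.

Per day: wake time is the end of the longest rest block intersecting
(00:00, 12:00] (ties → earliest block), bedtime that block's start
(possibly before midnight), rest hours the total rest within the calendar
day. Nocturnal disturbances are wake runs ≥ `disturbance_min` (10 min)
strictly inside rest spans and wholly within the 22:00–08:00 window,
attributed to the morning's day — and they are counted on the raw
classification, not the smoothed series, because smoothing exists
precisely to erase sub-30-minute interruptions. Requiring containment in
the window (not mere intersection) prevents the daytime wake span, which
is also flanked by rest on both sides, from counting as one giant
disturbance.

## Lagged sleep–adherence analysis

For each subject, pairs (predictor, response) are formed per day *d*:
rest hours of day *d* — or disturbances of the night *d → d+1* — against
the number of doses taken on day *d+1* (0–2; a binary variant is
available). A pair is kept only if both days have full patch function
(exactly 288 activity events; a stricter-than-288 count is configurable)
and derivable sleep. Pearson r with a two-sided t-test (n−2 df) is
reported per subject, uncorrected — matching per-subject exploratory
practice — with a Holm-adjusted column appended as a labelled extension.
At least 3 pairs and non-zero variance on both sides are required;
otherwise the correlation is reported undefined with the reason (a fully
adherent subject has a constant response).

## Physiology and self-management

Daily steps are the per-calendar-day sum of epoch counts (assumed
per-epoch increments, not cumulative). Sustained heart-rate elevation is
the per-day maximum over 30-minute sliding windows of the window-mean
pulse minus the individual resting rate, floored at 0; "sustained" as a
window mean is our operationalisation, with the window configurable. The
elevation-vs-steps relationship is summarised as a least-squares slope
plus the paired points — a qualitative fitness contrast, not a fitness
score. Morning self-management offsets are hours after the derived wake
of the first glucose test before noon and of the morning-slot ingestion;
events up to 1 h before the derived wake are clipped to 0 and flagged
(classification granularity). Glucose summaries report mean, min, max and
a normal-approximation 95% CI of the mean (not a prediction interval).

## Synthetic cohort

The generator emulates a five-subject, 37–42-day study (197 subject-days
by default, split 42/37/40/40/38). Per subject and night it draws a sleep
onset (clock-time mean ± SD), a duration (mean ± SD, clipped to 3–13 h),
and a Poisson number of nocturnal disturbances — contiguous wake-like
runs of 10–40 min carved strictly inside the block, emitted as upright
posture with moderate activity. Sleep is emitted *implicitly* (low
activity, recumbent, near-resting pulse) so the derivation stage is
genuinely exercised. Awake epochs draw Poisson step counts around
`activity_base` with optional exercise bouts; pulse is resting + slope ×
steps + noise awake and resting + reduced noise asleep, rounded to whole
bpm. Whole days lose their patch streams with probability
`patch_dropout_day_prob`. Dose-taking per slot is Bernoulli with

    logit p = logit(p_slot) + coupling_beta · (rest_hours[d−1] − mean rest)

centred on the subject's realized mean rest so `p_slot` stays the
marginal take probability; a taken dose is stamped at scheduled +
N(0, jitter), converted to a miss if the drawn delay exceeds 12 h.
Glucose tests occur shortly after waking with probability
`p_morning_test` plus Poisson extras in the afternoon/evening. Per-subject
seeds are master seed + subject index; everything is bit-reproducible.

Three presets encode the behavioural phenotypes the analysis is designed
to contrast: `consistent` (tight timing, regular sleep, ~10k steps/day),
`erratic` (wide timing range, fragmented variable sleep, duplicate doses,
sleep-coupled taking, elevated glucose), and `evening_missing` (reliable
mornings, frequent evening misses). Preset parameters were chosen once to
place cohort-level summaries in the ballpark reported for studies of this
design (taking ≈ high-70s %, wear ≥ 90%) and to order the phenotypes'
adherence; they are conditions of the simulation, not fitted quantities.

**What the generator does not model:** pharmacokinetic glucose response
to medication, circadian heart-rate rhythm beyond the activity link,
realistic glucometer usage bursts, coupling between glucose-test timing
and dose timing, within-day patch dropout, and posture-sensor noise
during sleep. Passing recovery tests therefore shows the analysis chain
is correct under the stated generative assumptions — not that it is
robust to every failure mode of real wearables data.

## Model-implied lagged correlation

For recovery testing, the generator exposes its model-implied Pearson r
between day-*d* rest and day-(*d+1*) dose count: with R ~ N(μ, σ²) and
Y | R the sum of two Bernoullis with logistic dependence on R − μ,

    r = E[(R−μ)(p_m+p_e)] / (σ · √(E[Var(Y|R)] + Var(E[Y|R])))

evaluated by Gauss–Hermite quadrature. The expression is exact when
onset jitter, disturbances and dropout are off (then calendar-day rest
equals the drawn duration); with onset jitter on, calendar-day rest gains
variance from the pre-midnight head of the following night and the
realized correlation exceeds the closed form — a property of calendar-day
accounting worth knowing when interpreting such analyses. Recovery runs
use the exact regime; the measured attenuation of the full pipeline
(classification + smoothing + QC) relative to the model value is a few
hundredths of r.

## Numerical and scale choices

Recovery statistics are computed at sizes that keep the full suite in the
single-digit minutes: 200 replicates of 40-day subjects for lagged-r
recovery, 400 for type-I calibration, ~100 subject-days for wake-time
error, exhaustive enumeration up to 12 epochs (smoothing) and 6 slots /
10 ingestions (assignment) for oracle equivalence. Timestamps are stored
at second resolution; ingestion stamps are floored to the second, so
recovered delays agree with the generative truth to 1/60 min. Percentages
are reported on the 0–100 scale. Degenerate inputs (zero prescribed
doses, constant correlation inputs, < 3 pairs, empty glucose) raise or
report explicit "undefined, with reason" values rather than NaNs leaking
through.

## Known limitations

- Wake-time derivation assumes one main waking event; genuinely biphasic
  sleepers get the longest morning-intersecting block's end, which can
  jump between fragments on heavily disturbed days (median error is
  epoch-scale, the tail is not).
- The disturbance count is floor-limited by the 10-min minimum and the
  5-min epoch grid; sub-epoch awakenings are invisible.
- Taking-adherence assignment is optimal at the subject level, so a
  surplus tablet may be credited to an adjacent unfilled slot within 12 h;
  with a 0–2 daily response this is the intended reading of "doses taken".
- Per-subject uncorrected P-values at α = .05 produce ≈ 0.5 false flags
  per 10-test cohort table by construction; the Holm column is the guard.
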
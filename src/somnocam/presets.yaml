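# Calibration presets for the synthetic cohort generator.
#
# Stage proportions are stationary targets per age group, shaped to the
# qualitative contrast seen in pediatric simple-PSG cohorts: REM is more
# common in 0-2 year-olds, Light is roughly half of sleep in both groups,
# Deep is somewhat below the ~30% of clinical adult PSG.  Stickiness is the
# per-epoch probability mass kept on the current stage (sleep stages persist
# for minutes).  time_inhomogeneity is a logit shift moving Deep earlier and
# REM later in the night; it is kept mild so that elapsed time alone never
# outweighs the Light plurality.
#
# Movement magnitudes are in ROI pixel counts per 0.5 s sample.  They are
# calibration choices, not measurements: Wake large and frequent, Light
# frequent, REM less frequent than Light, Deep nearly absent.
hypnogram:
  group_0_2:
    stage_proportions: {Wake: 0.07, Light: 0.45, Deep: 0.18, REM: 0.30}
    stickiness: 0.85
    time_inhomogeneity: 0.3
  group_3_6:
    stage_proportions: {Wake: 0.07, Light: 0.51, Deep: 0.22, REM: 0.20}
    stickiness: 0.85
    time_inhomogeneity: 0.3

movement:
  noise_floor: 3.0
  stages:
    Wake: {event_rate: 8.0, magnitude_mean: 1200.0, magnitude_dispersion: 0.5, duration: 4}
    Light: {event_rate: 4.0, magnitude_mean: 500.0, magnitude_dispersion: 0.5, duration: 3}
    REM: {event_rate: 1.5, magnitude_mean: 350.0, magnitude_dispersion: 0.5, duration: 3}
    Deep: {event_rate: 0.1, magnitude_mean: 150.0, magnitude_dispersion: 0.5, duration: 2}

blob:
  width: 8
  height: 8
  background: 20
  foreground: 220
  stages:
    Wake: {jump_prob: 0.6, step: 12}
    Light: {jump_prob: 0.35, step: 6}
    REM: {jump_prob: 0.15, step: 6}
    Deep: {jump_prob: 0.0, step: 0}
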
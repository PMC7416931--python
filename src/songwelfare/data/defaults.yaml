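# Default study configuration.
#
# Generator values encode the cohort statistics of isolated adult male
# zebra finches: a stable baseline of 2818 +/- 1183 motifs/day with an
# empirical floor of 629, a day-0 isolation level of 746 motifs rising to
# baseline with a ~3-day time constant, and per-manipulation day-1 post/pre
# effect ratios (surgery 54 +/- 34 %, pooled tethering 22 +/- 43 %,
# interactive white noise 1.01 +/- 0.29, i.e. no effect).  Tethering
# recovery relaxes toward full baseline (target ratio 2.64 of the suppressed
# pre-tethering level, ~1430 motifs/day expected after five days of
# tethering); surgery recovery reaches an expected 91 % of the pre-surgery
# rate on post-day 10.

seed: 20260101

generator:
  baseline_mean: 2818.0
  baseline_sd: 1183.0
  baseline_floor: 629.0
  bird_level_variance_fraction: 0.7
  adaptation_day0_mean: 746.0
  adaptation_tau: 3.0
  fp_rate: 0.01
  feature_mean: 3000.0   # Hz, targeted harmonic-syllable pitch
  feature_sd: 60.0       # Hz
  outlier_rate: 0.002
  wn_hit_rate: 0.5       # thresholds re-tuned daily for ~50 % hit rate

effects:
  surgery:                 {ratio_mean: 0.54, ratio_sd: 0.34, recovery_tau: 5.52, recovery_target_ratio: 1.0}
  tethering:               {ratio_mean: 0.22, ratio_sd: 0.43, recovery_tau: 8.05, recovery_target_ratio: 2.64}
  wn:                      {ratio_mean: 1.01, ratio_sd: 0.29, recovery_tau: 2.0,  recovery_target_ratio: 1.0}
  tethering_weight:        {ratio_mean: 0.55, ratio_sd: 0.79, recovery_tau: 8.05, recovery_target_ratio: 2.64}
  tethering_microdrive:    {ratio_mean: 0.05, ratio_sd: 0.08, recovery_tau: 8.05, recovery_target_ratio: 2.64}
  tethering_stim:          {ratio_mean: 0.55, ratio_sd: 0.79, recovery_tau: 8.05, recovery_target_ratio: 2.64}
  tethering_cage_transfer: {ratio_mean: 0.01, ratio_sd: 0.02, recovery_tau: 8.05, recovery_target_ratio: 2.64}

# Cohort sizes follow the study groups (19 unmanipulated, 26 white-noise,
# 12 surgery, 17 tethering events pooled over four sub-groups).
scenarios:
  baseline:                {n_birds: 19}
  isolation:               {n_birds: 6}
  white_noise:             {n_birds: 26}
  surgery:                 {n_birds: 12}
  tethering:               {n_birds: 17}
  tethering_weight:        {n_birds: 4}
  tethering_microdrive:    {n_birds: 5}
  tethering_stim:          {n_birds: 8}
  tethering_cage_transfer: {n_birds: 3}

thresholds:
  confidences: [95.0, 99.0, 99.5]
  n_boot_birds: 100000
  days_per_bird: 10

posterior:
  i_min: 0
  i_max: 4
  include_zero_bin: true

recovery:
  threshold_confidence: 99.0
  max_days: 8
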
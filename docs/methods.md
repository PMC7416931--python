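# Methods

## The measurement and the monitoring problem

The observable is the number of undirected song motifs a singly housed male
zebra finch produces per light phase (14 h lights-on within a 14/10
schedule; a "day" is one lights-on window, keyed by the calendar date of
lights-on, and dark-phase detections join the light phase that most
recently started). Counts come from a syllable detector whose output is a
per-rendition log; detections with a feature value (pitch or duration) more
than 5 reference standard deviations from the targeted syllable's mean are
rejected as false positives (strictly greater than 5 sd rejected, exactly
5 sd retained), non-target labels are dropped, and the retained target
renditions are summed per day. False negatives are not corrected.

Unstressed isolated males sing at a high, stable rate with a sharply
bounded lower tail; stressors (surgery, tethering) transiently suppress the
rate. The package estimates (a) percentile thresholds of the unstressed
rate distribution and (b) the posterior probability that a recent stressor
occurred given today's rate.

## Synthetic cohort model

No per-bird day counts are published, so the generator encodes the printed
summary statistics and the pipeline is validated by parameter recovery:
estimators applied to synthetic cohorts must return the configured values
within Monte-Carlo error.

**Baseline days.** Fully adapted daily counts are lognormal, moment-matched
to mean 2818 and sd 1183 motifs/day, resampled until ≥ the empirical floor
of 629 (the floor binds rarely — under 1% of draws for typical birds — so
the cohort mean is essentially unaffected). Counts are rounded to the
nearest integer after all multiplicative effects.

**Between- vs within-bird variance.** The printed statistics do not
decompose the variance, so the lognormal's log-variance is split by a free
parameter `bird_level_variance_fraction` (default 0.7) into a stable
per-bird multiplicative level and residual within-bird day noise. The
default reflects that individual birds differ strongly in level while each
bird's rate is described as reliable day to day; it is a choice, not a
measured quantity.

**Isolation adaptation.** The expected count rises as a saturating
exponential from the bird's scaled day-0 level (mean 746 motifs, a partial
recording) toward its baseline with time constant `adaptation_tau` = 3.0
days, which places the expected day-13 count (~2791) within a few percent
of the printed 2906. Day 0 is flagged `partial_day` and realized as a
uniform random fraction of twice the day-0 level (expectation preserved,
variance large, matching the wide printed day-0 spread); partial days are
excluded from baseline statistics, adaptation fits, and recovery-curve
denominators.

**Manipulation effects.** Each manipulation kind carries an `EffectSpec`
(day-1 post/pre ratio mean and sd, recovery time constant, recovery
target). Per bird, one ratio R is drawn from a normal truncated at zero
whose location is calibrated (Brent root-finding) so the truncated mean
equals `ratio_mean`; the expected first-full-day post/pre ratio therefore
equals the configured value exactly, which is what makes parameter recovery
at 3 MC SE on thousands of birds feasible. The per-bird expected ratio then
relaxes as r(d) = target − (target − R)·e^(−d/τ), anchored at the first
full post-event day (surgery's onset day is a partial recording; tethering's
day 0 is the full first 24 h). Post-event counts are generated relative to
the bird's *realized* pre-event mean — the same basis against which the
effect ratios were measured — with fresh multiplicative day noise; this
keeps the measured post/pre ratio an unbiased estimator of r(d) (dividing a
latent-level-based count by a noisy realized pre-mean would inflate it by
E[1/X̄] ≈ 1 + σ²/n).

Defaults: surgery 0.54 ± 0.34 with τ = 5.52 d and target 1.0, so the
expected day-10 ratio is 0.91; pooled tethering 0.22 ± 0.43 with target
2.64 and τ = 8.05 d, so the expected day-5 level is ~1430 motifs;
white noise 1.01 ± 0.29 (no effect). Tethering scenarios additionally scale
the pre-tethering level by the group's printed 24-h-pre mean relative to
baseline (pooled 1069/2818 ≈ 0.38), because tethered birds were measured
shortly after surgery or weight attachment and their recovery proceeds
toward full baseline, not toward that suppressed pre-level. Without this
burden the near-universal day-0 threshold crossing of tethered birds cannot
be reproduced at realistic absolute counts.

**Rendition logs.** A timeline expands into per-rendition events: exactly
`motif_count` in-range target renditions per day (features truncated within
5 sd of `feature_mean` = 3000 Hz, sd 60 Hz — a plausible harmonic-syllable
pitch scale), plus planted outlier renditions at odds `outlier_rate`
(default 0.002, |z| > 5) and non-target contaminants at odds `fp_rate`
(default 0.01, the printed upper bound on false positives). Filtering at
5 sd and re-aggregating therefore reproduces the timeline exactly — a
conservation law the tests rely on. White-noise cohorts trigger noise per
rendition with probability `wn_hit_rate` (default 0.5, the daily
re-thresholding aim). Partial-day structure is not recoverable from a log
alone; aggregation marks no partial days and callers supply that flag.

What the generator does *not* emulate: circadian structure within the light
phase (timestamps are uniform), serial correlation of counts across days
beyond the bird level, seasonal or age trends, bout structure, and any
acoustic content. Passing tests therefore validate the estimators'
bookkeeping and calibration, not these features of real data.

## Welfare thresholds

`bootstrap_thresholds` draws `n_boot_birds` (default 100 000) birds with
replacement, then `days_per_bird` (default 10) days with replacement within
each drawn bird, and takes W_x as the (100 − x)th percentile of the single
pooled resample. Nearest-rank percentiles (no interpolation) are used since
no interpolation rule is prescribed; pooling (rather than per-replicate
percentiles) matches the procedure's singular percentile computation, and a
per-replicate variant is a possible extension. The pooled percentile
converges to the exact inverse CDF of the bird-balanced mixture (each bird
weight 1/B split over its days), which the tests enumerate exactly on small
datasets. "Below threshold" is strict (<): a count equal to W_x does not
flag. Recovery curves report, per day since onset, the fraction of birds
with a full-day count strictly below W_x, excluding birds without data that
day from the denominator and recording n per point.

## Posterior of a recent manipulation

Likelihoods are empirical bin frequencies (no smoothing by default; an
optional pseudocount flag exists for downstream use), the prior is the
sample proportion of manipulation days, and the posterior follows Bayes'
formula per bin — which, with these ingredients, collapses algebraically to
the within-bin manipulation-day fraction n₁/(n₁+n₀); the tests verify the
formula against that direct count. Bins are half-open [10^i, 10^{i+1});
values at or above the top edge fall in the last bin; a leading [0, 1) bin
is included by default because manipulated birds can sing zero motifs
(strict log-only binning via `include_zero_bin=False`). A bin empty in both
conditions yields NaN, an explicit undefined marker.

## Cohort statistics

- Paired pre/post comparisons use the classical paired two-tailed t-test
  (scipy), plus the mean per-bird post/pre ratio as effect size. A zero
  difference vector is reported as t = 0, p = 1 (the 0/0 statistic is
  defined away as "no evidence of change").
- The per-bird-minima comparison uses the two-sided Wilcoxon rank-sum test:
  exact enumeration for combined n ≤ 12 without ties, normal approximation
  with continuity correction otherwise.
- Day-span matching between groups redraws a random subset of target day
  counts, randomly assigns them to distinct pool birds, and resamples that
  many days without replacement per bird, retrying infeasible assignments
  up to 10⁴ times (then raising) — the retry cap is a safeguard the
  original description leaves open.
- The adaptation fit is a 3-parameter least-squares saturating exponential
  (plateau, day-0 level, τ), day 0 excluded. τ is bounded by the observed
  span and the level parameters by twice the observed maximum: with τ free,
  the model degenerates into a straight line and the plateau becomes pure
  extrapolation (occasional 10⁵-scale plateaus on noisy 20-day series).
- The feature-shift classification z-scores the post-exposure mean against
  the pre-exposure distribution, z = (x̄_post − x̄_pre)/(s_pre/√n_post), at
  the two-sided 1% critical value, signed by the escape direction. The
  original criterion's exact reference distribution is not fully specified;
  this is a standard z-test reconstruction.

## Determinism and numerics

Every stochastic stage takes an explicit seed. Cohorts spawn one
`SeedSequence` child per bird by index, so cohorts are bit-identical for a
given (scenario, n_birds, seed) and stable under per-bird parallelism. The
pipeline fans a single top-level seed into named per-stage seeds (recorded
in the manifest) so stages can be rerun in isolation; reruns are
bit-identical and the config digest changes iff any configuration value
changes. Floor resampling is capped at 1000 attempts before clamping;
truncated-normal location calibration uses Brent's method to 1e-12.

## Problem sizes

The shipped default run uses the study-scale cohorts (19 baseline, 26
white-noise, 12 surgery, 17 pooled tethering plus the four sub-groups,
100 000 bootstrap birds) and completes in seconds. The parameter-recovery
experiments use 500 replicate cohorts (≈6000–8500 simulated birds per
quantity) for effect ratios and 200 replicate 19-bird cohorts (64 600
bird-days) for the baseline grand mean; these sizes put the Monte-Carlo
standard error well below the effects being recovered.

## Known limitations

- The generator's variance split and the tethering recovery target/τ are
  calibrated choices constrained by printed summaries, not fitted to data.
- Thresholds computed from a 19-bird synthetic draw vary noticeably between
  seeds (W_99 roughly 1000–1300), as expected for a 1st-percentile estimate
  from 19 birds; the printed empirical thresholds depend on the unpublished
  sample and are not reproduction targets.
- The truncated-normal effect model is thin-tailed; real post-tethering
  ratios are strongly right-skewed (range up to ~1.7 with mean 0.22), so
  tail-sensitive statistics of effect ratios should not be over-interpreted.
- The middle posterior bin's value depends entirely on how much baseline
  mass falls in [100, 1000); with the default generator that mass is near
  zero, so the synthetic posterior there is typically 1 or undefined.
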
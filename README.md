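# songwelfare

Quantitative welfare monitoring for singly housed male zebra finches from
their singing rate alone.

Isolated adult males sing hundreds to thousands of undirected song motifs
per day at a remarkably stable rate. Stressful procedures — brain surgery,
tethering to a commutator — transiently suppress that rate, while a benign
acoustic manipulation (interactive white noise) does not. Because the
baseline is high and its lower tail is sharply bounded, a low daily motif
count is strong evidence that a stressor occurred recently. `songwelfare`
turns this into two practical monitors:

1. **Welfare thresholds W_x.** From baseline day counts of unmanipulated
   birds, a hierarchical bootstrap (birds with replacement, then days with
   replacement within each drawn bird) estimates the singing rate exceeded
   on x% of unstressed bird-days. A day strictly below W_x flags a putative
   stressor with a false-alarm rate of (100 − x)%:

   W_x = Q_{(100−x)/100} of the pooled bootstrap resample (nearest rank).

2. **Posterior probability of a recent manipulation.** With a binary
   indicator m (1 = recent stressor) and daily rate s discretized into
   logarithmic bins with borders 10^i,

   P(m=1 | s) = P(s|m=1) P(m=1) / [ P(s|m=1) P(m=1) + P(s|m=0) P(m=0) ],

   where the likelihoods are within-condition bin frequencies and the prior
   is the sample proportion of manipulation days.

Since the recorded per-bird day counts behind these statistics are not
published, the package ships a first-class synthetic cohort generator that
reproduces their printed structure — baseline 2818 ± 1183 motifs/day with an
empirical floor of 629, a saturating-exponential rise after isolation onset,
day-1 post-surgery suppression to 54 ± 34% with recovery to ~91% by day 10,
and 24-h post-tethering suppression to 22 ± 43% — so every stage of the
pipeline is testable end to end, and parameter-recovery experiments can
verify that the estimators return what the generator encodes.

The package also covers the surrounding bookkeeping: detection-log I/O with
the 5-standard-deviation feature rejection filter, light-phase day
aggregation, windowed white-noise trigger fractions, paired pre/post
t-tests, rank-sum comparison of per-bird minima with day-span matching,
exponential adaptation fits, and recovery curves (fraction of birds below
W_x vs days since manipulation).

## Worked example

Run the full default study (all scenarios, thresholds, posterior,
statistics, recovery curves) and print the report:

```sh
songwelfare all --out demo_out
songwelfare report --out demo_out
```

```text
songwelfare run report
  config digest: cbe2bdbb36d5b1df
  seed: 20260101

Welfare thresholds (motifs/day):
  W_95 = 1571
  W_99 = 1246
  W_99.5 = 1109

Cohort statistics:
  paired_t_white_noise: n=26, statistic=1.307, p=0.2029, effect=1.069
  paired_t_surgery: n=12, statistic=-4.504, p=0.0008946, effect=0.5306
  paired_t_tethering: n=17, statistic=-11.66, p=3.123e-09, effect=0.241
  rank_sum_minima_wn_vs_baseline: n=45, statistic=nan, p=0.5425, effect=nan
  adaptation_plateau_mean: n=6, statistic=3105, p=nan, effect=3105

Posterior P(recent manipulation | singing rate):
  [0, 1): undefined  (n1=0, n0=0)
  [1, 10): 1.000  (n1=1, n0=0)
  [10, 100): 1.000  (n1=3, n0=0)
  [100, 1000): 1.000  (n1=15, n0=0)
  [1000, 10000): 0.030  (n1=10, n0=323)

Recovery (first day with < 50 % of birds below threshold):
  surgery: day 1
  tethering: day 4
  white_noise: day 0
```

Reading the report: the 19-bird synthetic baseline yields welfare thresholds
around 1100–1600 motifs/day for this cohort draw. The paired t-tests
recover the configured effects — no white-noise effect (ratio 1.07,
p = 0.20), a halving of the rate after surgery (ratio 0.53, p < 0.001), and
a collapse to 24% after tethering (p < 10⁻⁸). The posterior equals 1 in
every occupied bin below 1000 motifs (manipulated birds only) and is near 0
above 1000; the empty [0, 1) bin is reported as undefined rather than
silently 0 or 1. Surgery birds recover above threshold within a day on
average, tethered birds after about 4 days.

The same stages are available programmatically:

```python
from songwelfare import bootstrap_thresholds, generate_cohort

baseline = generate_cohort("baseline", n_birds=19, seed=1)
ts = bootstrap_thresholds(baseline, confidences=(95.0, 99.0, 99.5))
print(ts.thresholds)
```

## Layout

- `songwelfare.synthetic` — cohort and rendition-log generator
- `songwelfare.renditions` — detection-log I/O, 5-sd filter, aggregation
- `songwelfare.thresholds` — bootstrap W_x, classification, recovery curves
- `songwelfare.bayes` — binned posterior of a recent manipulation
- `songwelfare.stats` — paired tests, rank-sum, day matching, adaptation fits
- `songwelfare.pipeline` / `songwelfare.cli` — deterministic end-to-end runs

See `docs/methods.md` for the model, its assumptions, and every tunable
parameter.
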
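"""Cohort statistics vs independent from-first-principles oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from songwelfare.stats import (
    MatchingError,
    feature_shift_test,
    fit_adaptation_curve,
    paired_pre_post_test,
    rank_sum_min_test,
    subsample_match_days,
)
from songwelfare.synthetic import generate_cohort
from songwelfare.types import BirdTimeline, DayCount


def paired_t_oracle(pre, post):
    """Textbook paired t: t = d_bar / (s_d / sqrt(n)), two-sided p via the
    t distribution's survival function."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return t, p


class TestPairedTest:
    def test_identity_gives_null_result(self):
        res = paired_pre_post_test([10, 20, 30], [10, 20, 30])
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.df == 2

    def test_hand_dataset_matches_formula(self):
        res = paired_pre_post_test([10, 20, 30], [12, 19, 33])
        t, p = paired_t_oracle([10, 20, 30], [12, 19, 33])
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)
        assert res.mean_ratio == pytest.approx((1.2 + 0.95 + 1.1) / 3)

    def test_agrees_with_oracle_to_ten_digits_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            pre = rng.uniform(100, 4000, n)
            post = pre * rng.uniform(0.2, 1.5, n)
            res = paired_pre_post_test(pre, post)
            t, p = paired_t_oracle(pre, post)
            assert res.statistic == pytest.approx(t, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_surgery_cohorts_detect_the_day1_drop(self):
        """Replicate 12-bird surgery cohorts reject the no-change null at
        alpha=0.05 in at least 90% of cases (the effect is large)."""
        rejections = 0
        n_rep = 60
        for seed in range(n_rep):
            cohort = generate_cohort("surgery", 12, 1000 + seed)
            pre = [
                np.mean([c.motif_count for c in tl.counts if c.day_index < 0])
                for tl in cohort
            ]
            post = [tl.count_on(1).motif_count for tl in cohort]
            if paired_pre_post_test(pre, post).p_value < 0.05:
                rejections += 1
        assert rejections >= 0.9 * n_rep

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_pre_post_test([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            paired_pre_post_test([1], [2])


def ranksum_exact_oracle(a, b):
    """Brute force: enumerate all C(n1+n2, n1) rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    observed = ranks[:n1].sum()
    sums = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    mean = np.mean(sums)
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-9 for s in sums)
    return extreme / len(sums)


class TestRankSum:
    def test_identical_small_groups_give_p_one(self):
        p = rank_sum_min_test([629, 800, 950], [640, 810, 900])
        assert p == pytest.approx(1.0)

    def test_exact_p_equals_enumeration_for_three_vs_three(self):
        """3 vs 3: exact rank-sum p matches enumeration over all 20
        assignments."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.uniform(0, 100, 3)
            b = rng.uniform(0, 100, 3)
            assert rank_sum_min_test(a, b) == pytest.approx(
                ranksum_exact_oracle(a, b), abs=1e-12
            )

    def test_type_one_error_calibrated_under_null(self):
        """Both groups from one distribution: rejection rate at alpha=0.05
        stays within the binomial band around 0.05."""
        rng = np.random.default_rng(17)
        n_rep = 10_000
        rejections = 0
        for _ in range(n_rep):
            a = rng.normal(size=9)
            b = rng.normal(size=8)
            rejections += rank_sum_min_test(a, b) < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_rep) + 0.005

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_min_test([], [1.0])


class TestDayMatching:
    def test_equal_day_counts_are_matched_exactly(self):
        pool = {f"b{i}": list(range(10)) for i in range(6)}
        out = subsample_match_days([10, 10, 10, 10], pool, 4, seed=0)
        assert len(out) == 4
        for days in out.values():
            assert len(days) == 10 and len(set(days)) == 10

    def test_never_selects_a_day_twice_within_a_bird(self):
        rng = np.random.default_rng(2)
        pool = {
            f"b{i}": list(range(int(rng.integers(5, 30)))) for i in range(8)
        }
        targets = [int(rng.integers(1, 12)) for _ in range(8)]
        out = subsample_match_days(targets, pool, 5, seed=3)
        for bird, days in out.items():
            assert len(set(days)) == len(days)
            assert set(days) <= set(pool[bird])

    def test_deterministic_under_seed(self):
        pool = {f"b{i}": list(range(15)) for i in range(7)}
        targets = [3, 5, 8, 8, 10, 12]
        a = subsample_match_days(targets, pool, 5, seed=11)
        b = subsample_match_days(targets, pool, 5, seed=11)
        assert a == b

    def test_mean_selected_days_matches_targets(self):
        """Span-matched subsampling reproduces the target group's mean days
        per bird to within half a day."""
        rng = np.random.default_rng(23)
        targets = np.clip(rng.normal(11.3, 5.2, 26).round().astype(int), 1, 25)
        pool = {f"u{i}": list(range(25)) for i in range(19)}
        sizes = []
        for seed in range(40):
            out = subsample_match_days(targets.tolist(), pool, 19, seed=seed)
            sizes.extend(len(v) for v in out.values())
        assert abs(np.mean(sizes) - targets.mean()) < 0.5

    def test_infeasible_targets_raise_matching_error(self):
        pool = {"a": [0, 1], "b": [0, 1, 2]}
        with pytest.raises(MatchingError):
            subsample_match_days([5, 6], pool, 2, seed=0, max_attempts=50)


class TestAdaptationFit:
    def test_noiseless_curve_recovered_within_one_percent(self):
        days = np.arange(1, 15)
        y = 2900.0 - (2900.0 - 700.0) * np.exp(-days / 4.0)
        fit = fit_adaptation_curve(list(zip(days, y)))
        assert fit.plateau == pytest.approx(2900.0, rel=0.01)
        assert fit.tau == pytest.approx(4.0, rel=0.01)
        assert fit.residual_rms < 1.0

    def test_constant_series_yields_plateau_and_zero_rms(self):
        fit = fit_adaptation_curve([(d, 2500.0) for d in range(1, 8)])
        assert fit.plateau == 2500.0 and fit.residual_rms == 0.0

    def test_cohort_plateaus_track_configured_baseline(self):
        """Fitted plateaus across synthetic isolated birds stay within 10%
        of the cohort's configured mean singing rate."""
        cohort = generate_cohort("isolation", 60, 31, n_post_days=20)
        plateaus = [fit_adaptation_curve(tl).plateau for tl in cohort]
        assert abs(np.mean(plateaus) - 2818.0) / 2818.0 < 0.10

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            fit_adaptation_curve([(1, 100.0), (2, 200.0), (3, 250.0)])


class TestFeatureShift:
    def test_no_shift_is_maintained(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(3000, 50, 400)
        z, label = feature_shift_test(pre, pre.copy(), +1)
        assert z == 0.0 and label == "maintained"

    def test_planted_escape_shift_detected(self):
        rng = np.random.default_rng(2)
        pre = rng.normal(3000, 50, 500)
        post = rng.normal(3000 + 3 * 50, 50, 500)
        z, label = feature_shift_test(pre, post, +1)
        assert label == "shifted_away" and z > 2.58

    def test_shift_toward_triggering_region_classified(self):
        """A bird moving its syllable deeper into the noise-triggering range
        is flagged as shifted_toward (the rare seeking phenotype)."""
        rng = np.random.default_rng(3)
        pre = rng.normal(3000, 50, 500)
        post = rng.normal(3000 - 2 * 50, 50, 500)
        z, label = feature_shift_test(pre, post, +1)
        assert label == "shifted_toward" and z < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            feature_shift_test([5.0, 5.0, 5.0], [6.0], +1)
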
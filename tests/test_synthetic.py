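"""Synthetic-cohort generator: distributional contracts and determinism."""

import dataclasses
import math

import numpy as np
import pytest

from songwelfare.synthetic import (
    DEFAULT_EFFECTS,
    adaptation_expectation,
    apply_manipulation_effect,
    draw_bird_offset,
    generate_cohort,
    generate_rendition_log,
    sample_baseline_day,
    sample_effect_ratio,
    simulate_isolation_adaptation,
    truncated_normal_location,
)
from songwelfare.types import (
    BirdTimeline,
    ConfigurationError,
    DayCount,
    EffectSpec,
    GeneratorConfig,
    ManipulationEvent,
)


class TestBaselineSampling:
    def test_cohort_mean_matches_configured_baseline(self, config, rng):
        """1e5 draws (fresh bird per draw) land within 2% of 2818 motifs/day."""
        n = 100_000
        sigma_b = config.log_sigma_bird
        offsets = np.exp(rng.normal(-0.5 * sigma_b**2, sigma_b, n))
        draws = np.array(
            [sample_baseline_day(config, L, rng) for L in offsets[:20000]]
        )
        assert abs(draws.mean() - config.baseline_mean) / config.baseline_mean < 0.02
        # sd of the moment-matched lognormal, generous band (truncation shrinks it)
        assert 0.8 * config.baseline_sd < draws.std() < 1.1 * config.baseline_sd

    def test_no_draw_below_floor(self, config, rng):
        draws = [
            sample_baseline_day(config, draw_bird_offset(config, rng), rng)
            for _ in range(5000)
        ]
        assert min(draws) >= config.baseline_floor

    def test_degenerate_sd_gives_constant(self, rng):
        cfg = GeneratorConfig(baseline_sd=0.0, bird_level_variance_fraction=0.0)
        draws = {sample_baseline_day(cfg, 1.0, rng) for _ in range(100)}
        assert draws == {round(cfg.baseline_mean)}

    def test_truncated_mean_exceeds_untruncated(self, rng):
        """Floor-resampling can only raise the mean of the lognormal family."""
        cfg = GeneratorConfig(
            baseline_mean=1000.0, baseline_sd=800.0, baseline_floor=600.0,
            bird_level_variance_fraction=0.0,
        )
        n = 200_000
        truncated = np.array([sample_baseline_day(cfg, 1.0, rng) for _ in range(30000)])
        sigma = math.sqrt(cfg.log_sigma2_total)
        untruncated = 1000.0 * np.exp(rng.normal(-0.5 * sigma**2, sigma, n))
        mc_se = truncated.std() / math.sqrt(truncated.size)
        assert truncated.mean() > untruncated.mean() - 3 * mc_se

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(baseline_mean=500.0, baseline_floor=629.0)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(bird_level_variance_fraction=1.5)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(fp_rate=1.0)


class TestEffectRatioDraws:
    def test_truncated_normal_mean_is_calibrated(self, rng):
        """Zero-truncated draws average to ratio_mean even when sd > mean."""
        for mean, sd in [(0.54, 0.34), (0.22, 0.43), (1.01, 0.29)]:
            spec = EffectSpec(mean, sd, recovery_tau=5.0)
            draws = sample_effect_ratio(spec, rng, 100_000)
            assert draws.min() >= 0.0
            assert abs(draws.mean() - mean) < 4 * sd / math.sqrt(draws.size)

    def test_location_below_naive_mean_under_truncation(self):
        assert truncated_normal_location(0.22, 0.43) < 0.22
        assert truncated_normal_location(0.54, 0.0) == 0.54


class TestIsolationAdaptation:
    def test_noiseless_series_matches_closed_form(self, config):
        tl = simulate_isolation_adaptation(
            config, 14, np.random.default_rng(0), noiseless=True
        )
        for c in tl.counts:
            expected = adaptation_expectation(config, 1.0, c.day_index)
            assert c.motif_count == round(expected)
        assert tl.counts[0].partial_day and not tl.counts[1].partial_day

    def test_tiny_tau_reaches_baseline_by_day_one(self):
        cfg = GeneratorConfig(adaptation_tau=1e-9)
        tl = simulate_isolation_adaptation(
            cfg, 5, np.random.default_rng(0), noiseless=True
        )
        for c in tl.counts[1:]:
            assert c.motif_count == round(cfg.baseline_mean)

    def test_day13_cohort_mean_near_printed_plateau(self, config):
        """1000 isolated birds: mean day-13 count within 5% of 2906."""
        counts = []
        for i, tl in enumerate(
            generate_cohort("isolation", 1000, 42, n_post_days=14)
        ):
            c = tl.count_on(13)
            counts.append(c.motif_count)
        mean13 = np.mean(counts)
        assert abs(mean13 - 2906.0) / 2906.0 < 0.05

    def test_rejects_empty_series(self, config, rng):
        with pytest.raises(ValueError):
            simulate_isolation_adaptation(config, 0, rng)


def _flat_timeline(bird="b0", level=2000, n_pre=5, n_post=10, kind="surgery"):
    counts = tuple(
        DayCount(d, level, False) for d in range(-n_pre, n_post + 1)
    )
    return BirdTimeline(bird, counts), ManipulationEvent(bird, kind, 0)


class TestManipulationEffect:
    def test_null_effect_is_identity(self):
        tl, ev = _flat_timeline()
        spec = EffectSpec(1.0, 0.0, recovery_tau=5.0, recovery_target_ratio=1.0)
        out = apply_manipulation_effect(tl, ev, spec, np.random.default_rng(0))
        full = [c for c in out.counts if not c.partial_day]
        assert all(c.motif_count == 2000 for c in full)

    def test_pre_event_days_unchanged(self, rng):
        tl, ev = _flat_timeline()
        spec = DEFAULT_EFFECTS["surgery"]
        out = apply_manipulation_effect(tl, ev, spec, rng)
        for c in out.counts:
            if c.day_index < 0:
                assert c.motif_count == 2000

    def test_noiseless_trajectory_matches_closed_form(self):
        """Expected ratio at day d is target - (target-r1) exp(-d/tau)."""
        tl, ev = _flat_timeline(kind="tethering_onset")
        spec = EffectSpec(0.22, 0.0, recovery_tau=8.05, recovery_target_ratio=2.64)
        out = apply_manipulation_effect(tl, ev, spec, np.random.default_rng(0))
        for c in out.counts:
            if c.day_index < 0:
                continue
            expected = 2000 * spec.expected_ratio(c.day_index)
            assert c.motif_count == round(expected)

    def test_day1_mean_ratio_recovers_configured_surgery_effect(self):
        """Across many replicate birds the day-1 ratio averages to 0.54."""
        spec = DEFAULT_EFFECTS["surgery"]
        rng = np.random.default_rng(77)
        ratios = []
        for _ in range(4000):
            tl, ev = _flat_timeline()
            out = apply_manipulation_effect(tl, ev, spec, rng)
            ratios.append(out.count_on(1).motif_count / 2000)
        se = np.std(ratios) / math.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 0.54) < 3 * se

    def test_onset_outside_span_rejected(self, rng):
        tl, _ = _flat_timeline()
        ev = ManipulationEvent("b0", "surgery", 99)
        with pytest.raises(ValueError):
            apply_manipulation_effect(tl, ev, DEFAULT_EFFECTS["surgery"], rng)


class TestCohorts:
    def test_determinism_bit_identical(self):
        a = generate_cohort("tethering", 8, 5)
        b = generate_cohort("tethering", 8, 5)
        assert all(
            x.counts == y.counts and x.events == y.events
            for x, y in zip(a, b)
        )

    def test_surgery_cohort_structure(self):
        cohort = generate_cohort("surgery", 12, 1)
        assert len(cohort) == 12
        for tl in cohort:
            assert tl.event_of_kind("surgery") is not None
            pre = [c for c in tl.counts if c.day_index < 0 and not c.partial_day]
            assert len(pre) >= 5

    def test_all_counts_are_nonnegative_integers(self):
        for scenario in ("baseline", "isolation", "surgery", "tethering_microdrive"):
            for tl in generate_cohort(scenario, 40, 9):
                for c in tl.counts:
                    assert c.motif_count >= 0
                    assert isinstance(c.motif_count, int)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            generate_cohort("hibernation", 5, 0)

    def test_parameter_recovery_from_large_cohort(self):
        """Estimating baseline mean and effect ratios from 1000-bird cohorts
        recovers the configured values within 3 MC standard errors."""
        base = generate_cohort("baseline", 1000, 11, n_pre_days=5)
        vals = np.array(
            [c.motif_count for tl in base for c in tl.full_day_counts()]
        )
        # bird-level variance dominates: conservative SE via per-bird means
        bird_means = np.array(
            [np.mean([c.motif_count for c in tl.full_day_counts()]) for tl in base]
        )
        se = bird_means.std() / math.sqrt(len(bird_means))
        assert abs(vals.mean() - 2818.0) < 3 * se

        surg = generate_cohort("surgery", 1000, 12)
        r1, r10 = [], []
        for tl in surg:
            pre = np.mean(
                [c.motif_count for c in tl.counts if c.day_index < 0]
            )
            r1.append(tl.count_on(1).motif_count / pre)
            r10.append(tl.count_on(10).motif_count / pre)
        for sample, expected in [(r1, 0.54), (r10, 0.91)]:
            sample = np.asarray(sample)
            se = sample.std() / math.sqrt(sample.size)
            assert abs(sample.mean() - expected) < 3 * se


class TestRenditionLogGeneration:
    def test_clean_log_count_equals_timeline(self, rng):
        cfg = GeneratorConfig(fp_rate=0.0, outlier_rate=0.0)
        tl = BirdTimeline(
            "b1", tuple(DayCount(d, 100 + d, False) for d in range(3))
        )
        events = generate_rendition_log(tl, cfg, rng)
        assert len(events) == sum(c.motif_count for c in tl.counts)
        assert all(e.label == "target" for e in events)

    def test_contaminant_fraction_near_fp_rate(self, rng):
        cfg = GeneratorConfig(fp_rate=0.01, outlier_rate=0.0)
        tl = BirdTimeline("b1", (DayCount(0, 100_000, False),))
        events = generate_rendition_log(tl, cfg, rng)
        frac = np.mean([e.label != "target" for e in events])
        # binomial 99% CI around 0.01 at n ~ 1e5
        assert abs(frac - 0.01) < 3 * math.sqrt(0.01 * 0.99 / len(events))

    def test_outlier_fraction_matches_configuration(self, rng):
        cfg = GeneratorConfig(fp_rate=0.0, outlier_rate=0.02)
        tl = BirdTimeline("b1", (DayCount(0, 50_000, False),))
        events = generate_rendition_log(tl, cfg, rng)
        z = np.array(
            [
                abs(e.feature_value - cfg.feature_mean) / cfg.feature_sd
                for e in events
            ]
        )
        frac = (z > 5.0).mean()
        assert abs(frac - 0.02) < 3 * math.sqrt(0.02 * 0.98 / z.size)
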
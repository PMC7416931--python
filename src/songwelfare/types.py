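"""Core domain types for singing-rate welfare analysis.

The unit of observation throughout the package is the *bird-day*: the number
of undirected song motifs a singly housed male produced during one light
phase.  A :class:`BirdTimeline` holds one bird's daily motif counts aligned
to the manipulation events (isolation onset, surgery, tethering, ...) that
the bird experienced; a :class:`GeneratorConfig` holds every distributional
parameter of the synthetic cohort generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "EVENT_KINDS",
    "ConfigurationError",
    "EffectSpec",
    "GeneratorConfig",
    "ManipulationEvent",
    "DayCount",
    "BirdTimeline",
]

#: Closed set of manipulation-event kinds.
EVENT_KINDS = frozenset(
    {
        "isolation_onset",
        "wn_onset",
        "surgery",
        "tethering_onset",
        "weight_attachment",
        "cage_transfer",
    }
)


class ConfigurationError(ValueError):
    """Raised when a generator or effect configuration violates an invariant."""


@dataclass(frozen=True)
class EffectSpec:
    """Effect of one manipulation on the singing rate.

    Parameters
    ----------
    ratio_mean:
        Expected post/pre singing-rate ratio on the first full post-event
        day (e.g. 0.54 for brain surgery: the rate halves).
    ratio_sd:
        Across-bird standard deviation of that ratio.  Draws come from a
        normal truncated at zero whose location is calibrated so the
        truncated mean equals ``ratio_mean``.
    recovery_tau:
        Time constant (days) of the saturating-exponential relaxation of the
        expected ratio back toward ``recovery_target_ratio``.
    recovery_target_ratio:
        Asymptotic post/pre ratio.  1.0 means full recovery to the pre-event
        level; it may exceed 1 when the pre-event level was itself suppressed
        (tethering measured right after surgery).
    """

    ratio_mean: float
    ratio_sd: float
    recovery_tau: float
    recovery_target_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.ratio_mean < 0:
            raise ConfigurationError("ratio_mean must be >= 0")
        if self.ratio_sd < 0:
            raise ConfigurationError("ratio_sd must be >= 0")
        if self.recovery_tau <= 0:
            raise ConfigurationError("recovery_tau must be > 0")
        if self.recovery_target_ratio < 0:
            raise ConfigurationError("recovery_target_ratio must be >= 0")

    def expected_ratio(self, days_since_first_full: float) -> float:
        """Expected post/pre ratio ``d`` days after the first full post day.

        ``target - (target - ratio_mean) * exp(-d / recovery_tau)``; equals
        ``ratio_mean`` at d=0 and relaxes toward ``recovery_target_ratio``.
        """
        t = self.recovery_target_ratio
        return t - (t - self.ratio_mean) * math.exp(
            -days_since_first_full / self.recovery_tau
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Distributional parameters of the synthetic cohort generator.

    Daily counts of fully adapted, unmanipulated birds follow a lognormal
    moment-matched to ``(baseline_mean, baseline_sd)`` and resampled to stay
    at or above ``baseline_floor``.  The lognormal's log-variance is split by
    ``bird_level_variance_fraction`` into a per-bird multiplicative level
    (stable across days) and residual within-bird day noise.
    """

    baseline_mean: float = 2818.0
    baseline_sd: float = 1183.0
    baseline_floor: float = 629.0
    bird_level_variance_fraction: float = 0.7
    adaptation_day0_mean: float = 746.0
    adaptation_tau: float = 3.0
    effect_specs: Mapping[str, EffectSpec] = field(default_factory=dict)
    fp_rate: float = 0.01
    feature_mean: float = 3000.0
    feature_sd: float = 60.0
    outlier_rate: float = 0.002
    wn_hit_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.baseline_mean > self.baseline_floor >= 0):
            raise ConfigurationError(
                "require baseline_mean > baseline_floor >= 0"
            )
        if self.baseline_sd < 0:
            raise ConfigurationError("baseline_sd must be >= 0")
        if not 0.0 <= self.bird_level_variance_fraction <= 1.0:
            raise ConfigurationError(
                "bird_level_variance_fraction must be in [0, 1]"
            )
        if self.adaptation_tau <= 0:
            raise ConfigurationError("adaptation_tau must be > 0")
        if not 0.0 <= self.fp_rate < 1.0:
            raise ConfigurationError("fp_rate must be in [0, 1)")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ConfigurationError("outlier_rate must be in [0, 1)")
        if self.feature_sd <= 0:
            raise ConfigurationError("feature_sd must be > 0")
        if not 0.0 <= self.wn_hit_rate <= 1.0:
            raise ConfigurationError("wn_hit_rate must be in [0, 1]")

    # -- derived log-space parameters ------------------------------------

    @property
    def log_sigma2_total(self) -> float:
        """Total log-variance of the moment-matched lognormal."""
        if self.baseline_sd == 0:
            return 0.0
        cv2 = (self.baseline_sd / self.baseline_mean) ** 2
        return math.log1p(cv2)

    @property
    def log_sigma_bird(self) -> float:
        """Log-sd of the per-bird multiplicative level."""
        return math.sqrt(
            self.bird_level_variance_fraction * self.log_sigma2_total
        )

    @property
    def log_sigma_day(self) -> float:
        """Log-sd of the within-bird day noise."""
        return math.sqrt(
            (1.0 - self.bird_level_variance_fraction) * self.log_sigma2_total
        )

    def with_effects(self, specs: Mapping[str, EffectSpec]) -> "GeneratorConfig":
        return replace(self, effect_specs={**self.effect_specs, **specs})


@dataclass(frozen=True)
class ManipulationEvent:
    """One manipulation applied to one bird, keyed by onset day index."""

    bird_id: str
    kind: str
    onset_day: int

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigurationError(
                f"unknown event kind {self.kind!r}; expected one of "
                f"{sorted(EVENT_KINDS)}"
            )


@dataclass(frozen=True)
class DayCount:
    """One bird-day: day index, motif count, and a partial-recording flag."""

    day_index: int
    motif_count: int
    partial_day: bool = False

    def __post_init__(self) -> None:
        if self.motif_count < 0 or self.motif_count != int(self.motif_count):
            raise ValueError("motif_count must be a non-negative integer")


@dataclass
class BirdTimeline:
    """One bird's daily motif counts aligned to its manipulation events."""

    bird_id: str
    counts: Sequence[DayCount]
    events: Sequence[ManipulationEvent] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        days = [c.day_index for c in self.counts]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("day_index must be strictly increasing")

    def count_on(self, day_index: int) -> DayCount | None:
        for c in self.counts:
            if c.day_index == day_index:
                return c
        return None

    def full_day_counts(self) -> list[DayCount]:
        """Counts on non-partial days only."""
        return [c for c in self.counts if not c.partial_day]

    def event_of_kind(self, kind: str) -> ManipulationEvent | None:
        for e in self.events:
            if e.kind == kind:
                return e
        return None
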
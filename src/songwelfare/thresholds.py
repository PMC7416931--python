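"""Bootstrapped welfare thresholds and recovery curves.

The welfare threshold W_x is the daily motif count exceeded by putatively
unstressed isolated birds on x percent of bird-days: a day strictly below
W_x flags a putative stressor at confidence x.  Thresholds are estimated by
a hierarchical bootstrap of the baseline cohort — birds drawn with
replacement, then days with replacement within each drawn bird — which
respects the two-level (between-bird / within-bird) structure of the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .types import BirdTimeline

__all__ = [
    "WelfareThresholdSet",
    "RecoveryCurve",
    "bootstrap_thresholds",
    "classify_day",
    "recovery_curve",
    "per_bird_minimum",
]


@dataclass(frozen=True)
class WelfareThresholdSet:
    """Mapping confidence level x (percent) -> welfare threshold W_x.

    Higher confidence means a lower threshold: W_95 >= W_99 >= W_99.5.
    """

    thresholds: Mapping[float, float]
    n_boot_birds: int
    days_per_bird: int
    seed: int
    source_summary: tuple[int, int]  # (n_birds, n_days)

    def __post_init__(self) -> None:
        xs = sorted(self.thresholds)
        for lo, hi in zip(xs, xs[1:]):
            if self.thresholds[lo] < self.thresholds[hi]:
                raise ValueError(
                    "thresholds must be weakly decreasing in confidence"
                )

    def __getitem__(self, x: float) -> float:
        return self.thresholds[x]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "thresholds": {str(k): v for k, v in self.thresholds.items()},
            "n_boot_birds": self.n_boot_birds,
            "days_per_bird": self.days_per_bird,
            "seed": self.seed,
            "source_summary": {
                "n_birds": self.source_summary[0],
                "n_days": self.source_summary[1],
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


@dataclass(frozen=True)
class RecoveryCurve:
    """Fraction of birds below threshold vs days since manipulation onset."""

    manipulation: str
    points: tuple[tuple[int, float, int], ...] = field(default_factory=tuple)
    # each point: (day_since_onset, fraction_below, n_birds)

    def fractions(self) -> dict[int, float]:
        return {d: f for d, f, _ in self.points}

    def first_day_below(self, level: float = 0.5) -> int | None:
        """First day at which the below-threshold fraction drops under level."""
        for d, f, _ in self.points:
            if f < level:
                return d
        return None


def _per_bird_day_arrays(
    baseline: Sequence[Sequence[float]] | Sequence[BirdTimeline],
) -> list[np.ndarray]:
    arrays = []
    for bird in baseline:
        if isinstance(bird, BirdTimeline):
            vals = [c.motif_count for c in bird.full_day_counts()]
        else:
            vals = list(bird)
        if vals:
            arrays.append(np.asarray(vals, dtype=float))
    return arrays


def bootstrap_thresholds(
    baseline: Sequence[Sequence[float]] | Sequence[BirdTimeline],
    confidences: Sequence[float] = (95.0, 99.0, 99.5),
    n_boot_birds: int = 100_000,
    days_per_bird: int = 10,
    seed: int = 0,
) -> WelfareThresholdSet:
    """Hierarchical-bootstrap welfare thresholds from baseline day counts.

    Draws ``n_boot_birds`` birds with replacement; from each drawn bird,
    draws ``days_per_bird`` of its (full) days with replacement; W_x is the
    (100 - x)th nearest-rank percentile of the single pooled resample.
    Partial days are excluded from the input.  Deterministic given ``seed``.
    """
    arrays = _per_bird_day_arrays(baseline)
    if len(arrays) < 2:
        raise ValueError("need at least two birds with at least one day each")
    for x in confidences:
        if not 50.0 < x < 100.0:
            raise ValueError(f"confidence {x} outside (50, 100)")
    if n_boot_birds < 1 or days_per_bird < 1:
        raise ValueError("n_boot_birds and days_per_bird must be >= 1")

    lengths = np.array([a.size for a in arrays])
    offsets = np.concatenate([[0], np.cumsum(lengths[:-1])])
    flat = np.concatenate(arrays)

    rng = np.random.default_rng(seed)
    birds = rng.integers(0, len(arrays), size=n_boot_birds)
    # uniform day index within each drawn bird, vectorized over the ragged data
    u = rng.random(size=(n_boot_birds, days_per_bird))
    day_idx = (u * lengths[birds][:, None]).astype(np.int64)
    pooled = flat[offsets[birds][:, None] + day_idx].ravel()

    thresholds = {
        float(x): float(
            np.quantile(pooled, (100.0 - x) / 100.0, method="inverted_cdf")
        )
        for x in confidences
    }
    return WelfareThresholdSet(
        thresholds=thresholds,
        n_boot_birds=n_boot_birds,
        days_per_bird=days_per_bird,
        seed=seed,
        source_summary=(len(arrays), int(lengths.sum())),
    )


def classify_day(count: float, threshold: float) -> bool:
    """True iff the day falls strictly below the welfare threshold."""
    if count < 0:
        raise ValueError("count must be >= 0")
    return count < threshold


def recovery_curve(
    cohort: Sequence[BirdTimeline],
    manipulation: str,
    threshold: float,
    max_days: int,
) -> RecoveryCurve:
    """Fraction of birds strictly below ``threshold`` per day since onset.

    For each day 0..max_days after the named manipulation, birds with a full
    (non-partial) count that day enter the denominator; birds lacking data
    are excluded from that day's point.  Partial onset-day recordings are
    therefore never counted.
    """
    with_event = [
        (tl, tl.event_of_kind(manipulation)) for tl in cohort
    ]
    with_event = [(tl, e) for tl, e in with_event if e is not None]
    if not with_event:
        raise ValueError(f"no birds carry a {manipulation!r} event")
    points = []
    for d in range(max_days + 1):
        below = 0
        n = 0
        for tl, e in with_event:
            c = tl.count_on(e.onset_day + d)
            if c is None or c.partial_day:
                continue
            n += 1
            below += classify_day(c.motif_count, threshold)
        if n:
            points.append((d, below / n, n))
    return RecoveryCurve(manipulation, tuple(points))


def per_bird_minimum(
    cohort: Sequence[BirdTimeline],
    window: tuple[int, int] | None = None,
) -> dict[str, int]:
    """Minimum daily count per bird over full days in ``window`` (inclusive)."""
    if window is not None and window[1] < window[0]:
        raise ValueError("empty window")
    minima: dict[str, int] = {}
    for tl in cohort:
        vals = [
            c.motif_count
            for c in tl.full_day_counts()
            if window is None or window[0] <= c.day_index <= window[1]
        ]
        if not vals:
            raise ValueError(
                f"bird {tl.bird_id!r} has no full days in window"
            )
        minima[tl.bird_id] = min(vals)
    return minima
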
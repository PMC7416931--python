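"""Replicate-cohort experiments over the synthetic generator.

Parameter-recovery measurements used by the acceptance checks and the
report: simulate many replicate cohorts of a scenario, apply the same
estimators a study would apply to recorded data (per-bird post/pre ratios
against the realized pre-manipulation mean, cohort grand means), and return
the grand estimate with its Monte-Carlo standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import generate_cohort
from .types import BirdTimeline

__all__ = [
    "ReplicateEstimate",
    "manipulation_day_percent",
    "baseline_grand_mean",
]


@dataclass(frozen=True)
class ReplicateEstimate:
    """Grand mean over replicate cohorts with its Monte-Carlo standard error."""

    value: float
    mc_se: float
    n_birds_total: int
    n_replicates: int


def _per_bird_day_ratio(
    timeline: BirdTimeline, onset_day: int, day: int
) -> float | None:
    """Post/pre ratio: count on onset+day over the mean of full pre days."""
    pre = [
        c.motif_count
        for c in timeline.counts
        if c.day_index < onset_day and not c.partial_day
    ]
    target = timeline.count_on(onset_day + day)
    if not pre or target is None or target.partial_day:
        return None
    pre_mean = float(np.mean(pre))
    if pre_mean == 0:
        return None
    return target.motif_count / pre_mean


def manipulation_day_percent(
    scenario: str,
    day: int,
    *,
    n_birds: int,
    n_pre_days: int,
    n_replicates: int = 500,
    seed: int = 0,
    event_kind: str | None = None,
) -> ReplicateEstimate:
    """Mean post/pre singing-rate percent on a given post-manipulation day.

    Simulates ``n_replicates`` cohorts of ``n_birds``; per bird, the singing
    rate on post-event day ``day`` is expressed as a percent of the bird's
    mean rate over its ``n_pre_days`` full pre-event days; returns the grand
    mean percent across all birds with the MC standard error computed across
    replicate-cohort means.
    """
    root = np.random.SeedSequence(seed)
    cohort_seeds = root.generate_state(n_replicates) >> 1  # keep < 2**31
    replicate_means = []
    n_total = 0
    for s in cohort_seeds:
        cohort = generate_cohort(
            scenario,
            n_birds,
            int(s),
            n_pre_days=n_pre_days,
            n_post_days=max(day, 0),
        )
        ratios = []
        for tl in cohort:
            kinds = [e.kind for e in tl.events] if event_kind is None else [event_kind]
            onset = next(
                (e.onset_day for e in tl.events if e.kind in kinds), None
            )
            if onset is None:
                continue
            r = _per_bird_day_ratio(tl, onset, day)
            if r is not None:
                ratios.append(r)
        if ratios:
            replicate_means.append(float(np.mean(ratios)))
            n_total += len(ratios)
    means = np.asarray(replicate_means)
    value = 100.0 * float(means.mean())
    mc_se = 100.0 * float(means.std(ddof=1) / np.sqrt(means.size))
    return ReplicateEstimate(value, mc_se, n_total, means.size)


def baseline_grand_mean(
    *,
    n_birds: int = 19,
    n_days: int = 17,
    n_replicates: int = 200,
    seed: int = 0,
) -> ReplicateEstimate:
    """Grand mean daily motif count of fully adapted baseline cohorts."""
    root = np.random.SeedSequence(seed)
    cohort_seeds = root.generate_state(n_replicates) >> 1
    replicate_means = []
    n_total = 0
    for s in cohort_seeds:
        cohort = generate_cohort(
            "baseline", n_birds, int(s), n_pre_days=n_days
        )
        vals = [
            c.motif_count for tl in cohort for c in tl.full_day_counts()
        ]
        replicate_means.append(float(np.mean(vals)))
        n_total += len(vals)
    means = np.asarray(replicate_means)
    return ReplicateEstimate(
        float(means.mean()),
        float(means.std(ddof=1) / np.sqrt(means.size)),
        n_total,
        means.size,
    )
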
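"""Cohort-level statistical procedures.

Paired pre/post comparisons of singing rates, rank-sum comparison of
per-bird minima, the day-matching random subsampling scheme that equalizes
observation spans between groups, saturating-exponential fits to the
isolation adaptation, and the directional z-score test for operant shifts
of the targeted syllable feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats as sps

from .types import BirdTimeline

__all__ = [
    "PairedTestResult",
    "AdaptationFit",
    "FitError",
    "MatchingError",
    "paired_pre_post_test",
    "rank_sum_min_test",
    "subsample_match_days",
    "fit_adaptation_curve",
    "feature_shift_test",
]

#: Combined sample size up to which the rank-sum test enumerates exactly.
RANKSUM_EXACT_CUTOFF = 12

#: Two-sided 1% critical value of the standard normal.
_Z_CRIT_1PCT = sps.norm.ppf(0.995)


class FitError(RuntimeError):
    """Curve fit failed to converge; message carries diagnostics."""


class MatchingError(RuntimeError):
    """Day-matching subsample could not be constructed."""


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired two-tailed t-test on per-bird pre/post values."""

    statistic: float
    df: int
    p_value: float
    mean_ratio: float


@dataclass(frozen=True)
class AdaptationFit:
    """Saturating-exponential fit count(t) = plateau - (plateau - day0_level) e^{-t/tau}."""

    plateau: float
    day0_level: float
    tau: float
    residual_rms: float


def paired_pre_post_test(
    pre: Sequence[float], post: Sequence[float]
) -> PairedTestResult:
    """Paired two-tailed t-test of post vs pre singing rates, by bird.

    Also reports the mean of per-bird post/pre ratios (the effect size the
    welfare analysis quotes, e.g. 0.54 after surgery).  A zero difference
    vector (post identical to pre) yields statistic 0 and p-value 1.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.shape != b.shape:
        raise ValueError("pre and post must be paired (equal lengths)")
    n = a.size
    if n < 2:
        raise ValueError("need at least two birds")
    if np.allclose(a, b):
        t_stat, p = 0.0, 1.0
    else:
        res = sps.ttest_rel(b, a)
        t_stat, p = float(res.statistic), float(res.pvalue)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(a > 0, b / a, np.nan)
    mean_ratio = float(np.nanmean(ratios)) if np.isfinite(ratios).any() else math.nan
    return PairedTestResult(t_stat, n - 1, p, mean_ratio)


def rank_sum_min_test(
    minima_a: Sequence[float], minima_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing per-bird minima.

    Exact enumeration for combined n <= RANKSUM_EXACT_CUTOFF without ties;
    normal approximation with continuity correction otherwise.
    """
    a = np.asarray(minima_a, dtype=float)
    b = np.asarray(minima_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    small = a.size + b.size <= RANKSUM_EXACT_CUTOFF
    method = "exact" if (small and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def subsample_match_days(
    target_day_counts: Sequence[int],
    pool: Mapping[str, Sequence[int]],
    n_select_birds: int,
    seed: int,
    max_attempts: int = 10_000,
) -> dict[str, list[int]]:
    """Match per-bird observation spans between two groups by subsampling.

    Randomly selects ``n_select_birds`` of the target day counts, assigns
    each count to a distinct pool bird having at least that many days, and
    samples that many of the bird's days without replacement.  When a random
    assignment is infeasible, the whole sub-selection is redrawn, up to
    ``max_attempts`` times.  Deterministic given ``seed``.
    """
    targets_all = list(target_day_counts)
    birds = list(pool)
    if n_select_birds > len(birds):
        raise ValueError("n_select_birds exceeds the number of pool birds")
    if n_select_birds > len(targets_all):
        raise ValueError("n_select_birds exceeds the number of targets")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        chosen = rng.choice(len(targets_all), n_select_birds, replace=False)
        targets = [targets_all[i] for i in chosen]
        order = rng.permutation(len(birds))[:n_select_birds]
        assigned = {birds[j]: t for j, t in zip(order, targets)}
        if any(len(pool[b]) < t for b, t in assigned.items()):
            continue
        return {
            b: sorted(
                rng.choice(np.asarray(pool[b]), t, replace=False).tolist()
            )
            for b, t in assigned.items()
        }
    raise MatchingError(
        f"no feasible bird/day-count assignment in {max_attempts} attempts"
    )


def fit_adaptation_curve(
    series: BirdTimeline | Sequence[tuple[int, float]],
) -> AdaptationFit:
    """Least-squares saturating-exponential fit to the isolation rise.

    Fits count(t) = plateau - (plateau - day0_level) exp(-t / tau) to the
    daily motif counts, excluding day 0 (partial recording) and any
    partial-flagged day.  Needs at least four usable days.
    """
    if isinstance(series, BirdTimeline):
        pts = [
            (c.day_index, float(c.motif_count))
            for c in series.full_day_counts()
            if c.day_index != 0
        ]
    else:
        pts = [(int(d), float(v)) for d, v in series if int(d) != 0]
    if len(pts) < 4:
        raise ValueError("need at least four non-partial days excluding day 0")
    t = np.asarray([p[0] for p in pts], dtype=float)
    y = np.asarray([p[1] for p in pts], dtype=float)

    def model(tt, plateau, day0, tau):
        return plateau - (plateau - day0) * np.exp(-tt / tau)

    if np.allclose(y, y[0]):
        return AdaptationFit(float(y[0]), float(y[0]), 1.0, 0.0)

    # Bounded fit: with tau free to exceed the observed span the model
    # degenerates into a straight line and the plateau becomes pure
    # extrapolation, so tau is capped at the span and the levels at twice
    # the observed maximum.
    p0 = (float(y.max()), float(max(y.min(), 1.0)), min(3.0, float(t.max()) / 2))
    upper_level = 2.0 * float(y.max())
    upper_tau = max(float(t.max() - t.min()), 1.0)
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=p0,
            bounds=([0.0, 0.0, 1e-6], [upper_level, upper_level, upper_tau]),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"adaptation fit did not converge on {len(pts)} days "
            f"(t in [{t.min():.0f}, {t.max():.0f}]): {exc}"
        ) from exc
    resid = y - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    return AdaptationFit(float(popt[0]), float(popt[1]), float(popt[2]), rms)


def feature_shift_test(
    pre_features: Sequence[float],
    post_features: Sequence[float],
    escape_direction: int,
) -> tuple[float, str]:
    """Directional z-score test for an operant shift of the syllable feature.

    ``escape_direction`` is +1 when larger feature values move the syllable
    away from the noise-triggering region, -1 when smaller values do.  The
    post-exposure mean is z-scored against the pre-exposure distribution
    (z = (mean_post - mean_pre) / (sd_pre / sqrt(n_post))); classification
    is ``shifted_away``/``shifted_toward`` when |z| exceeds the two-sided 1%
    critical value in the corresponding direction, else ``maintained``.
    """
    a = np.asarray(pre_features, dtype=float)
    b = np.asarray(post_features, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if escape_direction not in (-1, 1):
        raise ValueError("escape_direction must be +1 or -1")
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    if sd == 0:
        raise ValueError("pre-exposure feature variance is zero")
    z = float((b.mean() - a.mean()) / (sd / math.sqrt(b.size)))
    if abs(z) <= _Z_CRIT_1PCT:
        return z, "maintained"
    away = (z > 0) == (escape_direction > 0)
    return z, "shifted_away" if away else "shifted_toward"
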
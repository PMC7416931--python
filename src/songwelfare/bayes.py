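"""Binned Bayesian posterior of a recent stressful manipulation.

Given a day's singing rate s and a binary manipulation indicator m (1 if a
putative stressor such as surgery or tethering occurred recently), the
posterior follows Bayes' theorem with empirical ingredients:

    P(m=1 | s) = P(s | m=1) P(m=1) / [ P(s | m=1) P(m=1) + P(s | m=0) P(m=0) ]

where the likelihoods P(s | m) are per-bin frequencies of the observed day
counts within each condition, and the prior P(m) is the sample proportion
N_m / (N_{m=1} + N_{m=0}).  Rates are discretized into logarithmic bins with
borders 10^i; because manipulated birds can sing zero motifs, a leading
[0, 1) bin is included by default (strict log-only binning is available).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "UNDEFINED",
    "PosteriorModel",
    "make_log_bins",
    "fit_posterior_model",
    "posterior_for_rate",
    "compute_prior",
]

#: Marker for a posterior that is undefined because the bin holds no data in
#: either condition.  Never silently 0 or 1.
UNDEFINED = float("nan")


def make_log_bins(
    i_min: int, i_max: int, include_zero_bin: bool = True
) -> np.ndarray:
    """Logarithmic bin edges 10^i for i in [i_min, i_max].

    Bins are half-open [lo, hi); with ``include_zero_bin`` a leading [0,
    10^i_min) bin is prepended so zero-motif days are representable.  Values
    at or above the top edge fall into the last bin (overflow rule applied
    at lookup, not here).
    """
    if i_min >= i_max:
        raise ValueError("i_min must be < i_max")
    edges = [10.0 ** i for i in range(i_min, i_max + 1)]
    if include_zero_bin:
        edges = [0.0] + edges
    return np.asarray(edges)


def compute_prior(n_m1: int, n_m0: int) -> float:
    """Sample-proportion prior P(m=1) = N_{m=1} / (N_{m=1} + N_{m=0})."""
    if n_m1 < 0 or n_m0 < 0:
        raise ValueError("counts must be non-negative")
    if n_m1 + n_m0 == 0:
        raise ValueError("at least one observation required")
    return n_m1 / (n_m1 + n_m0)


def _bin_of(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bin index per value, with top-edge overflow into last bin."""
    idx = np.searchsorted(edges, values, side="right") - 1
    last = len(edges) - 2
    return np.clip(idx, 0, last)


@dataclass(frozen=True)
class PosteriorModel:
    """Empirical binned posterior of a recent manipulation given singing rate."""

    bin_edges: tuple[float, ...]
    counts_m1: tuple[int, ...]
    counts_m0: tuple[int, ...]
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        nb = len(self.bin_edges) - 1
        if nb < 1:
            raise ValueError("need at least one bin")
        if len(self.counts_m1) != nb or len(self.counts_m0) != nb:
            raise ValueError("per-bin counts must match the number of bins")

    # -- derived quantities ----------------------------------------------

    @property
    def n_m1(self) -> int:
        return int(sum(self.counts_m1))

    @property
    def n_m0(self) -> int:
        return int(sum(self.counts_m0))

    @property
    def prior_m1(self) -> float:
        return compute_prior(self.n_m1, self.n_m0)

    def _likelihood(self, counts: tuple[int, ...]) -> np.ndarray:
        c = np.asarray(counts, dtype=float) + self.smoothing
        total = c.sum()
        return c / total if total > 0 else c

    @property
    def lik_m1(self) -> np.ndarray:
        return self._likelihood(self.counts_m1)

    @property
    def lik_m0(self) -> np.ndarray:
        return self._likelihood(self.counts_m0)

    @property
    def posterior(self) -> np.ndarray:
        """Per-bin P(m=1 | s); NaN where both conditions are empty."""
        p1 = self.prior_m1
        p0 = 1.0 - p1
        num = self.lik_m1 * p1
        den = num + self.lik_m0 * p0
        out = np.full(len(num), UNDEFINED)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        return out

    # -- persistence ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "bin_edges": list(self.bin_edges),
            "counts_m1": list(self.counts_m1),
            "counts_m0": list(self.counts_m0),
            "smoothing": self.smoothing,
            "prior_m1": self.prior_m1,
            "posterior": [
                None if math.isnan(p) else p for p in self.posterior
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PosteriorModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        payload = json.loads(text)
        return cls(
            bin_edges=tuple(payload["bin_edges"]),
            counts_m1=tuple(payload["counts_m1"]),
            counts_m0=tuple(payload["counts_m0"]),
            smoothing=payload.get("smoothing", 0.0),
        )


def fit_posterior_model(
    manip_counts: Sequence[float],
    baseline_counts: Sequence[float],
    bins: np.ndarray | Sequence[float] | None = None,
    *,
    smoothing: float = 0.0,
) -> PosteriorModel:
    """Fit the empirical binned posterior from two sets of day counts.

    ``manip_counts`` are singing rates on days shortly after a manipulation
    (m=1); ``baseline_counts`` are rates of unmanipulated birds (m=0).
    Likelihoods are within-condition bin frequencies (no smoothing by
    default; ``smoothing`` adds that pseudocount to every bin).
    """
    manip = np.asarray(manip_counts, dtype=float)
    base = np.asarray(baseline_counts, dtype=float)
    if manip.size == 0 or base.size == 0:
        raise ValueError("both conditions need at least one day count")
    if (manip < 0).any() or (base < 0).any():
        raise ValueError("singing rates must be non-negative")
    edges = np.asarray(bins) if bins is not None else make_log_bins(0, 4, True)
    nb = len(edges) - 1
    c1 = np.bincount(_bin_of(manip, edges), minlength=nb)
    c0 = np.bincount(_bin_of(base, edges), minlength=nb)
    return PosteriorModel(
        bin_edges=tuple(float(e) for e in edges),
        counts_m1=tuple(int(v) for v in c1),
        counts_m0=tuple(int(v) for v in c0),
        smoothing=smoothing,
    )


def posterior_for_rate(s: float, model: PosteriorModel) -> float:
    """Posterior P(m=1 | s) of the bin containing ``s`` (NaN if undefined)."""
    if s < 0:
        raise ValueError("singing rate must be >= 0")
    edges = np.asarray(model.bin_edges)
    if s < edges[0]:
        raise ValueError(
            f"rate {s} below the lowest bin edge {edges[0]}"
        )
    idx = int(_bin_of(np.asarray([s]), edges)[0])
    return float(model.posterior[idx])
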
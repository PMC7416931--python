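"""Per-rendition detection logs: read/write, outlier filtering, aggregation.

A detection log is a delimited text file with one row per detected syllable
rendition (bird id, ISO-8601 timestamp, label, acoustic feature value,
white-noise trigger flag).  This module applies the 5-standard-deviation
feature rejection filter used to suppress false-positive detections,
aggregates retained target renditions into daily motif counts keyed by the
light phase, and computes windowed white-noise trigger fractions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import BirdTimeline, DayCount

__all__ = [
    "LOG_FORMAT_VERSION",
    "LogParseError",
    "RenditionEvent",
    "FeatureReference",
    "DailySchedule",
    "read_rendition_log",
    "write_rendition_log",
    "filter_renditions",
    "aggregate_daily_counts",
    "trigger_fraction_window",
]

#: Versioned header comment written as the first line of every log file.
LOG_FORMAT_VERSION = "songwelfare-rendition-log v1"

_COLUMNS = ["bird_id", "timestamp", "label", "feature_value", "triggered_wn"]
_LABELS = frozenset({"target", "other", "noise"})


class LogParseError(ValueError):
    """Malformed detection log; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class RenditionEvent:
    """One detected syllable rendition."""

    bird_id: str
    timestamp: dt.datetime
    label: str  # target | other | noise
    feature_value: float
    triggered_wn: bool = False

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {sorted(_LABELS)}")
        if self.label == "target" and not np.isfinite(self.feature_value):
            raise ValueError("target renditions need a finite feature value")


@dataclass(frozen=True)
class FeatureReference:
    """Reference feature distribution of the targeted syllable.

    Renditions whose feature (pitch or duration, depending on the
    experiment) lies more than ``k_sd`` reference standard deviations from
    ``ref_mean`` are rejected as likely false positives.  The reference
    statistics are supplied by the caller (e.g. from a labeled sample of the
    first experiment days, or from the generator configuration).
    """

    ref_mean: float
    ref_sd: float
    k_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.ref_sd <= 0:
            raise ValueError("ref_sd must be > 0")
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")

    def in_range(self, value: float) -> bool:
        # strictly-greater-than k_sd is rejected; exactly k_sd is retained
        return abs(value - self.ref_mean) <= self.k_sd * self.ref_sd


@dataclass(frozen=True)
class DailySchedule:
    """Light-phase schedule; a 'day' is one lights-on window.

    Daily counts are keyed by the calendar date of lights-on, so a light
    phase that crosses midnight still forms a single day.  The default is a
    14/10 h day/night schedule with lights on at 07:00.
    """

    lights_on: dt.time = dt.time(7, 0)
    lights_off: dt.time = dt.time(21, 0)

    def __post_init__(self) -> None:
        if self.lights_on == self.lights_off:
            raise ValueError("light phase must have positive length")

    def day_of(self, ts: dt.datetime) -> dt.date:
        """Calendar date of the most recent lights-on at or before ``ts``.

        Events in the dark phase are assigned to the enclosing nearest day
        by the same rule: they join the light phase that most recently
        started.
        """
        if ts.time() >= self.lights_on:
            return ts.date()
        return ts.date() - dt.timedelta(days=1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_rendition_log(events: Iterable[RenditionEvent], path: str | Path) -> None:
    """Write events as a versioned, header-bearing CSV (UTF-8, ISO-8601)."""
    path = Path(path)
    rows = [
        {
            "bird_id": e.bird_id,
            "timestamp": e.timestamp.isoformat(),
            "label": e.label,
            "feature_value": repr(float(e.feature_value)),
            "triggered_wn": int(e.triggered_wn),
        }
        for e in events
    ]
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {LOG_FORMAT_VERSION}\n")
        frame.to_csv(fh, index=False)


def read_rendition_log(path: str | Path) -> list[RenditionEvent]:
    """Read a detection log; returns events sorted by timestamp.

    Raises :class:`LogParseError` naming the first offending line on missing
    columns, unparseable timestamps, bad labels, or non-numeric features.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        has_version = first.startswith("#")
        fh.seek(0)
        try:
            frame = pd.read_csv(fh, comment="#", dtype=str, skip_blank_lines=True)
        except pd.errors.ParserError as exc:
            raise LogParseError(str(exc)) from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise LogParseError(f"missing columns: {', '.join(missing)}", line=2 if has_version else 1)

    # data rows start after the optional version comment and the header
    offset = 3 if has_version else 2

    ts = pd.to_datetime(frame["timestamp"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise LogParseError(
            f"unparseable timestamp {frame['timestamp'].iloc[bad[0]]!r}",
            line=int(bad[0]) + offset,
        )
    feat = pd.to_numeric(frame["feature_value"], errors="coerce")
    bad = np.flatnonzero(feat.isna().to_numpy() & frame["feature_value"].notna().to_numpy())
    if bad.size:
        raise LogParseError(
            f"non-numeric feature_value {frame['feature_value'].iloc[bad[0]]!r}",
            line=int(bad[0]) + offset,
        )
    bad = np.flatnonzero(~frame["label"].isin(sorted(_LABELS)).to_numpy())
    if bad.size:
        raise LogParseError(
            f"unknown label {frame['label'].iloc[bad[0]]!r}",
            line=int(bad[0]) + offset,
        )
    trig = frame["triggered_wn"].astype(str).str.strip().str.lower()
    trig_bool = trig.isin({"1", "true", "t", "yes"})

    events = [
        RenditionEvent(
            bird_id=str(b),
            timestamp=t.to_pydatetime(),
            label=str(lab),
            feature_value=float(f),
            triggered_wn=bool(g),
        )
        for b, t, lab, f, g in zip(
            frame["bird_id"], ts, frame["label"], feat, trig_bool
        )
    ]
    events.sort(key=lambda e: e.timestamp)
    return events


# ---------------------------------------------------------------------------
# filtering and aggregation
# ---------------------------------------------------------------------------

def filter_renditions(
    events: Sequence[RenditionEvent], ref: FeatureReference
) -> list[RenditionEvent]:
    """Retain target-labeled events within ``k_sd`` reference sds of the mean.

    Non-target labels (calls, cage noise, detector false positives) are
    removed, as are target detections whose feature value lies strictly
    beyond the rejection boundary.  Order is preserved; the operation is
    idempotent.
    """
    return [
        e
        for e in events
        if e.label == "target" and ref.in_range(e.feature_value)
    ]


def aggregate_daily_counts(
    events: Sequence[RenditionEvent],
    schedule: DailySchedule | None = None,
    *,
    start_date: dt.date | None = None,
) -> BirdTimeline:
    """Aggregate one bird's (filtered) events into daily motif counts.

    One count per light-phase day, keyed by the calendar date of lights-on
    and converted to integer day indices relative to ``start_date`` (default:
    the first observed day).  Days without events inside the observed span
    are omitted (no count, rather than zero), since an empty day is
    indistinguishable from a recording gap at this level.
    """
    schedule = schedule or DailySchedule()
    if not events:
        return BirdTimeline("", ())
    bird_ids = {e.bird_id for e in events}
    if len(bird_ids) > 1:
        raise ValueError(
            f"events from multiple birds: {sorted(bird_ids)}"
        )
    per_day: dict[dt.date, int] = {}
    for e in events:
        day = schedule.day_of(e.timestamp)
        per_day[day] = per_day.get(day, 0) + 1
    origin = start_date or min(per_day)
    counts = tuple(
        DayCount((day - origin).days, n, False)
        for day, n in sorted(per_day.items())
    )
    return BirdTimeline(bird_ids.pop(), counts)


def trigger_fraction_window(
    events: Sequence[RenditionEvent],
    day: dt.date | int,
    window: str = "first",
    n: int = 200,
    schedule: DailySchedule | None = None,
) -> float:
    """Fraction of WN-triggering renditions among the first/last ``n`` of a day.

    ``day`` selects one light-phase day, either as a calendar date or as a
    day index counted from the first observed day.  Only target-labeled
    events are considered; they are taken in time order.
    """
    if window not in {"first", "last"}:
        raise ValueError("window must be 'first' or 'last'")
    if n <= 0:
        raise ValueError("n must be > 0")
    schedule = schedule or DailySchedule()
    target = sorted(
        (e for e in events if e.label == "target"), key=lambda e: e.timestamp
    )
    days = sorted({schedule.day_of(e.timestamp) for e in target})
    if isinstance(day, int):
        if not days:
            raise ValueError("no target events")
        day = min(days) + dt.timedelta(days=day)
    day_events = [e for e in target if schedule.day_of(e.timestamp) == day]
    if len(day_events) < n:
        raise ValueError(
            f"day {day} has {len(day_events)} target events, fewer than n={n}"
        )
    chosen = day_events[:n] if window == "first" else day_events[-n:]
    return sum(e.triggered_wn for e in chosen) / n
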
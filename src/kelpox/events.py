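"""Hypoxic-event detection and per-site exposure summaries.

A hypoxic event is a maximal run of consecutive valid oxygen samples at or
below the hypoxia threshold (conventionally 2 mg/L) lasting at least a
minimum duration (one hour). Events whose minimum falls below the severe
threshold (0.05 mg/L, near-anoxia) are flagged. Exposure at a site is then
summarised by the event count, mean event duration, mean return time
(end of one event to the start of the next), together with scalar variability
metrics of the oxygen record (minimum, coefficient of variation, mean
absolute rate of change) and mean/maximum temperature.

Conventions, chosen where field practice varies:

* comparator: DO <= threshold counts as exposure (configurable to strict <);
* duration = number of below-threshold samples x grid interval, so six
  consecutive 10-min samples constitute a 1.0-h exposure;
* runs separated only by invalid samples are merged when the dropout is
  shorter than ``max_gap_minutes`` — a brief sensor dropout inside one
  exposure should not split it in two; a valid above-threshold sample
  always separates events;
* events are attributed to the calendar month of their start instant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ValidationError
from .series import SensorSeries, regularize

__all__ = [
    "HypoxicEvent",
    "ExposureSummary",
    "MonthlyEventProportions",
    "detect_hypoxic_events",
    "return_times",
    "summarize_exposure",
    "monthly_event_proportions",
]

HYPOXIA_THRESHOLD_MGL = 2.0
SEVERE_THRESHOLD_MGL = 0.05
MIN_EVENT_DURATION_H = 1.0


@dataclass(frozen=True)
class HypoxicEvent:
    site_id: str
    start: pd.Timestamp
    end: pd.Timestamp  # last below-threshold sample
    duration_h: float
    min_do_mgL: float
    severe: bool
    n_samples: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError("event end precedes start")


@dataclass(frozen=True)
class ExposureSummary:
    """Per-site scalar exposure metrics.

    ``mean_duration_h`` is None when no events occurred;
    ``mean_return_time_h`` is None when fewer than two events occurred.
    """

    site_id: str
    mean_temp_C: float
    max_temp_C: float
    min_do_mgL: float
    do_cv: float
    mean_abs_rate_mgL_per_h: float
    n_events: int
    mean_duration_h: float | None
    mean_return_time_h: float | None
    any_hypoxia: bool


@dataclass(frozen=True)
class MonthlyEventProportions:
    """Share of a site's events starting in each calendar month (Jan-Dec)."""

    site_id: str
    proportions: tuple  # 12 floats, Jan..Dec

    def __post_init__(self) -> None:
        if len(self.proportions) != 12:
            raise ValidationError("proportions must have 12 entries")


def detect_hypoxic_events(
    series: SensorSeries,
    threshold_mgL: float = HYPOXIA_THRESHOLD_MGL,
    min_duration_h: float = MIN_EVENT_DURATION_H,
    severe_threshold_mgL: float = SEVERE_THRESHOLD_MGL,
    max_gap_minutes: float = 30.0,
    strict: bool = False,
) -> list[HypoxicEvent]:
    """Find maximal below-threshold runs meeting the minimum duration.

    Parameters
    ----------
    threshold_mgL
        Hypoxia threshold; a sample counts when DO <= threshold
        (DO < threshold when ``strict``).
    min_duration_h
        Minimum qualifying duration; duration counts below-threshold
        samples times the grid interval.
    max_gap_minutes
        Two below-threshold runs separated *only* by invalid samples
        spanning at most this long are merged into one event.
    """
    if threshold_mgL <= 0:
        raise ValidationError("threshold must be positive")
    s = regularize(series)
    do = s.do_mgL
    valid = s.do_valid
    if strict:
        below = valid & (do < threshold_mgL)
    else:
        below = valid & (do <= threshold_mgL)
    if not below.any():
        return []

    # maximal candidate runs of consecutive below samples
    padded = np.concatenate(([False], below, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]  # [start, stop) index pairs

    # merge runs separated only by invalid samples within the gap allowance
    max_gap_samples = int(max_gap_minutes // s.interval_minutes)
    merged: list[list[int]] = [[int(starts[0]), int(stops[0])]]
    for a, b in zip(starts[1:], stops[1:]):
        prev = merged[-1]
        gap = slice(prev[1], a)
        gap_len = a - prev[1]
        if gap_len <= max_gap_samples and not valid[gap].any():
            prev[1] = int(b)
        else:
            merged.append([int(a), int(b)])

    interval_h = s.interval_minutes / 60.0
    events = []
    for a, b in merged:
        run = slice(a, b)
        n_below = int(below[run].sum())
        duration_h = n_below * interval_h
        if duration_h < min_duration_h:
            continue
        idx = np.flatnonzero(below[run]) + a
        min_do = float(do[idx].min())
        events.append(
            HypoxicEvent(
                site_id=s.site_id,
                start=s.timestamps[idx[0]],
                end=s.timestamps[idx[-1]],
                duration_h=duration_h,
                min_do_mgL=min_do,
                severe=min_do < severe_threshold_mgL,
                n_samples=n_below,
            )
        )
    return events


def return_times(events: list[HypoxicEvent]) -> list[float]:
    """Hours from the end of each event to the start of the next."""
    if len(events) < 2:
        return []
    out = []
    for prev, nxt in zip(events, events[1:]):
        out.append((nxt.start - prev.end) / pd.Timedelta(hours=1))
    return out


def summarize_exposure(
    series: SensorSeries,
    events: list[HypoxicEvent],
    cv_ddof: int = 1,
) -> ExposureSummary:
    """Scalar exposure metrics for one site.

    The DO coefficient of variation uses the sample (n-1) standard
    deviation by default (``cv_ddof=0`` for the population convention).
    The mean absolute rate of change averages |dDO|/dt over adjacent valid
    pairs exactly one grid step apart; pairs spanning gaps are excluded.
    """
    s = regularize(series)
    tmask, dmask = s.temp_valid, s.do_valid
    if not (tmask.any() or dmask.any()):
        raise EmptyInputError(f"site {s.site_id}: no valid samples")
    temp = s.temperature_C[tmask]
    do = s.do_mgL[dmask]
    if do.size == 0:
        raise EmptyInputError(f"site {s.site_id}: no valid DO samples")

    do_mean = float(do.mean())
    do_sd = float(do.std(ddof=cv_ddof)) if do.size > cv_ddof else 0.0
    do_cv = do_sd / do_mean if do_mean != 0 else np.nan

    pair = dmask[:-1] & dmask[1:]
    interval_h = s.interval_minutes / 60.0
    if pair.any():
        rate = float(np.abs(np.diff(s.do_mgL))[pair].mean()) / interval_h
    else:
        rate = np.nan

    rts = return_times(events)
    return ExposureSummary(
        site_id=s.site_id,
        mean_temp_C=float(temp.mean()) if temp.size else np.nan,
        max_temp_C=float(temp.max()) if temp.size else np.nan,
        min_do_mgL=float(do.min()),
        do_cv=do_cv,
        mean_abs_rate_mgL_per_h=rate,
        n_events=len(events),
        mean_duration_h=(float(np.mean([e.duration_h for e in events]))
                         if events else None),
        mean_return_time_h=float(np.mean(rts)) if rts else None,
        any_hypoxia=bool(events),
    )


def monthly_event_proportions(events: list[HypoxicEvent]) -> MonthlyEventProportions:
    """Share of events starting in each calendar month; sums to one.

    Events are attributed to their start month only; an exposure spanning a
    month boundary is not split.
    """
    if not events:
        raise EmptyInputError("monthly proportions undefined for zero events")
    counts = np.zeros(12, dtype=int)
    for e in events:
        counts[e.start.month - 1] += 1
    props = counts / counts.sum()
    return MonthlyEventProportions(
        site_id=events[0].site_id, proportions=tuple(float(p) for p in props)
    )
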
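"""Vessel-noise dominance and exceedance indicators.

*Dominance* measures how much of the monitored time contains vessel noise:
the percentage of sampled hours (or minutes) overlapped by at least one
acoustic vessel detection.  *Exceedance* measures how much noise vessels add
when present: the difference between 125 Hz decidecade band levels during
vessel detections and vessel-free reference levels.  Exceedance can be
negative when other low-frequency sources (fish choruses, wind) raise levels
in vessel-free periods above those measured during detections.

All level arithmetic is done in dB except where a power average is explicitly
required (the minute-exceedance baseline), which is computed as the linear
mean-square mean converted back to dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .bands import BandLevelSeries, from_db, to_db
from .detector import VesselDetectionEvent
from .errors import InvalidArgumentError, UndefinedMetricError

__all__ = [
    "DominanceSummary",
    "ExceedanceRecord",
    "HourOfDayProfile",
    "dominance_percent_hours",
    "hourly_exceedance",
    "minute_exceedance",
    "hour_of_day_profile",
]


def month_bounds(month: str | pd.Period) -> tuple[pd.Timestamp, pd.Timestamp]:
    """UTC [start, end) of a calendar month given ``'YYYY-MM'`` or a Period."""
    p = pd.Period(month, freq="M")
    start = p.to_timestamp(how="start").tz_localize("UTC")
    return start, start + pd.offsets.MonthBegin(1)


def _vessel_events(events: Iterable[VesselDetectionEvent]) -> list[VesselDetectionEvent]:
    return [e for e in events if e.label == "vessel"]


def _bins_overlapped(
    bin_starts: pd.DatetimeIndex, bin_seconds: float, events: Sequence[VesselDetectionEvent]
) -> np.ndarray:
    """Boolean mask over time bins: True where any event overlaps the bin."""
    mask = np.zeros(len(bin_starts), dtype=bool)
    if len(bin_starts) == 0:
        return mask
    ends = bin_starts + pd.Timedelta(seconds=bin_seconds)
    for ev in events:
        mask |= (bin_starts < ev.end) & (ends > ev.start)
    return mask


@dataclass
class DominanceSummary:
    """Monthly vessel-noise dominance at hourly resolution plus detection stats."""

    month: str
    percent_hours_dominant: float
    n_vessel_hours: int
    n_sampled_hours: int
    counts_per_day: pd.Series = field(repr=False)
    count_month: int = 0
    durations_min: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)


@dataclass
class ExceedanceRecord:
    """One exceedance measurement (hourly/monthly or per-event minute resolution)."""

    resolution: Literal["hourly", "minute"]
    value_db: float | None = None  # hourly: single monthly value
    median_diff_db: float | None = None  # minute resolution, per event
    max_diff_db: float | None = None
    baseline_start: pd.Timestamp | None = None
    baseline_end: pd.Timestamp | None = None
    n_vessel: int = 0
    n_non_vessel: int = 0


@dataclass
class HourOfDayProfile:
    """Mean minutes of each clock hour dominated by vessel noise, with SE."""

    mean_minutes: np.ndarray  # 24 entries
    se_minutes: np.ndarray  # 24 entries
    n_days: int


def dominance_percent_hours(
    events: Iterable[VesselDetectionEvent],
    sampled_hours: pd.DatetimeIndex,
    month: str | pd.Period | None = None,
) -> DominanceSummary:
    """Percent of sampled hours with at least one vessel detection in a month.

    An hour counts as a vessel hour if any vessel-labelled event overlaps it,
    even partially.  ``sampled_hours`` enumerates the hour starts with valid
    band-level coverage; hours outside ``month`` (if given) are dropped.
    """
    sampled_hours = pd.DatetimeIndex(sampled_hours)
    vessel = _vessel_events(events)
    if month is not None:
        m0, m1 = month_bounds(month)
        sampled_hours = sampled_hours[(sampled_hours >= m0) & (sampled_hours < m1)]
        vessel = [e for e in vessel if e.overlaps(m0, m1)]
        month_str = str(pd.Period(month, freq="M"))
    else:
        month_str = ""
    if len(sampled_hours) == 0:
        raise UndefinedMetricError("no sampled hours: dominance undefined")
    mask = _bins_overlapped(sampled_hours, 3600.0, vessel)
    starts = pd.DatetimeIndex([e.start for e in vessel])
    counts_per_day = (
        pd.Series(1, index=starts).groupby(starts.floor("D")).sum()
        if len(starts)
        else pd.Series(dtype=int)
    )
    return DominanceSummary(
        month=month_str,
        percent_hours_dominant=100.0 * mask.sum() / len(sampled_hours),
        n_vessel_hours=int(mask.sum()),
        n_sampled_hours=len(sampled_hours),
        counts_per_day=counts_per_day,
        count_month=len(vessel),
        durations_min=np.array([e.duration_s / 60.0 for e in vessel]),
    )


def hourly_exceedance(
    hourly_levels: BandLevelSeries,
    events: Iterable[VesselDetectionEvent],
    month: str | pd.Period | None = None,
    statistic: Literal["median", "mean"] = "median",
) -> ExceedanceRecord:
    """Monthly low-frequency vessel-noise exceedance at hourly resolution.

    value = statistic(levels of vessel hours) − statistic(levels of
    non-vessel hours), in dB; an hour is a vessel hour iff at least one
    vessel event overlaps it.  The default statistic is the median of the
    hourly dB levels; the mean (dB domain) is available as a config switch.
    """
    if hourly_levels.resolution != "hour":
        raise InvalidArgumentError("hourly_exceedance requires an hourly series")
    times = hourly_levels.times
    levels = hourly_levels.levels_db
    valid = np.isfinite(levels)
    if month is not None:
        m0, m1 = month_bounds(month)
        valid &= (times >= m0) & (times < m1)
    mask = _bins_overlapped(times, 3600.0, _vessel_events(events))
    v = levels[valid & mask]
    nv = levels[valid & ~mask]
    if v.size == 0 or nv.size == 0:
        raise UndefinedMetricError(
            f"need both classes: {v.size} vessel / {nv.size} non-vessel hours"
        )
    stat = np.median if statistic == "median" else np.mean
    return ExceedanceRecord(
        resolution="hourly",
        value_db=float(stat(v) - stat(nv)),
        n_vessel=int(v.size),
        n_non_vessel=int(nv.size),
    )


def minute_exceedance(
    event: VesselDetectionEvent,
    minute_levels: BandLevelSeries,
    all_events: Iterable[VesselDetectionEvent],
) -> ExceedanceRecord:
    """Per-event exceedance against the nearest-in-time vessel-free window.

    The event's minutes are compared with a vessel-free reference window of
    the same duration (same number of minute bins): the baseline is the dB
    value of the linear power mean over that window.  Candidate windows are
    contiguous runs of minutes that overlap no vessel event and have valid
    levels; the window with the smallest time gap to the event wins, with the
    earlier window taking ties.  Both a median and a maximum difference are
    reported.
    """
    if minute_levels.resolution != "minute":
        raise InvalidArgumentError("minute_exceedance requires a minute series")
    times = minute_levels.times
    levels = minute_levels.levels_db
    finite = np.isfinite(levels)
    vessel = _vessel_events(all_events)
    vessel_mask = _bins_overlapped(times, 60.0, vessel)

    ends = times + pd.Timedelta(seconds=60)
    in_event = (times < event.end) & (ends > event.start) & finite
    n = int(in_event.sum())
    if n == 0:
        raise UndefinedMetricError("event overlaps no valid minute bins")
    ev_levels = levels[in_event]

    ok = finite & ~vessel_mask
    # exhaustive same-length window search over the minute grid
    best: tuple[float, pd.Timestamp, int] | None = None
    for ws in range(len(times) - n + 1):
        if not ok[ws : ws + n].all():
            continue
        w0, w1 = times[ws], times[ws + n - 1] + pd.Timedelta(seconds=60)
        if w1 <= event.start:
            gap = (event.start - w1).total_seconds()
        elif w0 >= event.end:
            gap = (w0 - event.end).total_seconds()
        else:  # cannot happen: ok-windows exclude event minutes
            gap = 0.0
        if best is None or gap < best[0]:
            best = (gap, w0, ws)
    if best is None:
        raise UndefinedMetricError("no vessel-free window of matching duration")
    _, w0, ws = best
    baseline = float(to_db(from_db(levels[ws : ws + n]).mean()))
    return ExceedanceRecord(
        resolution="minute",
        median_diff_db=float(np.median(ev_levels) - baseline),
        max_diff_db=float(np.max(ev_levels) - baseline),
        baseline_start=w0,
        baseline_end=w0 + pd.Timedelta(seconds=60 * n),
        n_vessel=n,
        n_non_vessel=n,
    )


def hour_of_day_profile(
    events: Iterable[VesselDetectionEvent],
    month: str | pd.Period,
    minute_levels: BandLevelSeries | None = None,
) -> HourOfDayProfile:
    """Minutes per clock hour dominated by vessel noise, averaged over days.

    For each hour-of-day h the value is the mean over days of the month of
    the number of minute bins of hour h overlapped by at least one vessel
    event; SE is the sample standard deviation across days divided by
    √(days).  If a minute-level series is given, only its days with at least
    50% minute coverage enter the average; otherwise all days of the month do.
    """
    m0, m1 = month_bounds(month)
    if minute_levels is not None:
        t = minute_levels.times
        fin = np.isfinite(minute_levels.levels_db)
        per_day = pd.Series(fin, index=t).groupby(t.floor("D")).sum()
        days = per_day.index[per_day >= 720]
        days = days[(days >= m0) & (days < m1)]
    else:
        days = pd.date_range(m0, m1, freq="D", inclusive="left")
    n_days = len(days)
    mean = np.zeros(24)
    se = np.zeros(24)
    if n_days == 0:
        return HourOfDayProfile(mean, se, 0)

    vessel = _vessel_events(events)
    tally = np.zeros((n_days, 24))
    for di, day in enumerate(days):
        minute_starts = pd.date_range(day, periods=1440, freq="min")
        overlapped = _bins_overlapped(minute_starts, 60.0, vessel)
        tally[di] = overlapped.reshape(24, 60).sum(axis=1)
    mean = tally.mean(axis=0)
    if n_days > 1:
        se = tally.std(axis=0, ddof=1) / np.sqrt(n_days)
    return HourOfDayProfile(mean_minutes=mean, se_minutes=se, n_days=n_days)
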
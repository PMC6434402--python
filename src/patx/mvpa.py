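"""Personalized target heart zones and MVPA bout detection.

The target-zone minimum follows the Karvonen heart-rate-reserve formula

    HRR      = max_hr - rhr
    zone_min = HRR * Y + rhr          (Y = 0.5 by default)

computed per subject per day so the resting heart rate can drift over the
study.  Maximal HR defaults to the age-predicted 220 - age unless given
explicitly.  When no resting-HR input is available, the day's RHR is
estimated as the mean of its 30 lowest recorded minute values.

A minute is "in zone" iff its (possibly imputed) heart rate is at or
above ``zone_min`` — the zone has no upper cutoff.  A bout of
moderate-to-vigorous physical activity (MVPA) is a run of at least 10
consecutive in-zone minutes; runs separated by a single out-of-zone
minute are combined first (the dip is treated as a device artifact or a
momentary drop), and the bridged minute counts toward bout duration by
default.  The daily sum of bout durations is the day's *target minutes*.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hr_io import MINUTES_PER_DAY, MinuteSeries

__all__ = [
    "ZoneParams",
    "Bout",
    "DayProfile",
    "karvonen_zone",
    "estimate_rhr",
    "daily_zone_params",
    "in_zone_mask",
    "detect_bouts",
    "target_minutes",
]


@dataclass(frozen=True)
class ZoneParams:
    """Karvonen target-zone parameters for one subject-day."""

    rhr: float
    max_hr: float
    y: float = 0.5

    def __post_init__(self) -> None:
        if not 25 <= self.rhr < self.max_hr <= 230:
            raise ValueError(
                f"require 25 <= rhr < max_hr <= 230, got rhr={self.rhr}, "
                f"max_hr={self.max_hr}"
            )
        if not 0 < self.y <= 1:
            raise ValueError(f"intensity constant y must be in (0, 1], got {self.y}")

    @property
    def hrr(self) -> float:
        """Heart-rate reserve, beats/min."""
        return self.max_hr - self.rhr

    @property
    def zone_min(self) -> float:
        """Target-zone lower bound = HRR * y + RHR, beats/min."""
        return self.hrr * self.y + self.rhr


def karvonen_zone(rhr: float, max_hr: float, y: float = 0.5) -> ZoneParams:
    """Build zone parameters from resting and maximal heart rate."""
    return ZoneParams(rhr=rhr, max_hr=max_hr, y=y)


def estimate_rhr(day: MinuteSeries, n_lowest: int = 30) -> float:
    """Fallback resting-HR estimator: mean of the day's ``n_lowest``
    lowest present minute values.

    Raises ``ValueError`` when fewer than ``n_lowest`` minutes are
    present.
    """
    present = day.hr[day.present_mask]
    if present.size < n_lowest:
        raise ValueError(
            f"resting-HR estimate needs >= {n_lowest} present minutes, "
            f"day has {present.size}"
        )
    return float(np.mean(np.sort(present)[:n_lowest]))


def daily_zone_params(
    day: MinuteSeries,
    subject_age: float | None = None,
    rhr: float | None = None,
    y: float = 0.5,
    max_hr: float | None = None,
) -> ZoneParams:
    """Zone parameters for one subject-day.

    ``max_hr`` defaults to the age-predicted 220 - age; an explicit value
    overrides.  ``rhr`` comes from a per-day input when supplied, else
    from :func:`estimate_rhr` on the day itself.
    """
    if max_hr is None:
        if subject_age is None:
            raise ValueError("need subject_age or an explicit max_hr")
        max_hr = 220.0 - float(subject_age)
    if rhr is None:
        rhr = estimate_rhr(day)
    return ZoneParams(rhr=float(rhr), max_hr=float(max_hr), y=y)


def in_zone_mask(day: MinuteSeries, zone: ZoneParams) -> np.ndarray:
    """Boolean length-1440 mask: HR present (or imputed) and >= zone_min.

    Missing minutes are out of zone.  The lower bound is inclusive.
    """
    hr = day.hr
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(hr), False, hr >= zone.zone_min)


@dataclass(frozen=True)
class Bout:
    """One MVPA bout: half-open minute interval within a day."""

    start_slot: int
    end_slot: int
    #: minutes actually in zone (excludes bridged out-of-zone minutes)
    in_zone_minutes: int
    date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.end_slot <= self.start_slot:
            raise ValueError("empty bout interval")

    @property
    def duration_minutes(self) -> int:
        """Elapsed duration, bridged minutes included."""
        return self.end_slot - self.start_slot


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open (start, end)."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def detect_bouts(
    mask: Sequence[bool] | np.ndarray,
    min_bout: int = 10,
    merge_gap: int = 1,
    merge_before_filter: bool = True,
    date: dt.date | None = None,
) -> list[Bout]:
    """Detect MVPA bouts from an in-zone minute mask.

    Maximal in-zone runs are found; runs separated by at most
    ``merge_gap`` out-of-zone minutes are combined left to right (chains
    collapse: A-1-B-1-C becomes one bout); merged runs shorter than
    ``min_bout`` elapsed minutes are discarded.  With
    ``merge_before_filter=False`` the stricter reading applies: only runs
    already of length >= ``min_bout`` are kept, and merging happens
    between those qualifying bouts afterwards.

    ``merge_gap=0`` disables merging.
    """
    mask = np.asarray(mask, dtype=bool)
    runs = _runs(mask)

    def merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
        if merge_gap <= 0 or not intervals:
            return intervals
        merged = [intervals[0]]
        for s, e in intervals[1:]:
            ps, pe = merged[-1]
            if s - pe <= merge_gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        return merged

    if merge_before_filter:
        intervals = merge(runs)
        intervals = [(s, e) for s, e in intervals if e - s >= min_bout]
    else:
        qualifying = [(s, e) for s, e in runs if e - s >= min_bout]
        intervals = merge(qualifying)

    bouts = []
    for s, e in intervals:
        in_zone = int(mask[s:e].sum())
        bouts.append(Bout(start_slot=s, end_slot=e, in_zone_minutes=in_zone, date=date))
    return bouts


def target_minutes(bouts: Sequence[Bout], count_bridged: bool = True) -> int:
    """Daily target minutes: sum of bout durations.

    With ``count_bridged=True`` (default) the elapsed-time convention is
    used and bridged out-of-zone minutes count; otherwise only in-zone
    minutes are summed.  Overlapping bouts are rejected.
    """
    ordered = sorted(bouts, key=lambda b: b.start_slot)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_slot < a.end_slot:
            raise ValueError(f"overlapping bouts at slots {a.end_slot}/{b.start_slot}")
    if count_bridged:
        return sum(b.duration_minutes for b in ordered)
    return sum(b.in_zone_minutes for b in ordered)


@dataclass
class DayProfile:
    """Everything derived for one subject-day."""

    subject_id: str
    date: dt.date
    wear_minutes: int
    compliant: bool
    zone: ZoneParams | None = None
    bouts: list[Bout] = field(default_factory=list)
    target_minutes: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_minutes <= MINUTES_PER_DAY:
            raise ValueError("target_minutes outside [0, 1440]")
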
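"""Wear-time compliance: daily flags, cohort selection, threshold sweep.

A day counts as worn at a given minute iff a heart-rate value is present
at that minute — no further off-wrist heuristic.  Wear time is always
computed *before* imputation.  A day is compliant when its wear minutes
reach ``round(daily_fraction * 1440)`` (1152 min, i.e. 19.2 h, at the
default 80%).  Cohort selection keeps subjects whose least compliant
semester still exceeds ``min_days_per_semester`` (strictly, by default).
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .hr_io import MINUTES_PER_DAY, MinuteSeries, StudyCalendar

__all__ = [
    "ComplianceConfig",
    "ComplianceSummary",
    "wear_minutes",
    "is_compliant",
    "summarize_compliance",
    "select_cohort",
    "wear_threshold_sweep",
    "gap_length_profile",
    "gap_lengths",
]


@dataclass(frozen=True)
class ComplianceConfig:
    """Compliance thresholds.

    daily_fraction
        Fraction of the 1440-minute day that must be worn; default 0.80,
        i.e. a 1152-minute threshold.
    min_days_per_semester
        A subject is retained when every semester has *more* than this
        many compliant days (comparator configurable); default 49.
    comparator
        ``"gt"`` (strictly above, default) or ``"ge"``.
    """

    daily_fraction: float = 0.80
    min_days_per_semester: int = 49
    comparator: Literal["gt", "ge"] = "gt"

    def __post_init__(self) -> None:
        if not 0 < self.daily_fraction <= 1:
            raise ValueError("daily_fraction must be in (0, 1]")
        if self.min_days_per_semester < 0:
            raise ValueError("min_days_per_semester must be >= 0")

    @property
    def min_wear_minutes(self) -> int:
        return int(round(self.daily_fraction * MINUTES_PER_DAY))


def wear_minutes(day: MinuteSeries) -> int:
    """Count of minutes with a recorded heart rate (pre-imputation)."""
    return day.n_present


def is_compliant(day: MinuteSeries, cfg: ComplianceConfig | None = None) -> bool:
    """True iff the day's wear minutes meet the daily-fraction threshold."""
    cfg = cfg or ComplianceConfig()
    return wear_minutes(day) >= cfg.min_wear_minutes


@dataclass
class ComplianceSummary:
    """Per-subject compliance bookkeeping used by cohort selection."""

    subject_id: str
    #: date -> wear minutes for every materialized day
    day_wear: dict[dt.date, int] = field(default_factory=dict)
    #: date -> compliant flag
    day_compliant: dict[dt.date, bool] = field(default_factory=dict)
    #: semester name -> count of compliant days
    semester_counts: dict[str, int] = field(default_factory=dict)

    @property
    def least_compliant_semester_count(self) -> int:
        if not self.semester_counts:
            return 0
        return min(self.semester_counts.values())


def summarize_compliance(
    days: Iterable[MinuteSeries],
    cfg: ComplianceConfig,
    calendar: StudyCalendar,
) -> dict[str, ComplianceSummary]:
    """Build per-subject summaries over the calendar's semesters.

    Days inside excluded break ranges do not count toward semester
    compliance.  Semesters that end before a subject's enrollment window
    (when the calendar records one) are ignored for that subject; any
    other semester with no compliant days counts 0.
    """
    summaries: dict[str, ComplianceSummary] = {}
    for day in days:
        s = summaries.setdefault(day.subject_id, ComplianceSummary(day.subject_id))
        w = wear_minutes(day)
        s.day_wear[day.date] = w
        s.day_compliant[day.date] = w >= cfg.min_wear_minutes

    for s in summaries.values():
        enroll = calendar.enrollment.get(s.subject_id)
        for name, (start, end) in calendar.semesters.items():
            if enroll is not None and end <= enroll[0]:
                continue  # subject not yet enrolled in this semester
            count = sum(
                1
                for date, ok in s.day_compliant.items()
                if ok and start <= date < end and not calendar.is_excluded(date)
            )
            s.semester_counts[name] = count
    return summaries


def select_cohort(
    summaries: dict[str, ComplianceSummary],
    cfg: ComplianceConfig,
    calendar: StudyCalendar,
) -> set[str]:
    """Subjects whose least compliant semester passes the day-count rule."""
    selected = set()
    for sid, s in summaries.items():
        least = s.least_compliant_semester_count
        if cfg.comparator == "gt":
            ok = least > cfg.min_days_per_semester
        else:
            ok = least >= cfg.min_days_per_semester
        if ok and s.semester_counts:
            selected.add(sid)
    return selected


def wear_threshold_sweep(
    days: Sequence[MinuteSeries],
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Eligible-day counts while sweeping the daily wear threshold.

    For each threshold fraction (default 1.0 down to 0.0 in steps of 0.1)
    counts days whose wear fraction is at or above it.  Returns a frame
    with columns ``threshold``, ``eligible_day_count``,
    ``cumulative_fraction``; counts are nondecreasing as the threshold
    drops.
    """
    if len(days) == 0:
        raise ValueError("wear_threshold_sweep requires at least one day")
    if thresholds is None:
        thresholds = [round(1.0 - 0.1 * k, 1) for k in range(11)]
    fractions = np.array([wear_minutes(d) / MINUTES_PER_DAY for d in days])
    rows = []
    for thr in thresholds:
        count = int((fractions >= thr - 1e-12).sum())
        rows.append(
            {
                "threshold": thr,
                "eligible_day_count": count,
                "cumulative_fraction": count / len(days),
            }
        )
    return pd.DataFrame(rows)


def gap_lengths(day: MinuteSeries) -> list[int]:
    """Lengths of maximal runs of missing minutes within one day."""
    missing = np.isnan(day.hr)
    if not missing.any():
        return []
    padded = np.concatenate(([False], missing, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return (ends - starts).tolist()


def gap_length_profile(days: Iterable[MinuteSeries]) -> Counter:
    """Pooled multiset of missing-run lengths across subject-days.

    Gaps spanning midnight are split at the day boundary by construction
    of the per-day data model.  Used to parameterize the imputation
    benchmark and the synthetic generator.
    """
    counter: Counter = Counter()
    for day in days:
        counter.update(gap_lengths(day))
    return counter
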
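"""Minute-level heart-rate I/O and the core data model.

A subject-day is held as a :class:`MinuteSeries`: a fixed vector of 1440
heart-rate slots (slot ``k`` = minute ``k`` of the local day, 0-based),
with ``NaN`` marking minutes for which the device recorded nothing.
Days are forced to 1440 slots regardless of daylight-saving anomalies;
readings that would fall beyond slot 1439 are dropped with a warning.

The study calendar — which calendar months are under observation, which
date ranges (breaks) are excluded, how the observation window splits into
semesters, and the seasonal period used downstream — is a
:class:`StudyCalendar` loaded from YAML or JSON.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MINUTES_PER_DAY",
    "HR_MIN",
    "HR_MAX",
    "MinuteSeries",
    "StudyCalendar",
    "IngestError",
    "read_minute_hr",
    "write_day_profiles",
    "read_day_profiles",
    "load_calendar",
    "default_calendar",
]

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440
#: Physiological plausibility bounds; readings outside are rejected at ingest.
HR_MIN = 25.0
HR_MAX = 250.0


class IngestError(ValueError):
    """Raised when an input file violates the ingest contract."""


@dataclass
class MinuteSeries:
    """One subject-day of minute-resolution heart rate.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    date
        Calendar date of the day (local clock).
    hr
        Length-1440 float array; ``NaN`` marks missing minutes. Present
        values must lie in ``[25, 250]`` beats/min.
    """

    subject_id: str
    date: dt.date
    hr: np.ndarray

    def __post_init__(self) -> None:
        self.hr = np.asarray(self.hr, dtype=float)
        if self.hr.shape != (MINUTES_PER_DAY,):
            raise ValueError(
                f"hr must have exactly {MINUTES_PER_DAY} slots, got {self.hr.shape}"
            )
        present = self.hr[~np.isnan(self.hr)]
        if present.size and (present.min() < HR_MIN or present.max() > HR_MAX):
            bad = present[(present < HR_MIN) | (present > HR_MAX)][0]
            raise ValueError(
                f"heart rate {bad} outside [{HR_MIN}, {HR_MAX}] for "
                f"{self.subject_id} {self.date}"
            )

    @property
    def present_mask(self) -> np.ndarray:
        """Boolean mask of minutes with a recorded value."""
        return ~np.isnan(self.hr)

    @property
    def n_present(self) -> int:
        return int(self.present_mask.sum())

    def copy(self) -> "MinuteSeries":
        return MinuteSeries(self.subject_id, self.date, self.hr.copy())


def _parse_month(value) -> tuple[int, int]:
    if isinstance(value, str):
        y, m = value.split("-")
        return int(y), int(m)
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return int(value[0]), int(value[1])
    raise ValueError(f"cannot parse month specification {value!r}")


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass
class StudyCalendar:
    """Observation months, excluded breaks, semesters and seasonal period.

    ``months`` is the ordered list of (year, month) pairs under observation
    (e.g. the academic months of an 18-month study, summers absent).
    ``excluded_ranges`` are half-open date intervals ``[start, end)``
    removed from consideration (seasonal breaks).  ``semesters`` partition
    the observation window for the compliance filter.  ``period`` is the
    number of months in one repeating seasonal cycle (9 for an academic
    year with summers withheld).
    """

    months: list[tuple[int, int]]
    excluded_ranges: list[tuple[dt.date, dt.date]] = field(default_factory=list)
    semesters: dict[str, tuple[dt.date, dt.date]] = field(default_factory=dict)
    period: int = 9
    #: optional per-subject enrollment windows: subject_id -> (start, end)
    enrollment: dict[str, tuple[dt.date, dt.date]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = [y * 12 + (m - 1) for y, m in self.months]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("months: must be strictly increasing")
        ranges = sorted(self.excluded_ranges)
        for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
            if s2 < e1:
                raise ValueError(
                    f"excluded_ranges: [{s1},{e1}) overlaps [{s2},{e2})"
                )
        for s, e in self.excluded_ranges:
            if e <= s:
                raise ValueError(f"excluded_ranges: empty or inverted [{s},{e})")
        if self.period < 2:
            raise ValueError(f"period: must be >= 2, got {self.period}")
        if self.period > len(self.months):
            raise ValueError(
                f"period: {self.period} exceeds number of observed months "
                f"({len(self.months)})"
            )
        for y, m in self.months:
            first = dt.date(y, m, 1)
            nxt = dt.date(y + (m == 12), m % 12 + 1, 1)
            days = (dt.date.fromordinal(o) for o in range(first.toordinal(), nxt.toordinal()))
            if not any(not self.is_excluded(d) for d in days):
                raise ValueError(f"months: {y}-{m:02d} entirely inside excluded_ranges")

    def is_excluded(self, date: dt.date) -> bool:
        return any(s <= date < e for s, e in self.excluded_ranges)

    def is_observed(self, date: dt.date) -> bool:
        return (date.year, date.month) in set(self.months) and not self.is_excluded(date)

    def semester_of(self, date: dt.date) -> str | None:
        for name, (s, e) in self.semesters.items():
            if s <= date < e:
                return name
        return None

    def month_index(self, year: int, month: int) -> int:
        """Position of (year, month) in the observed-month ordering."""
        return self.months.index((year, month))

    def iter_dates(self) -> Iterable[dt.date]:
        """All observed (non-excluded) dates in calendar order."""
        for y, m in self.months:
            first = dt.date(y, m, 1)
            nxt = dt.date(y + (m == 12), m % 12 + 1, 1)
            for o in range(first.toordinal(), nxt.toordinal()):
                d = dt.date.fromordinal(o)
                if not self.is_excluded(d):
                    yield d


def read_minute_hr(
    path: str | Path,
    *,
    sep: str | None = None,
) -> list[MinuteSeries]:
    """Read long-format minute heart-rate records into per-day series.

    The file must be delimited text with columns ``subject_id``,
    ``timestamp`` (ISO-8601, minute resolution; seconds are truncated) and
    ``heart_rate``.  Minutes absent from the file become missing markers.

    Raises
    ------
    IngestError
        On an unparseable timestamp, a heart rate outside [25, 250], or a
        duplicate (subject, minute) row — each named with its row number.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    required = {"subject_id", "timestamp", "heart_rate"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise IngestError(f"{path}: missing columns {sorted(missing_cols)}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise IngestError(
            f"{path}: unparseable timestamp {df['timestamp'].iloc[row]!r} "
            f"at data row {row + 1}"
        )
    hr = pd.to_numeric(df["heart_rate"], errors="coerce")
    if hr.isna().any():
        row = int(np.flatnonzero(hr.isna().to_numpy())[0])
        raise IngestError(
            f"{path}: unparseable heart_rate {df['heart_rate'].iloc[row]!r} "
            f"at data row {row + 1}"
        )
    out_of_range = (hr < HR_MIN) | (hr > HR_MAX)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise IngestError(
            f"{path}: heart_rate {hr.iloc[row]} outside [{HR_MIN}, {HR_MAX}] "
            f"at data row {row + 1}"
        )

    dates = ts.dt.date
    slots = ts.dt.hour * 60 + ts.dt.minute  # seconds truncated by construction

    dup = df.assign(_d=dates, _s=slots).duplicated(["subject_id", "_d", "_s"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise IngestError(
            f"{path}: duplicate minute for subject {df['subject_id'].iloc[row]} "
            f"at {df['timestamp'].iloc[row]} (data row {row + 1})"
        )

    series: list[MinuteSeries] = []
    frame = pd.DataFrame(
        {"subject_id": df["subject_id"], "date": dates, "slot": slots, "hr": hr}
    )
    for (sid, date), grp in frame.groupby(["subject_id", "date"], sort=True):
        arr = np.full(MINUTES_PER_DAY, np.nan)
        sl = grp["slot"].to_numpy()
        over = sl >= MINUTES_PER_DAY
        if over.any():
            warnings.warn(
                f"{sid} {date}: {int(over.sum())} reading(s) beyond slot 1439 dropped",
                stacklevel=2,
            )
        keep = ~over
        arr[sl[keep]] = grp["hr"].to_numpy()[keep]
        series.append(MinuteSeries(str(sid), date, arr))
    logger.info("read %d rows -> %d subject-days from %s", len(df), len(series), path)
    return series


_PROFILE_COLUMNS = [
    "subject_id",
    "date",
    "wear_minutes",
    "compliant",
    "rhr",
    "max_hr",
    "zone_min",
    "target_minutes",
    "n_bouts",
]


def write_day_profiles(profiles: Iterable, path: str | Path) -> None:
    """Write day profiles as CSV; round-trips losslessly via
    :func:`read_day_profiles`."""
    rows = []
    for p in profiles:
        z = p.zone
        rows.append(
            {
                "subject_id": p.subject_id,
                "date": p.date.isoformat(),
                "wear_minutes": p.wear_minutes,
                "compliant": p.compliant,
                "rhr": z.rhr if z is not None else np.nan,
                "max_hr": z.max_hr if z is not None else np.nan,
                "zone_min": z.zone_min if z is not None else np.nan,
                "target_minutes": p.target_minutes,
                "n_bouts": len(p.bouts),
            }
        )
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, index=False)


def read_day_profiles(path: str | Path) -> pd.DataFrame:
    """Read a day-profile CSV back into a typed DataFrame."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["compliant"] = df["compliant"].astype(bool)
    return df


def load_calendar(path: str | Path) -> StudyCalendar:
    """Load and validate a study calendar from a YAML or JSON file.

    Expected keys: ``months`` (list of ``YYYY-MM`` strings or [year, month]
    pairs), ``excluded_ranges`` (list of ``[start, end]`` ISO dates,
    half-open), ``semesters`` (mapping name -> [start, end]), ``period``
    (int), and optionally ``enrollment`` (mapping subject -> [start, end]).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: calendar file must contain a mapping")
    known = {"months", "excluded_ranges", "semesters", "period", "enrollment"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown calendar keys {sorted(unknown)}")
    try:
        months = [_parse_month(m) for m in raw.get("months", [])]
        excluded = [
            (_parse_date(s), _parse_date(e)) for s, e in raw.get("excluded_ranges", [])
        ]
        semesters = {
            str(name): (_parse_date(s), _parse_date(e))
            for name, (s, e) in (raw.get("semesters") or {}).items()
        }
        enrollment = {
            str(sid): (_parse_date(s), _parse_date(e))
            for sid, (s, e) in (raw.get("enrollment") or {}).items()
        }
        period = int(raw.get("period", 9))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return StudyCalendar(
        months=months,
        excluded_ranges=excluded,
        semesters=semesters,
        period=period,
        enrollment=enrollment,
    )


def default_calendar() -> StudyCalendar:
    """The 18-month academic calendar: Aug 2015 – Apr 2017 with the summer
    months May–Jul 2016 withheld, four named semesters, period 9."""
    months = []
    y, m = 2015, 8
    while (y, m) <= (2017, 4):
        if not (y == 2016 and m in (5, 6, 7)):
            months.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    semesters = {
        "fall2015": (dt.date(2015, 8, 1), dt.date(2016, 1, 1)),
        "spring2016": (dt.date(2016, 1, 1), dt.date(2016, 5, 1)),
        "fall2016": (dt.date(2016, 8, 1), dt.date(2017, 1, 1)),
        "spring2017": (dt.date(2017, 1, 1), dt.date(2017, 5, 1)),
    }
    return StudyCalendar(
        months=months,
        excluded_ranges=[(dt.date(2016, 5, 1), dt.date(2016, 8, 1))],
        semesters=semesters,
        period=9,
    )
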
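"""Synthetic minute-level heart-rate cohorts with known ground truth.

No public dataset accompanies the pipeline, so every stage is exercised
against generated subjects whose activity trends, bouts, and missingness
are known by construction:

* baseline HR — a single circadian sinusoid per subject whose trough sits
  at the subject's resting HR, plus white measurement noise;
* MVPA bouts — scheduled daytime intervals (>= 10 min, separated by >= 5
  out-of-zone minutes) during which HR is raised above the subject's
  Karvonen zone minimum, with short sub-threshold ramps on either side;
* long-term drift — the expected daily target minutes change linearly by
  ``drift`` minutes/day per observed month (the injected trend);
* seasonality — an additive per-phase offset repeating with the
  calendar's period (the academic-year cycle);
* missingness — device-dropout gaps of 2–150 minutes (short gaps most
  common, start probability elevated during bouts to mimic dropout under
  exertion), occasional noncompliant days with a large missing chunk,
  and occasional entirely missing days.

Missingness is applied last; ground truth (bout intervals, target
minutes, deleted slots) is recorded pre-missingness.  All randomness
derives from the mandatory seed; each subject gets an independent
substream keyed by subject index, so output is invariant to generation
order.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .hr_io import MINUTES_PER_DAY, MinuteSeries, StudyCalendar, default_calendar
from .mvpa import ZoneParams

__all__ = ["SynthConfig", "GroundTruth", "generate_cohort", "generate_complete_days"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.  Units: beats/min for HR quantities, minutes
    for durations, minutes/day-per-month for drift."""

    seed: int
    n_subjects: int = 10
    calendar: StudyCalendar | None = None
    # physiology
    rhr_mean: float = 62.0
    rhr_sd: float = 5.0
    age_range: tuple[float, float] = (18.0, 22.0)
    circadian_amplitude: float = 25.0
    noise_sd: float = 3.0
    # activity
    base_target_minutes: float = 30.0
    drift: float = 0.0
    seasonal_profile: tuple[float, ...] | None = None
    seasonal_amplitude: float = 5.0
    bout_duration_mean: float = 20.0
    bout_intensity: float = 15.0
    y: float = 0.5
    # missingness
    gaps: bool = True
    gap_rate_per_day: float = 3.0
    gap_short_range: tuple[int, int] = (2, 25)
    gap_long_range: tuple[int, int] = (26, 150)
    gap_long_prob: float = 0.15
    bout_gap_multiplier: float = 3.0
    noncompliant_day_prob: float = 0.08
    whole_day_missing_prob: float = 0.02
    #: optional mixed-cohort spec: ((n, drift), ...) overriding n_subjects/drift
    drift_groups: tuple[tuple[int, float], ...] | None = None
    subject_prefix: str = "S"

    def __post_init__(self) -> None:
        for name in ("gap_long_prob", "noncompliant_day_prob", "whole_day_missing_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.noise_sd < 0 or self.gap_rate_per_day < 0:
            raise ValueError("noise_sd and gap_rate_per_day must be >= 0")
        if self.bout_duration_mean < 10:
            raise ValueError("bout_duration_mean must be >= 10 (minimum bout length)")

    def resolved_calendar(self) -> StudyCalendar:
        return self.calendar if self.calendar is not None else default_calendar()

    def resolved_seasonal(self, period: int) -> np.ndarray:
        if self.seasonal_profile is not None:
            prof = np.asarray(self.seasonal_profile, dtype=float)
            if prof.size != period:
                raise ValueError(
                    f"seasonal_profile length {prof.size} != period {period}"
                )
            return prof - prof.mean()
        phases = np.arange(period)
        prof = self.seasonal_amplitude * np.cos(2 * np.pi * phases / period)
        return prof - prof.mean()

    def subject_specs(self) -> list[tuple[str, float]]:
        """(subject_id, drift) pairs, honoring drift_groups if given."""
        if self.drift_groups is None:
            return [
                (f"{self.subject_prefix}{i:04d}", self.drift)
                for i in range(self.n_subjects)
            ]
        specs = []
        i = 0
        for n, drift in self.drift_groups:
            for _ in range(n):
                specs.append((f"{self.subject_prefix}{i:04d}", drift))
                i += 1
        return specs


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    #: subject -> injected label (positive / negative / none, by drift sign)
    labels: dict[str, str] = field(default_factory=dict)
    #: subject -> drift used
    drifts: dict[str, float] = field(default_factory=dict)
    #: subject -> (rhr, age, zone) — zone uses the true rhr and 220 - age
    physiology: dict[str, tuple[float, float, ZoneParams]] = field(default_factory=dict)
    #: (subject, date) -> list of true bout intervals (start, end), half-open
    bouts: dict[tuple[str, dt.date], list[tuple[int, int]]] = field(default_factory=dict)
    #: (subject, date) -> true target minutes (sum of bout lengths)
    target_minutes: dict[tuple[str, dt.date], int] = field(default_factory=dict)
    #: (subject, date) -> boolean mask of slots made missing
    deleted: dict[tuple[str, dt.date], np.ndarray] = field(default_factory=dict)

    def label_of(self, subject_id: str) -> str:
        return self.labels[subject_id]


_DAY_WINDOW = (7 * 60, 22 * 60)  # bouts scheduled between 07:00 and 22:00
_RAMP_MINUTES = 3


def _schedule_bouts(
    rng: np.random.Generator, n_bouts: int, mean_duration: float
) -> list[tuple[int, int]]:
    """Non-overlapping daytime bout intervals separated by >= 5 minutes."""
    intervals: list[tuple[int, int]] = []
    for _ in range(n_bouts):
        dur = int(min(10 + rng.poisson(mean_duration - 10), 90))
        for _attempt in range(25):
            start = int(rng.integers(_DAY_WINDOW[0], _DAY_WINDOW[1] - dur))
            end = start + dur
            # 5-minute buffer so truth bouts never merge under the 1-min rule
            if all(end + 5 <= s or e + 5 <= start for s, e in intervals):
                intervals.append((start, end))
                break
    return sorted(intervals)


def _day_hr(
    rng: np.random.Generator,
    rhr: float,
    zone: ZoneParams,
    cfg: SynthConfig,
    bouts: list[tuple[int, int]],
    phase_shift: float,
) -> np.ndarray:
    """One complete day of HR: circadian baseline + bouts + noise."""
    t = np.arange(MINUTES_PER_DAY)
    # trough of the sinusoid sits at the resting HR
    baseline = rhr + cfg.circadian_amplitude * 0.5 * (
        1 - np.cos(2 * np.pi * (t - phase_shift) / MINUTES_PER_DAY)
    )
    hr = baseline.copy()
    for start, end in bouts:
        dur = end - start
        # in-bout level: above zone_min by intensity, with slow within-bout
        # variation that never dips below zone_min + 2 (noise aside)
        wobble = 5.0 * np.sin(np.linspace(0, np.pi, dur))
        level = zone.zone_min + cfg.bout_intensity + wobble - 5.0
        hr[start:end] = np.maximum(level, zone.zone_min + 2.0)
        # sub-threshold ramps on either side
        for k in range(1, _RAMP_MINUTES + 1):
            frac = 1 - k / (_RAMP_MINUTES + 1)
            lo = start - k
            if lo >= 0 and not any(s <= lo < e for s, e in bouts):
                hr[lo] = max(hr[lo], baseline[lo] + frac * (zone.zone_min - 2 - baseline[lo]))
            hi = end - 1 + k
            if hi < MINUTES_PER_DAY and not any(s <= hi < e for s, e in bouts):
                hr[hi] = max(hr[hi], baseline[hi] + frac * (zone.zone_min - 2 - baseline[hi]))
    if cfg.noise_sd > 0:
        hr = hr + rng.normal(0, cfg.noise_sd, MINUTES_PER_DAY)
    return np.clip(hr, 30.0, 240.0)


def _sample_gap_mask(
    rng: np.random.Generator, cfg: SynthConfig, bout_slots: np.ndarray
) -> np.ndarray:
    """Device-dropout mask for one day: Poisson number of gaps, lengths
    2–150 min (short-heavy), start odds elevated inside bouts."""
    mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
    n_gaps = rng.poisson(cfg.gap_rate_per_day)
    if n_gaps == 0:
        return mask
    base_weights = np.ones(MINUTES_PER_DAY)
    base_weights[bout_slots] = cfg.bout_gap_multiplier
    for _ in range(n_gaps):
        if rng.random() < cfg.gap_long_prob:
            lo, hi = cfg.gap_long_range
        else:
            lo, hi = cfg.gap_short_range
        length = int(rng.integers(lo, hi + 1))
        # gaps must fit in the day and never overlap, so every placed gap
        # keeps its drawn length (the empirical histogram stays faithful)
        for _attempt in range(10):
            w = base_weights[: MINUTES_PER_DAY - length + 1]
            start = int(rng.choice(w.size, p=w / w.sum()))
            if not mask[max(0, start - 1) : start + length + 1].any():
                mask[start : start + length] = True
                break
    return mask


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # stable per-subject substream: invariant to generation order
    return np.random.default_rng([seed, 7919, index])


def generate_cohort(cfg: SynthConfig) -> tuple[list[MinuteSeries], GroundTruth]:
    """Generate the full synthetic cohort over the study calendar.

    Returns one :class:`MinuteSeries` per subject per observed date
    (all-missing days included) plus the :class:`GroundTruth`.
    Reproducible: the same config yields byte-identical output.
    """
    calendar = cfg.resolved_calendar()
    seasonal = cfg.resolved_seasonal(calendar.period)
    dates = list(calendar.iter_dates())
    month_index = {ym: i for i, ym in enumerate(calendar.months)}

    series: list[MinuteSeries] = []
    truth = GroundTruth()
    for idx, (sid, drift) in enumerate(cfg.subject_specs()):
        rng = _subject_rng(cfg.seed, idx)
        age = float(rng.uniform(*cfg.age_range))
        rhr = float(np.clip(rng.normal(cfg.rhr_mean, cfg.rhr_sd), 45, 85))
        zone = ZoneParams(rhr=rhr, max_hr=220.0 - age, y=cfg.y)
        phase_shift = float(rng.uniform(0, MINUTES_PER_DAY))

        truth.labels[sid] = (
            "positive" if drift > 0 else "negative" if drift < 0 else "none"
        )
        truth.drifts[sid] = drift
        truth.physiology[sid] = (rhr, age, zone)

        for date in dates:
            mi = month_index[(date.year, date.month)]
            expected = max(
                0.0,
                cfg.base_target_minutes + drift * mi + seasonal[mi % calendar.period],
            )
            n_bouts = rng.poisson(expected / cfg.bout_duration_mean)
            bouts = _schedule_bouts(rng, n_bouts, cfg.bout_duration_mean)
            hr = _day_hr(rng, rhr, zone, cfg, bouts, phase_shift)

            truth.bouts[(sid, date)] = bouts
            truth.target_minutes[(sid, date)] = sum(e - s for s, e in bouts)

            mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
            if cfg.gaps:
                u = rng.random()
                if u < cfg.whole_day_missing_prob:
                    mask[:] = True
                elif u < cfg.whole_day_missing_prob + cfg.noncompliant_day_prob:
                    # large missing chunk -> wear below the 80% threshold
                    length = int(rng.integers(300, MINUTES_PER_DAY + 1))
                    start = int(rng.integers(0, MINUTES_PER_DAY - min(length, MINUTES_PER_DAY) + 1))
                    mask[start : start + length] = True
                else:
                    bout_slots = np.concatenate(
                        [np.arange(s, e) for s, e in bouts]
                    ) if bouts else np.array([], dtype=int)
                    mask = _sample_gap_mask(rng, cfg, bout_slots)
            truth.deleted[(sid, date)] = mask
            hr_out = hr.copy()
            hr_out[mask] = np.nan
            series.append(MinuteSeries(sid, date, hr_out))
    return series, truth


def generate_complete_days(n: int, cfg: SynthConfig) -> list[MinuteSeries]:
    """Gap-free days (circadian baseline + bouts + noise) for the
    imputation benchmark.  Deterministic given ``cfg.seed``."""
    bench_cfg = replace(cfg, gaps=False)
    days: list[MinuteSeries] = []
    calendar = cfg.resolved_calendar()
    base_date = next(iter(calendar.iter_dates()))
    for i in range(n):
        rng = _subject_rng(cfg.seed, 100_000 + i)
        age = float(rng.uniform(*cfg.age_range))
        rhr = float(np.clip(rng.normal(cfg.rhr_mean, cfg.rhr_sd), 45, 85))
        zone = ZoneParams(rhr=rhr, max_hr=220.0 - age, y=cfg.y)
        phase_shift = float(rng.uniform(0, MINUTES_PER_DAY))
        n_bouts = rng.poisson(cfg.base_target_minutes / cfg.bout_duration_mean)
        bouts = _schedule_bouts(rng, n_bouts, cfg.bout_duration_mean)
        hr = _day_hr(rng, rhr, zone, bench_cfg, bouts, phase_shift)
        days.append(
            MinuteSeries(f"bench{i:04d}", base_date + dt.timedelta(days=i % 28), hr)
        )
    return days
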
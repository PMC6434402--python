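"""End-to-end orchestration: compliance -> imputation -> zones/bouts ->
monthly panel -> decomposition -> Mann-Kendall -> labels.

The stages run in a fixed order and every filter logs its in/out counts,
so `subjects_in = subjects_labeled + subjects_excluded` always holds and
each exclusion carries a reason.  All intermediates are plain tables
(day profiles, monthly panels, trend results) and each stage can be
re-run from the previous stage's written output.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import compliance as comp
from . import imputation as imp
from . import mvpa, trends
from .hr_io import MinuteSeries, StudyCalendar

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for a full pipeline run."""

    compliance: comp.ComplianceConfig = field(default_factory=comp.ComplianceConfig)
    imputation: imp.ImputationConfig = field(default_factory=imp.ImputationConfig)
    # zone settings
    y: float = 0.5
    # bout settings
    min_bout: int = 10
    merge_gap: int = 1
    merge_before_filter: bool = True
    count_bridged: bool = True
    # trend settings
    period: int | None = None  # None -> calendar.period
    alpha: float = 0.05
    seed: int = 0

    _KNOWN = None  # populated below

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        """Build from a nested plain mapping; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "compliance" in kwargs and isinstance(kwargs["compliance"], Mapping):
            kwargs["compliance"] = comp.ComplianceConfig(**kwargs["compliance"])
        if "imputation" in kwargs and isinstance(kwargs["imputation"], Mapping):
            kwargs["imputation"] = imp.ImputationConfig(**kwargs["imputation"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Everything a pipeline run produces."""

    profiles: list[mvpa.DayProfile]
    panels: list[trends.MonthlyPanel]
    results: list[trends.TrendResult]
    cohort: set[str]
    excluded: dict[str, str]  # subject -> exclusion reason
    balance: tuple[float, float] | None  # Kruskal-Wallis (H, p), if computable
    counts: dict[str, int]

    def trend_table(self) -> pd.DataFrame:
        return trends.trend_table(self.results)

    def label_counts(self) -> dict[str, int]:
        out = {"positive": 0, "negative": 0, "none": 0}
        for r in self.results:
            out[r.label] += 1
        return out


def run_pipeline(
    days: Sequence[MinuteSeries],
    calendar: StudyCalendar,
    ages: Mapping[str, float] | None = None,
    rhr: Mapping[str, float] | Mapping[tuple[str, dt.date], float] | None = None,
    max_hr: Mapping[str, float] | None = None,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on in-memory minute series.

    ``ages`` maps subject -> age in years (used for the age-predicted
    maximal HR 220 - age unless ``max_hr`` supplies an explicit value).
    ``rhr`` optionally maps subject (or (subject, date)) -> resting HR;
    when absent the day's resting HR is estimated from its 30 lowest
    recorded minutes.  The run is deterministic: no stage draws random
    numbers.
    """
    cfg = cfg or PipelineConfig()
    ages = ages or {}
    max_hr = max_hr or {}
    days = sorted(days, key=lambda d: (d.subject_id, d.date))
    subjects_in = sorted({d.subject_id for d in days})
    counts: dict[str, int] = {"subjects_in": len(subjects_in), "days_in": len(days)}

    # stage 1: compliance screening
    summaries = comp.summarize_compliance(days, cfg.compliance, calendar)
    cohort = comp.select_cohort(summaries, cfg.compliance, calendar)
    excluded = {
        sid: (
            "below min compliant days per semester "
            f"(least semester = {summaries[sid].least_compliant_semester_count})"
        )
        for sid in subjects_in
        if sid not in cohort
    }
    counts["subjects_cohort"] = len(cohort)
    logger.info(
        "compliance: %d subjects in, %d retained, %d excluded",
        len(subjects_in), len(cohort), len(excluded),
    )

    # stages 2-3: imputation, zones, bouts (compliant cohort days only)
    def day_rhr(sid: str, date: dt.date) -> float | None:
        if rhr is None:
            return None
        if (sid, date) in rhr:  # type: ignore[operator]
            return float(rhr[(sid, date)])  # type: ignore[index]
        if sid in rhr:  # type: ignore[operator]
            return float(rhr[sid])  # type: ignore[index]
        return None

    profiles: list[mvpa.DayProfile] = []
    n_imputed_days = 0
    for day in days:
        if day.subject_id not in cohort:
            continue
        wear = comp.wear_minutes(day)
        compliant = comp.is_compliant(day, cfg.compliance)
        profile = mvpa.DayProfile(
            subject_id=day.subject_id,
            date=day.date,
            wear_minutes=wear,
            compliant=compliant,
        )
        if compliant:
            imputed = imp.impute_linear(day, cfg.imputation)
            if imputed.n_present > wear:
                n_imputed_days += 1
            try:
                zone = mvpa.daily_zone_params(
                    day,  # RHR fallback estimates from recorded minutes only
                    subject_age=ages.get(day.subject_id),
                    rhr=day_rhr(day.subject_id, day.date),
                    y=cfg.y,
                    max_hr=max_hr.get(day.subject_id),
                )
            except ValueError as exc:
                logger.warning(
                    "%s %s: no zone (%s); day contributes 0 target minutes",
                    day.subject_id, day.date, exc,
                )
                profiles.append(profile)
                continue
            mask = mvpa.in_zone_mask(imputed, zone)
            bouts = mvpa.detect_bouts(
                mask,
                min_bout=cfg.min_bout,
                merge_gap=cfg.merge_gap,
                merge_before_filter=cfg.merge_before_filter,
                date=day.date,
            )
            profile.zone = zone
            profile.bouts = bouts
            profile.target_minutes = mvpa.target_minutes(bouts, cfg.count_bridged)
        profiles.append(profile)
    counts["days_profiled"] = len(profiles)
    counts["days_imputed"] = n_imputed_days
    logger.info("profiled %d cohort days (%d had gaps imputed)", len(profiles), n_imputed_days)

    # stage 4: monthly panels
    panels = []
    by_subject: dict[str, list[mvpa.DayProfile]] = {}
    for p in profiles:
        by_subject.setdefault(p.subject_id, []).append(p)
    for sid in sorted(by_subject):
        panels.append(trends.monthly_panel(by_subject[sid], calendar))
    counts["subjects_paneled"] = len(panels)

    # stages 5-7: decomposition, Mann-Kendall, labels
    period = cfg.period if cfg.period is not None else calendar.period
    results = trends.extract_trends(panels, period=period, alpha=cfg.alpha)
    counts["subjects_labeled"] = len(results)
    counts["subjects_excluded"] = len(excluded)

    balance = None
    labels_present = {r.label for r in results}
    if len(labels_present) >= 2:
        try:
            balance = trends.check_compliance_balance(panels, results, cfg.alpha)
        except ValueError as exc:
            logger.warning("compliance-balance check skipped: %s", exc)

    assert counts["subjects_in"] == counts["subjects_labeled"] + counts["subjects_excluded"]
    return PipelineResult(
        profiles=profiles,
        panels=panels,
        results=results,
        cohort=cohort,
        excluded=excluded,
        balance=balance,
        counts=counts,
    )
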
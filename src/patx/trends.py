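"""Long-term MVPA trend extraction.

Daily target minutes are downsampled to one value per observed calendar
month: the month's summed target minutes over compliant days, divided by
the number of compliant days in that month (normalizing short months and
uneven compliance).  Classical additive seasonal decomposition with the
calendar's period (9 months per academic year by default) splits the
monthly series into trend + seasonal + remainder:

* trend — centered simple moving average of window ``period`` (odd
  window; the first and last ``(period - 1) // 2`` positions are
  undefined);
* seasonal — per-phase means of the detrended series, re-centered to
  zero mean;
* remainder — observed - trend - seasonal.

The defined positions of the trend component are then tested with the
Mann-Kendall test (tie-corrected variance, continuity-corrected normal
approximation, two-sided p), and each subject is labeled positive,
negative, or none at significance level alpha (default .05).  A
Kruskal-Wallis check compares compliant-days-per-month distributions
across the three label groups to flag compliance imbalance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hr_io import StudyCalendar
from .mvpa import DayProfile

__all__ = [
    "MonthlyPanel",
    "Decomposition",
    "TrendResult",
    "monthly_panel",
    "seasonal_decompose_additive",
    "mann_kendall",
    "classify_trend",
    "extract_trends",
    "check_compliance_balance",
]

logger = logging.getLogger(__name__)

Label = Literal["positive", "negative", "none"]


@dataclass
class MonthlyPanel:
    """Normalized monthly target minutes for one subject.

    ``normalized[i]`` is target minutes per compliant day in calendar
    month ``months[i]``; NaN where the month has no compliant days.
    """

    subject_id: str
    months: list[tuple[int, int]]
    target_sum: np.ndarray
    compliant_days: np.ndarray
    normalized: np.ndarray


@dataclass
class Decomposition:
    """Additive decomposition: observed = trend + seasonal + remainder.

    ``trend`` is NaN at the ``(period - 1) // 2`` edge positions on each
    side; ``seasonal`` repeats one value per phase and sums to ~0 over a
    period.  ``interpolated`` flags interior months that were pre-filled
    by linear interpolation before decomposing.
    """

    observed: np.ndarray
    trend: np.ndarray
    seasonal: np.ndarray
    remainder: np.ndarray
    period: int
    interpolated: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall outcome and label for one subject."""

    subject_id: str
    s_statistic: int
    variance_s: float
    z_score: float
    p_value: float
    label: Label
    alpha: float = 0.05
    n_used: int = 0


def monthly_panel(
    profiles: Iterable[DayProfile], calendar: StudyCalendar
) -> MonthlyPanel:
    """Aggregate one subject's day profiles to the normalized monthly panel.

    Only compliant days contribute to either the target-minute sum or the
    day count; days outside the observed months (or inside excluded break
    ranges) are ignored.  A month with zero compliant days yields NaN.
    """
    profiles = list(profiles)
    sids = {p.subject_id for p in profiles}
    if len(sids) > 1:
        raise ValueError(f"monthly_panel expects one subject, got {sorted(sids)}")
    subject_id = sids.pop() if sids else ""

    n = len(calendar.months)
    month_pos = {ym: i for i, ym in enumerate(calendar.months)}
    target_sum = np.zeros(n)
    compliant_days = np.zeros(n, dtype=int)
    for p in profiles:
        ym = (p.date.year, p.date.month)
        if ym not in month_pos or calendar.is_excluded(p.date) or not p.compliant:
            continue
        i = month_pos[ym]
        target_sum[i] += p.target_minutes
        compliant_days[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(compliant_days > 0, target_sum / np.maximum(compliant_days, 1), np.nan)
    return MonthlyPanel(
        subject_id=subject_id,
        months=list(calendar.months),
        target_sum=target_sum,
        compliant_days=compliant_days,
        normalized=normalized,
    )


def _interpolate_interior(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill interior NaNs; leading/trailing NaNs are untouched."""
    out = series.astype(float).copy()
    idx = np.flatnonzero(~np.isnan(out))
    flags = np.zeros(out.size, dtype=bool)
    if idx.size >= 2:
        interior = np.arange(idx[0], idx[-1] + 1)
        nan_interior = interior[np.isnan(out[interior])]
        out[nan_interior] = np.interp(nan_interior, idx, out[idx])
        flags[nan_interior] = True
    return out, flags


def seasonal_decompose_additive(
    series: Sequence[float] | np.ndarray, period: int
) -> Decomposition:
    """Classical additive decomposition with an odd moving-average window.

    The series must have at least ``2 * period`` observations.  Interior
    missing values are pre-filled by linear interpolation (flagged in the
    output); leading/trailing missing values shorten the series and keep
    their positions NaN in every component.
    """
    observed = np.asarray(series, dtype=float)
    if period < 2:
        raise ValueError("period must be >= 2")
    filled, interp_flags = _interpolate_interior(observed)
    defined = np.flatnonzero(~np.isnan(filled))
    if defined.size < 2 * period:
        raise ValueError(
            f"series needs >= {2 * period} defined values for period {period}, "
            f"has {defined.size}"
        )
    lo, hi = defined[0], defined[-1] + 1  # contiguous after interior fill
    y = filled[lo:hi]
    n = y.size
    half = (period - 1) // 2

    trend_core = np.convolve(y, np.ones(period) / period, mode="valid")
    trend = np.full(n, np.nan)
    trend[half : n - half] = trend_core
    if period % 2 == 0:
        # 2xMA convention for even windows: average adjacent MAs
        trend = np.full(n, np.nan)
        ma = np.convolve(y, np.ones(period) / period, mode="valid")
        ma2 = (ma[:-1] + ma[1:]) / 2
        trend[period // 2 : period // 2 + ma2.size] = ma2

    detrended = y - trend
    seasonal_means = np.array(
        [np.nanmean(detrended[phase::period]) for phase in range(period)]
    )
    seasonal_means -= seasonal_means.mean()
    seasonal = np.array([seasonal_means[i % period] for i in range(n)])
    remainder = y - trend - seasonal

    def expand(x: np.ndarray) -> np.ndarray:
        full = np.full(observed.size, np.nan)
        full[lo:hi] = x
        return full

    return Decomposition(
        observed=observed,
        trend=expand(trend),
        seasonal=expand(seasonal),
        remainder=expand(remainder),
        period=period,
        interpolated=interp_flags,
    )


def mann_kendall(series: Sequence[float] | np.ndarray) -> tuple[int, float, float, float]:
    """Mann-Kendall monotonic-trend test.

    Missing (NaN) positions are dropped with order preserved.  Returns
    ``(S, Var(S), Z, p)`` where

        S      = sum over i<j of sign(x_j - x_i)
        Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18   (tie groups t)
        Z      = (S - 1)/sqrt(Var) if S > 0, 0 if S = 0, (S + 1)/sqrt(Var)
        p      = two-sided from the standard normal.

    Requires at least 3 defined values.  For n < 10 the normal
    approximation is crude; a warning is logged.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 3:
        raise ValueError(f"mann_kendall needs >= 3 defined values, got {n}")
    if n < 10:
        logger.warning("mann_kendall: normal approximation is crude for n=%d < 10", n)

    diff_signs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff_signs, k=1).sum())

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0

    if var_s == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return s, float(var_s), float(z), p


def classify_trend(
    s_statistic: int, p_value: float, alpha: float = 0.05
) -> Label:
    """Label a tested series: positive/negative when significant, else none."""
    if p_value < alpha and s_statistic > 0:
        return "positive"
    if p_value < alpha and s_statistic < 0:
        return "negative"
    return "none"


def extract_trends(
    panels: Iterable[MonthlyPanel],
    period: int | None = None,
    alpha: float = 0.05,
) -> list[TrendResult]:
    """Full per-subject trend extraction: decompose each normalized
    monthly series, Mann-Kendall-test the trend component's defined
    positions, and label.

    Subjects whose series is too short to decompose, or whose defined
    trend has fewer than 3 points, are labeled ``none`` with a warning.
    """
    results = []
    for panel in panels:
        p = period if period is not None else 9
        try:
            decomp = seasonal_decompose_additive(panel.normalized, p)
            trend = decomp.trend[~np.isnan(decomp.trend)]
            s, var_s, z, pval = mann_kendall(trend)
            label = classify_trend(s, pval, alpha)
            results.append(
                TrendResult(panel.subject_id, s, var_s, z, pval, label, alpha, trend.size)
            )
        except ValueError as exc:
            logger.warning("subject %s labeled none: %s", panel.subject_id, exc)
            results.append(
                TrendResult(panel.subject_id, 0, 0.0, 0.0, 1.0, "none", alpha, 0)
            )
    return results


def check_compliance_balance(
    panels: Sequence[MonthlyPanel],
    results: Sequence[TrendResult],
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Kruskal-Wallis H-test on compliant-days-per-month across labels.

    Pools every subject-month's compliant-day count into its subject's
    label group and compares the group distributions.  A significant
    result (p < alpha) suggests trend labels reflect *when* subjects were
    compliant rather than how active they were.
    """
    label_of = {r.subject_id: r.label for r in results}
    groups: dict[str, list[int]] = {"positive": [], "negative": [], "none": []}
    for panel in panels:
        lbl = label_of.get(panel.subject_id)
        if lbl is not None:
            groups[lbl].extend(int(c) for c in panel.compliant_days)
    nonempty = [np.asarray(g) for g in groups.values() if len(g) > 0]
    if len(nonempty) < 2:
        raise ValueError("need at least 2 nonempty label groups")
    if all(np.all(g == nonempty[0][0]) for g in nonempty):
        return 0.0, 1.0  # identical constant data: no evidence of imbalance
    h, p = stats.kruskal(*nonempty)
    return float(h), float(p)


def trend_table(results: Iterable[TrendResult]) -> pd.DataFrame:
    """Trend results as a (subject_id, S, Z, p, label) table."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "s_statistic": r.s_statistic,
                "variance_s": r.variance_s,
                "z_score": r.z_score,
                "p_value": r.p_value,
                "label": r.label,
                "n_used": r.n_used,
            }
            for r in results
        ]
    )
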
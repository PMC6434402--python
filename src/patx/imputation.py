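"""Gap imputation by linear interpolation, plus the block-deletion
RMSE benchmark used to justify it.

Only interior gaps are imputed: a run of missing minutes needs a present
value on both flanks.  Gaps longer than ``max_gap_minutes`` (default
150) are left missing, as are leading/trailing gaps.  Imputed values are
real-valued; present values are never altered, so the operation is
idempotent.

The benchmark degrades complete 24-hour records by deleting random
non-overlapping blocks of fixed length until roughly the target fraction
(default 20%) of the day is missing, imputes, and scores root-mean-square
error on the deleted slots only.  Alternative imputers plug in as plain
callables ``MinuteSeries -> MinuteSeries``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .hr_io import MINUTES_PER_DAY, MinuteSeries

__all__ = [
    "ImputationConfig",
    "BenchmarkResult",
    "impute_linear",
    "delete_blocks",
    "rmse",
    "benchmark_imputation",
]

Imputer = Callable[[MinuteSeries], MinuteSeries]


@dataclass(frozen=True)
class ImputationConfig:
    """Imputation and benchmark settings.

    max_gap_minutes
        Longest interior gap eligible for interpolation (minutes).
    missing_target_fraction
        Fraction of the day the benchmark deletes (stop at first >=).
    block_lengths
        Benchmark deletion block lengths in minutes.
    round_output
        Round imputed values to whole beats/min for display; off by
        default since downstream zone comparison is threshold-based.
    """

    max_gap_minutes: int = 150
    missing_target_fraction: float = 0.20
    block_lengths: tuple[int, ...] = (25, 50, 150)
    round_output: bool = False

    def __post_init__(self) -> None:
        if self.max_gap_minutes < 1:
            raise ValueError("max_gap_minutes must be >= 1")
        if not 0 < self.missing_target_fraction < 1:
            raise ValueError("missing_target_fraction must be in (0, 1)")
        if any(b < 1 for b in self.block_lengths):
            raise ValueError("block_lengths must be positive")


@dataclass(frozen=True)
class BenchmarkResult:
    method: str
    block_length: int
    rmse: float
    n_slots: int

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def impute_linear(
    day: MinuteSeries, cfg: ImputationConfig | None = None
) -> MinuteSeries:
    """Fill interior gaps of length <= ``max_gap_minutes`` by straight-line
    interpolation between the flanking present values.

    Leading/trailing gaps and over-long gaps stay missing.  A day with
    fewer than two present values is returned unchanged.
    """
    cfg = cfg or ImputationConfig()
    hr = day.hr.copy()
    present = np.flatnonzero(~np.isnan(hr))
    if present.size < 2:
        return day.copy()
    filled = np.interp(np.arange(MINUTES_PER_DAY), present, hr[present])
    out = hr.copy()
    # fill only interior gaps no longer than the cap
    gap_starts = present[:-1] + 1
    gap_ends = present[1:]  # gap is [start, end), end exclusive of next present
    for s, e in zip(gap_starts, gap_ends):
        length = e - s
        if 0 < length <= cfg.max_gap_minutes:
            out[s:e] = filled[s:e]
    if cfg.round_output:
        imputed = np.isnan(hr) & ~np.isnan(out)
        out[imputed] = np.round(out[imputed])
    return MinuteSeries(day.subject_id, day.date, out)


def delete_blocks(
    day: MinuteSeries,
    block_length: int,
    target_fraction: float,
    seed: int | np.random.Generator,
) -> tuple[MinuteSeries, np.ndarray]:
    """Delete non-overlapping contiguous blocks from a complete day.

    Blocks of exactly ``block_length`` minutes are removed at positions
    drawn uniformly without replacement among remaining feasible starts,
    until the missing fraction first reaches ``target_fraction`` (the
    final block may overshoot; blocks may touch but never overlap).
    Returns the degraded day and the boolean mask of deleted slots.
    """
    if day.n_present != MINUTES_PER_DAY:
        raise ValueError("delete_blocks requires a complete day")
    if block_length > MINUTES_PER_DAY:
        raise ValueError("block_length exceeds the day length")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
    target_slots = target_fraction * MINUTES_PER_DAY
    while mask.sum() < target_slots:
        occupied = np.flatnonzero(mask)
        feasible = np.ones(MINUTES_PER_DAY - block_length + 1, dtype=bool)
        for pos in occupied:
            lo = max(0, pos - block_length + 1)
            feasible[lo : pos + 1] = False
        starts = np.flatnonzero(feasible)
        if starts.size == 0:
            break  # no room left for another block
        start = int(rng.choice(starts))
        mask[start : start + block_length] = True
    hr = day.hr.copy()
    hr[mask] = np.nan
    return MinuteSeries(day.subject_id, day.date, hr), mask


def rmse(
    original: MinuteSeries, imputed: MinuteSeries, mask: np.ndarray
) -> float:
    """Root-mean-square error over the deleted slots, in beats/min.

    Slots in the mask that remain missing after imputation (e.g. gaps the
    imputer declined to fill) are excluded from the mean; an all-missing
    mask is an error.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("rmse: empty mask")
    diff = imputed.hr[mask] - original.hr[mask]
    diff = diff[~np.isnan(diff)]
    if diff.size == 0:
        raise ValueError("rmse: no imputed values on the mask")
    return float(np.sqrt(np.mean(diff**2)))


def benchmark_imputation(
    complete_days: Sequence[MinuteSeries],
    methods: dict[str, Imputer] | None = None,
    cfg: ImputationConfig | None = None,
    seed: int = 0,
) -> list[BenchmarkResult]:
    """Block-deletion benchmark: pooled RMSE per method x block length.

    Every supplied day must be complete.  For each block length, each day
    is degraded once (deterministically from ``seed``), each method
    imputes the degraded copy, and squared errors are pooled over all
    days before taking the root.  Results are invariant to day ordering.
    """
    cfg = cfg or ImputationConfig()
    if len(complete_days) == 0:
        raise ValueError("benchmark requires at least one complete day")
    for d in complete_days:
        if d.n_present != MINUTES_PER_DAY:
            raise ValueError(f"day {d.subject_id} {d.date} is not complete")
    if methods is None:
        methods = {"linear_interpolation": lambda day: impute_linear(day, cfg)}

    # one deterministic degradation per (day, block length), independent of
    # the order days are supplied in; crc32 keying is stable across processes
    def day_rng(day: MinuteSeries, block: int) -> np.random.Generator:
        key = zlib.crc32(f"{day.subject_id}|{day.date.isoformat()}|{block}".encode())
        return np.random.default_rng([seed, block, key])

    # pool in canonical (subject, date) order so results are bitwise
    # independent of the order days were supplied in
    ordered = sorted(complete_days, key=lambda d: (d.subject_id, d.date))
    results: list[BenchmarkResult] = []
    for block in cfg.block_lengths:
        degraded = [
            delete_blocks(d, block, cfg.missing_target_fraction, day_rng(d, block))
            for d in ordered
        ]
        for name, method in sorted(methods.items()):
            sq_sum, n = 0.0, 0
            for original, (deg, mask) in zip(ordered, degraded):
                imp = method(deg)
                diff = imp.hr[mask] - original.hr[mask]
                diff = diff[~np.isnan(diff)]
                sq_sum += float(np.sum(diff**2))
                n += diff.size
            results.append(
                BenchmarkResult(name, block, float(np.sqrt(sq_sum / n)) if n else 0.0, n)
            )
    return results


def benchmark_table(results: Iterable[BenchmarkResult]) -> pd.DataFrame:
    """Benchmark results as a (method, block_length, rmse) table."""
    return pd.DataFrame(
        [
            {"method": r.method, "block_length": r.block_length, "rmse": r.rmse}
            for r in results
        ]
    )
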
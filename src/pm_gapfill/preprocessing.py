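"""Minute-level QC pipeline: two-stage outlier filtering and hourly aggregation.

Stages run in a fixed order: spike flags -> IQR flags -> timeline
regularization -> delayed-timestamp correction -> short-gap interpolation ->
hourly aggregation -> secondary hourly flags.  No stage deletes rows; flagged
values become NaN so they stay eligible for downstream gap filling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from pm_gapfill.errors import DegenerateInputError, InvalidConfigError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the quality-control pipeline (defaults per the study)."""

    spike_threshold: float = 200.0  # ug/m3
    spike_ratio: float = 3.0
    iqr_multiplier: float = 1.5
    delay_tolerance: float = 15.0  # seconds, exclusive
    short_gap_max: int = 5  # minutes, exclusive ("shorter than")
    min_valid_minutes: int = 40  # inclusive ("at least")
    hourly_hard_threshold: float = 270.0  # ug/m3
    hourly_spike_threshold: float = 200.0  # ug/m3
    hourly_spike_ratio: float = 3.0
    quartile_method: str = "linear"  # order-statistic interpolation scheme

    def __post_init__(self) -> None:
        for name in (
            "spike_threshold",
            "spike_ratio",
            "iqr_multiplier",
            "delay_tolerance",
            "short_gap_max",
            "min_valid_minutes",
            "hourly_hard_threshold",
            "hourly_spike_threshold",
            "hourly_spike_ratio",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")


def flag_spike_outliers(
    values: Sequence[float] | np.ndarray,
    threshold: float = 200.0,
    ratio: float = 3.0,
) -> np.ndarray:
    """Flag point i iff value_i > threshold AND value_i > ratio * value_{i-1}.

    A missing predecessor never triggers a flag; the first point has no
    predecessor and is never flagged.
    """
    v = np.asarray(values, dtype=float)
    mask = np.zeros(len(v), dtype=bool)
    if len(v) < 2:
        return mask
    prev = v[:-1]
    cur = v[1:]
    ok = ~np.isnan(prev) & ~np.isnan(cur)
    mask[1:] = ok & (cur > threshold) & (cur > ratio * prev)
    return mask


def flag_iqr_outliers(values: Sequence[float] | np.ndarray, multiplier: float = 1.5) -> np.ndarray:
    """Flag points strictly outside [Q1 - m*IQR, Q3 + m*IQR].

    Quartiles use linear interpolation of order statistics over the
    non-missing values.  Comparisons are strict, so a constant series
    yields no flags.
    """
    v = np.asarray(values, dtype=float)
    observed = v[~np.isnan(v)]
    if observed.size < 4:
        raise DegenerateInputError(f"IQR rule needs >= 4 observed values, got {observed.size}")
    q1, q3 = np.percentile(observed, [25.0, 75.0])
    iqr = q3 - q1
    lower, upper = q1 - multiplier * iqr, q3 + multiplier * iqr
    with np.errstate(invalid="ignore"):
        return (v < lower) | (v > upper)


def regularize_timeline(records: pd.DataFrame) -> pd.DataFrame:
    """Align records onto a complete 1-minute grid spanning min..max timestamp.

    Rows at off-grid timestamps (non-zero seconds) are retained so the
    subsequent delay-correction stage can reassign them.
    """
    if records.empty:
        return records.copy()
    start = records.index.min().floor("min")
    stop = records.index.max().floor("min")
    grid = pd.date_range(start, stop, freq="min")
    full_index = grid.union(records.index)
    out = records.reindex(full_index)
    out.index.name = None
    return out


def correct_delayed_timestamps(records: pd.DataFrame, delay_tolerance: float = 15.0) -> pd.DataFrame:
    """Shift slightly late readings back to their intended minute.

    A record at hh:mm:ss with 0 < ss < tolerance moves to hh:mm:00 when that
    minute holds no data; otherwise it stays put and a warning is logged.
    Off-grid rows that were successfully moved are dropped from the output
    (their values now live on the grid); unmovable off-grid rows remain.
    """
    if records.empty:
        return records.copy()
    out = records.copy()
    seconds = out.index.second + out.index.microsecond / 1e6
    delayed = (seconds > 0) & (seconds < delay_tolerance)
    to_drop = []
    for ts in out.index[delayed]:
        target = ts.floor("min")
        row = out.loc[ts]
        if target in out.index and not out.loc[target].isna().all():
            logger.warning("delayed reading at %s not moved: minute %s already occupied", ts, target)
            continue
        out.loc[target] = row.to_numpy()
        to_drop.append(ts)
    if to_drop:
        out = out.drop(index=to_drop)
    return out.sort_index()


def fill_short_gaps(series: pd.Series, short_gap_max: int = 5) -> pd.Series:
    """Linearly interpolate missing runs shorter than ``short_gap_max``.

    Only runs bounded by observed values on both sides qualify; runs of
    length >= short_gap_max and boundary-touching runs are untouched.
    """
    v = series.to_numpy(dtype=float).copy()
    n = len(v)
    missing = np.isnan(v)
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        run_len = j - i
        if 0 < i and j < n and run_len < short_gap_max:
            left, right = v[i - 1], v[j]
            v[i:j] = left + (right - left) * np.arange(1, run_len + 1) / (run_len + 1)
        i = j
    return pd.Series(v, index=series.index, name=series.name)


def aggregate_hourly(records: pd.DataFrame, min_valid_minutes: int = 40) -> pd.DataFrame:
    """Average minutes into hourly values where coverage is sufficient.

    An hour's PM2.5 is the mean of its valid minutes when at least
    ``min_valid_minutes`` are present (inclusive), NaN otherwise.  Auxiliary
    columns are averaged over whatever is available.  The output spans every
    hour of the minute grid.
    """
    if records.empty:
        return records.copy()
    hours = records.index.floor("h")
    grouped = records.groupby(hours)
    out = grouped.mean()
    counts = grouped["pm25"].count()
    out.loc[counts < min_valid_minutes, "pm25"] = np.nan
    full = pd.date_range(out.index.min(), out.index.max(), freq="h")
    out = out.reindex(full)
    out.index.name = None
    return out


def flag_hourly_outliers(values: Sequence[float] | np.ndarray, config: QCConfig | None = None) -> np.ndarray:
    """Secondary hourly filter: value > hard threshold, or a >3x spike above
    the previous hour while exceeding the spike threshold."""
    config = config or QCConfig()
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        hard = v > config.hourly_hard_threshold
    spikes = flag_spike_outliers(v, config.hourly_spike_threshold, config.hourly_spike_ratio)
    return np.where(np.isnan(v), False, hard | spikes)


def preprocess_minute_data(records: pd.DataFrame, config: QCConfig | None = None) -> pd.DataFrame:
    """Full minute-to-hour QC pipeline; returns the hourly series."""
    config = config or QCConfig()
    if records.empty:
        return records.copy()
    out = records.copy().sort_index()

    # stage 1: outlier flags on the raw values (union of the two rules)
    values = out["pm25"].to_numpy(dtype=float)
    mask = flag_spike_outliers(values, config.spike_threshold, config.spike_ratio)
    try:
        mask = mask | flag_iqr_outliers(values, config.iqr_multiplier)
    except DegenerateInputError:
        logger.warning("too few observed minutes for the IQR rule; skipping it")
    out.loc[mask, "pm25"] = np.nan

    out = regularize_timeline(out)
    out = correct_delayed_timestamps(out, config.delay_tolerance)
    # any reading still off-grid cannot be attributed to a minute
    off_grid = out.index.second != 0
    if off_grid.any():
        logger.warning("%d readings remain off-grid and are ignored", int(off_grid.sum()))
        out = out[~off_grid]
    out["pm25"] = fill_short_gaps(out["pm25"], config.short_gap_max)

    hourly = aggregate_hourly(out, config.min_valid_minutes)
    hourly_mask = flag_hourly_outliers(hourly["pm25"].to_numpy(dtype=float), config)
    hourly.loc[hourly_mask, "pm25"] = np.nan
    return hourly


def completeness_report(hourly: pd.DataFrame) -> pd.DataFrame:
    """Plain-text monthly completeness summary of the hourly series."""
    by_month = hourly["pm25"].groupby(hourly.index.to_period("M"))
    return pd.DataFrame(
        {
            "hours": by_month.size(),
            "observed": by_month.count(),
            "completeness_pct": 100.0 * by_month.count() / by_month.size(),
        }
    )
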
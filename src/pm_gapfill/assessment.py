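"""Air-quality characterization of a filled hourly series.

Hourly values are banded against the WHO daily guideline of 15 ug/m3 (the
study's convention, deliberately replicated even though it compares hourly
values to a 24-hour threshold) and mapped to an AQI through a configurable
piecewise-linear breakpoint table (default: US EPA PM2.5 breakpoints,
pre-2024 revision).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

WHO_DAILY_THRESHOLD = 15.0  # ug/m3

#: Exceedance bands partition [0, inf): multiples of the WHO threshold.
EXCEEDANCE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("below", 0.0, 15.0),
    ("1-2x", 15.0, 30.0),
    ("2-4x", 30.0, 60.0),
    ("4-8x", 60.0, 120.0),
    (">8x", 120.0, float("inf")),
)

BAND_LABELS = tuple(label for label, _, _ in EXCEEDANCE_BANDS)


@dataclass(frozen=True)
class AqiBreakpoint:
    conc_lo: float
    conc_hi: float
    index_lo: int
    index_hi: int
    category: str


#: US EPA PM2.5 breakpoints (pre-2024 revision).
DEFAULT_AQI_BREAKPOINTS: tuple[AqiBreakpoint, ...] = (
    AqiBreakpoint(0.0, 12.0, 0, 50, "Good"),
    AqiBreakpoint(12.1, 35.4, 51, 100, "Moderate"),
    AqiBreakpoint(35.5, 55.4, 101, 150, "Unhealthy for Sensitive Groups"),
    AqiBreakpoint(55.5, 150.4, 151, 200, "Unhealthy"),
    AqiBreakpoint(150.5, 250.4, 201, 300, "Very Unhealthy"),
    AqiBreakpoint(250.5, 350.4, 301, 400, "Hazardous"),
    AqiBreakpoint(350.5, 500.4, 401, 500, "Hazardous"),
)


def classify_exceedance(pm25: float, who_threshold: float = WHO_DAILY_THRESHOLD) -> str:
    """Band label for one concentration; boundary values go to the upper band."""
    if np.isnan(pm25):
        return "missing"
    scale = who_threshold / WHO_DAILY_THRESHOLD
    for label, lo, hi in EXCEEDANCE_BANDS:
        if lo * scale <= pm25 < hi * scale:
            return label
    return EXCEEDANCE_BANDS[-1][0]


def _band_series(series: pd.Series, who_threshold: float = WHO_DAILY_THRESHOLD) -> pd.Series:
    scale = who_threshold / WHO_DAILY_THRESHOLD
    edges = [lo * scale for _, lo, _ in EXCEEDANCE_BANDS] + [float("inf")]
    codes = np.digitize(series.to_numpy(dtype=float), edges[1:-1], right=False)
    labels = pd.Series([BAND_LABELS[c] for c in codes], index=series.index)
    labels[series.isna()] = "missing"
    return labels


def _group_keys(series: pd.Series, by: str):
    if by == "overall":
        return pd.Series("overall", index=series.index)
    if by == "month":
        return series.index.to_period("M").astype(str)
    if by == "season":
        from pm_gapfill.synthetic import season_of_month

        return pd.Series([season_of_month(m) for m in series.index.month], index=series.index)
    raise ValueError(f"unknown grouping {by!r}")


def exceedance_summary(
    series: pd.Series | pd.DataFrame,
    by: str = "overall",
    who_threshold: float = WHO_DAILY_THRESHOLD,
) -> pd.DataFrame:
    """Per-group fraction of hours in each exceedance band (rows sum to 1)."""
    if isinstance(series, pd.DataFrame):
        series = series["pm25"]
    observed = series.dropna()
    bands = _band_series(observed, who_threshold)
    keys = _group_keys(observed, by)
    table = (
        pd.crosstab(keys, bands, normalize="index")
        .reindex(columns=list(BAND_LABELS), fill_value=0.0)
    )
    table.columns.name = None
    table.index.name = by
    return table


def compute_aqi(
    pm25: float | np.ndarray,
    breakpoints: Sequence[AqiBreakpoint] = DEFAULT_AQI_BREAKPOINTS,
) -> tuple[np.ndarray, np.ndarray] | tuple[float, str]:
    """Piecewise-linear AQI and category from PM2.5 concentration.

    Concentrations are truncated to 0.1 ug/m3 (the table's resolution)
    before segment interpolation; values above the top breakpoint clamp to
    the maximum index.
    """
    scalar = np.isscalar(pm25)
    conc = np.atleast_1d(np.asarray(pm25, dtype=float))
    trunc = np.floor(conc * 10.0) / 10.0
    index = np.full(conc.shape, np.nan)
    category = np.full(conc.shape, "", dtype=object)
    top = breakpoints[-1]
    for bp in breakpoints:
        sel = (trunc >= bp.conc_lo) & (trunc <= bp.conc_hi)
        span = bp.conc_hi - bp.conc_lo
        index[sel] = bp.index_lo + (trunc[sel] - bp.conc_lo) / span * (bp.index_hi - bp.index_lo)
        category[sel] = bp.category
    above = trunc > top.conc_hi
    index[above] = top.index_hi
    category[above] = top.category
    index = np.round(index)
    if scalar:
        return float(index[0]), str(category[0])
    return index, category


def descriptive_stats(series: pd.Series | pd.DataFrame, by: str = "overall") -> pd.DataFrame:
    """Count, mean, SD, extremes, quartiles, skewness and kurtosis per group.

    Skewness and excess kurtosis use the moment-based (Fisher) definitions;
    both are NaN for constant groups.
    """
    if isinstance(series, pd.DataFrame):
        series = series["pm25"]
    observed = series.dropna()
    keys = _group_keys(observed, by)

    def _stats(group: pd.Series) -> pd.Series:
        v = group.to_numpy(dtype=float)
        constant = v.std() == 0
        return pd.Series(
            {
                "count": len(v),
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                "min": v.min(),
                "q25": np.percentile(v, 25),
                "median": np.percentile(v, 50),
                "q75": np.percentile(v, 75),
                "max": v.max(),
                "skewness": np.nan if constant else stats.skew(v, bias=True),
                "kurtosis": np.nan if constant else stats.kurtosis(v, fisher=True, bias=True),
            }
        )

    out = observed.groupby(keys).apply(_stats)
    if isinstance(out, pd.Series):  # pandas returns a Series for uniform dtypes
        out = out.unstack()
    out.index.name = by
    return out


def build_assessment(
    series: pd.DataFrame,
    provenance: pd.Series | None = None,
    who_threshold: float = WHO_DAILY_THRESHOLD,
    breakpoints: Sequence[AqiBreakpoint] = DEFAULT_AQI_BREAKPOINTS,
) -> pd.DataFrame:
    """Per-hour assessment records on a filled series.

    ``provenance`` marks each hour ``observed`` or ``imputed`` (e.g. derived
    from a fill report); when omitted all hours are labelled observed.
    """
    pm = series["pm25"]
    index, category = compute_aqi(pm.to_numpy(dtype=float), breakpoints)
    out = pd.DataFrame(
        {
            "pm25": pm,
            "band": _band_series(pm, who_threshold),
            "aqi": index,
            "aqi_category": category,
            "provenance": provenance if provenance is not None else "observed",
        },
        index=series.index,
    )
    return out
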
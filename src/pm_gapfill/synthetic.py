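"""Synthetic hourly PM2.5 generator with controlled statistical structure.

The generated series emulates the qualitative structure of urban PM2.5
monitoring data: a positive, right-skewed marginal; a bimodal diurnal cycle
with morning and evening peaks; winter-elevated seasonal amplitude;
autocorrelated multiplicative noise; and a negatively coupled wind speed.
It exists so that every downstream module can be exercised without any
external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from pm_gapfill.errors import InvalidConfigError, PlacementError
from pm_gapfill.gaps import GapSpec

#: Minimum distance (points) between injected gaps and from either boundary.
#: Chosen so that full contexts exist for all fixed-context methods.
C_MAX = 32

_COMPASS_BIN = 22.5  # 16-point compass resolution, degrees


def season_of_month(month: int) -> int:
    """Season code: 1 winter, 2 spring, 3 summer, 4 autumn."""
    return {12: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2, 6: 3, 7: 3, 8: 3, 9: 4, 10: 4, 11: 4}[month]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic hourly series.

    ``diurnal_peaks`` are (hour, amplitude) pairs of Gaussian bumps added to
    a flat baseline; ``seasonal_amplitude`` is the fractional swing of the
    annual cycle (winter high); ``ar_coefficient`` drives an AR(1) noise
    process applied on the log scale; ``wind_coupling`` (<= 0) is the linear
    coefficient of wind speed subtracted from the concentration.
    """

    n_hours: int = 8760
    start_timestamp: str = "2024-01-01 00:00"
    base_level: float = 25.0
    diurnal_peaks: tuple[tuple[float, float], ...] = ((8.0, 0.45), (19.5, 0.40))
    seasonal_amplitude: float = 0.18
    ar_coefficient: float = 0.85
    noise_scale: float = 0.30
    synoptic_ar: float = 0.99  # slow "episode" component, e-folding ~4 days
    synoptic_scale: float = 0.35
    wind_coupling: float = -1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hours < 48:
            raise InvalidConfigError(f"n_hours must be >= 48, got {self.n_hours}")
        if not 0.0 <= self.ar_coefficient < 1.0 or not 0.0 <= self.synoptic_ar < 1.0:
            raise InvalidConfigError("AR coefficients must lie in [0, 1)")
        if self.wind_coupling > 0:
            raise InvalidConfigError("wind_coupling must be <= 0 (negative PM-wind correlation)")
        if self.base_level <= 0 or self.noise_scale < 0:
            raise InvalidConfigError("base_level must be positive and noise_scale non-negative")


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path with marginal standard deviation ``sd``."""
    innov_sd = sd * math.sqrt(1.0 - phi * phi) if sd > 0 else 0.0
    eps = rng.normal(0.0, innov_sd, size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd) if sd > 0 else 0.0
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def _diurnal_factor(hours: np.ndarray, peaks: Sequence[tuple[float, float]], width: float = 2.0) -> np.ndarray:
    """Bimodal diurnal multiplier: 1 + sum of circular Gaussian bumps."""
    factor = np.ones_like(hours, dtype=float)
    for peak_hour, amplitude in peaks:
        delta = np.abs(hours - peak_hour)
        delta = np.minimum(delta, 24.0 - delta)  # wrap around midnight
        factor += amplitude * np.exp(-0.5 * (delta / width) ** 2)
    return factor


def generate_series(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a deterministic hourly series with covariates.

    Returns a DataFrame indexed by hourly timestamps with columns
    ``pm25``, ``T``, ``U``, ``Ff``, ``DD``, ``hour``, ``season``.
    Concentration is built as base x seasonal x diurnal x exp(AR(1) noise)
    plus a (negative) wind-speed coupling term, clipped at zero.
    """
    rng = np.random.default_rng(config.seed)
    index = pd.date_range(config.start_timestamp, periods=config.n_hours, freq="h")

    day_of_year = index.dayofyear.to_numpy(dtype=float)
    hour = index.hour.to_numpy(dtype=float)

    # annual cycle peaking mid-January (winter elevated)
    seasonal = 1.0 + config.seasonal_amplitude * np.cos(2.0 * np.pi * (day_of_year - 15.0) / 365.25)
    diurnal = _diurnal_factor(hour, config.diurnal_peaks)
    # two-timescale log noise: hourly fluctuations plus multi-day episodes
    log_noise = _ar1(rng, config.n_hours, config.ar_coefficient, config.noise_scale) + _ar1(
        rng, config.n_hours, config.synoptic_ar, config.synoptic_scale
    )

    # covariates -------------------------------------------------------
    temp = (
        -2.0
        - 18.0 * np.cos(2.0 * np.pi * (day_of_year - 15.0) / 365.25)
        + 4.0 * np.sin(2.0 * np.pi * (hour - 9.0) / 24.0)
        + _ar1(rng, config.n_hours, 0.9, 2.5)
    )
    wind = np.clip(3.0 + _ar1(rng, config.n_hours, 0.92, 1.6), 0.0, None)
    humidity = np.clip(70.0 - 0.6 * (temp - temp.mean()) + _ar1(rng, config.n_hours, 0.85, 8.0), 5.0, 100.0)
    direction = np.mod(200.0 + np.cumsum(rng.normal(0.0, 12.0, size=config.n_hours)), 360.0)

    pm25 = config.base_level * seasonal * diurnal * np.exp(log_noise)
    pm25 = pm25 + config.wind_coupling * wind
    pm25 = np.clip(pm25, 0.0, None)

    return pd.DataFrame(
        {
            "pm25": pm25,
            "T": temp,
            "U": humidity,
            "Ff": wind,
            "DD": direction,
            "hour": index.hour.to_numpy(dtype=np.int64),
            "season": np.array([season_of_month(m) for m in index.month], dtype=np.int64),
        },
        index=index,
    )


def bin_wind_direction(degrees: np.ndarray) -> np.ndarray:
    """Snap degrees to the nearest of 16 compass points (still in degrees)."""
    return np.mod(np.round(np.asarray(degrees, dtype=float) / _COMPASS_BIN) * _COMPASS_BIN, 360.0)


@dataclass(frozen=True)
class GapPattern:
    """Synthetic missingness pattern: gaps of one length at a target fraction."""

    gap_length: int
    missing_fraction: float = 0.05
    min_separation: int = C_MAX

    def __post_init__(self) -> None:
        if self.gap_length < 1:
            raise InvalidConfigError("gap_length must be >= 1")
        if not 0.0 <= self.missing_fraction < 0.5:
            raise InvalidConfigError("missing_fraction must lie in [0, 0.5)")


def inject_missingness(
    series: pd.DataFrame | pd.Series,
    pattern: GapPattern,
    seed: int,
    max_tries: int = 200_000,
) -> tuple[pd.DataFrame | pd.Series, list[GapSpec]]:
    """Carve ``floor(f*N/L)`` non-overlapping gaps of length L into a copy.

    Gaps are separated by at least ``pattern.min_separation`` points from
    each other and from either boundary; original values are stored on the
    returned :class:`GapSpec` objects for later scoring.  Placement is by
    seeded rejection sampling and deterministic given ``seed``.
    """
    is_frame = isinstance(series, pd.DataFrame)
    values = (series["pm25"] if is_frame else series).to_numpy(dtype=float)
    n = len(values)
    L = pattern.gap_length
    sep = pattern.min_separation
    n_gaps = int(math.floor(pattern.missing_fraction * n / L))
    if n_gaps == 0:
        return series.copy(), []

    lo, hi = sep, n - sep - L  # inclusive start bounds
    if hi < lo:
        raise PlacementError(
            f"series of length {n} cannot host a length-{L} gap at distance >= {sep} from both boundaries"
        )
    # closed-form packing bound: k gaps need sep + (k-1)(L+sep) <= hi
    max_packable = 1 + (hi - lo) // (L + sep)
    if n_gaps > max_packable:
        raise PlacementError(
            f"cannot place {n_gaps} gaps of length {L}: at most {max_packable} fit in a series of "
            f"length {n} under the inter-gap/boundary separation of {sep} points"
        )

    rng = np.random.default_rng(seed)
    starts: list[int] = []
    tries = 0
    while len(starts) < n_gaps:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"placed only {len(starts)}/{n_gaps} gaps of length {L} after {max_tries} draws; "
                f"binding constraint: inter-gap separation >= {sep} points in a series of length {n}"
            )
        cand = int(rng.integers(lo, hi + 1))
        if all(cand + L + sep <= s or s + L + sep <= cand for s in starts):
            starts.append(cand)

    starts.sort()
    out = series.copy()
    gaps = []
    for i, s in enumerate(starts):
        prev_end = starts[i - 1] + L if i > 0 else 0
        next_start = starts[i + 1] if i + 1 < len(starts) else n
        gaps.append(
            GapSpec(
                start=s,
                length=L,
                left_context=s - prev_end,
                right_context=next_start - (s + L),
                truth=values[s : s + L].copy(),
            )
        )
        if is_frame:
            out.iloc[s : s + L, out.columns.get_loc("pm25")] = np.nan
        else:
            out.iloc[s : s + L] = np.nan
    return out, gaps
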
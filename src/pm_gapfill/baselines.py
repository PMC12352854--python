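"""Statistical and interpolation baselines for hourly gap filling.

All baselines operate on raw (unscaled) values: they are either constants,
exact interpolants, or scale-equivariant forecasts, so standardization
would change nothing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline

from pm_gapfill.errors import InsufficientDataError, InvalidConfigError, MethodInapplicableError
from pm_gapfill.gaps import GapSpec

logger = logging.getLogger(__name__)

_STATS = {"mean": np.mean, "median": np.median}


@dataclass(frozen=True)
class BaselineConfig:
    local_flank: int = 15  # hours either side of the gap
    linear_window: int = 10
    poly_degree: int = 3
    ar_order: tuple[int, int, int] = (1, 0, 0)
    ar_context: int = 100  # hours before the gap
    ar_min_context: int = 10
    max_anchors: int = 12  # per-side cap for polynomial/B-spline fits

    def __post_init__(self) -> None:
        if self.local_flank < 1 or self.linear_window < 1 or self.poly_degree < 1:
            raise InvalidConfigError("flanks, windows and poly_degree must be positive")


def _values(series) -> np.ndarray:
    if isinstance(series, pd.DataFrame):
        return series["pm25"].to_numpy(dtype=float)
    if isinstance(series, pd.Series):
        return series.to_numpy(dtype=float)
    return np.asarray(series, dtype=float)


def impute_global(series, gap: GapSpec, statistic: str = "mean") -> np.ndarray:
    """Constant fill with the mean/median of all observed values."""
    v = _values(series)
    observed = v[~np.isnan(v)]
    if observed.size == 0:
        raise InsufficientDataError("no observed values to compute a global statistic")
    return np.full(gap.length, _STATS[statistic](observed))


def impute_local(series, gap: GapSpec, statistic: str = "mean", flank: int = 15) -> np.ndarray:
    """Constant fill with the statistic of the flanking window.

    The window is [start - flank, stop + flank) intersected with the series,
    excluding the gap itself; an empty window falls back to the global
    statistic.
    """
    v = _values(series)
    lo = max(0, gap.start - flank)
    hi = min(len(v), gap.stop + flank)
    window = np.concatenate((v[lo : gap.start], v[gap.stop : hi]))
    window = window[~np.isnan(window)]
    if window.size == 0:
        return impute_global(series, gap, statistic)
    return np.full(gap.length, _STATS[statistic](window))


def _anchors(v: np.ndarray, gap: GapSpec, per_side: int) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Closest observed points on each side of the gap (indices, values, counts)."""
    left_idx = np.flatnonzero(~np.isnan(v[: gap.start]))[-per_side:]
    right_idx = gap.stop + np.flatnonzero(~np.isnan(v[gap.stop :]))[:per_side]
    idx = np.concatenate((left_idx, right_idx))
    return idx, v[idx], len(left_idx), len(right_idx)


def impute_interpolation(
    series,
    gap: GapSpec,
    kind: str = "linear",
    config: BaselineConfig | None = None,
) -> np.ndarray:
    """Curve fill through anchor points around the gap.

    ``linear`` needs one anchor per side and passes exactly through the two
    bounding observations; ``polynomial`` (degree 3) and ``bspline`` need at
    least two per side.  Anchor windows for the curved kinds take up to
    min(gap length, ``max_anchors``) points per side, floored at two.
    """
    config = config or BaselineConfig()
    v = _values(series)
    positions = gap.positions

    if kind == "linear":
        idx, vals, n_left, n_right = _anchors(v, gap, 1)
        if n_left < 1 or n_right < 1:
            raise MethodInapplicableError("linear interpolation needs an anchor on each side")
        return np.interp(positions, idx, vals)

    per_side = max(2, min(gap.length, config.max_anchors))
    idx, vals, n_left, n_right = _anchors(v, gap, per_side)
    if n_left < 2 or n_right < 2:
        raise MethodInapplicableError(f"{kind} interpolation needs >= 2 anchors on each side")

    if kind == "polynomial":
        degree = min(config.poly_degree, len(idx) - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            coeffs = np.polyfit(idx - gap.start, vals, degree)
        return np.polyval(coeffs, positions - gap.start)
    if kind == "bspline":
        k = min(3, len(idx) - 1)
        spline = make_interp_spline(idx.astype(float), vals, k=k)
        return np.asarray(spline(positions.astype(float)))
    raise InvalidConfigError(f"unknown interpolation kind: {kind!r}")


def impute_ar(series, gap: GapSpec, config: BaselineConfig | None = None) -> np.ndarray:
    """ARIMA(1,0,0) forecast from the run of observations preceding the gap.

    Uses up to ``ar_context`` contiguous pre-gap values (at least
    ``ar_min_context``); falls back to the local mean when estimation fails.
    """
    config = config or BaselineConfig()
    v = _values(series)
    pre = v[: gap.start]
    run = 0
    while run < len(pre) and not np.isnan(pre[len(pre) - 1 - run]):
        run += 1
    run = min(run, config.ar_context)
    if run < config.ar_min_context:
        raise MethodInapplicableError(
            f"AR imputation needs >= {config.ar_min_context} contiguous pre-gap points, found {run}"
        )
    context = pre[len(pre) - run :]
    try:
        from statsmodels.tsa.arima.model import ARIMA

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ARIMA(context, order=config.ar_order, trend="c")
            fitted = model.fit()
            forecast = np.asarray(fitted.forecast(steps=gap.length), dtype=float)
        if not np.all(np.isfinite(forecast)):
            raise ValueError("non-finite forecast")
        return forecast
    except Exception as exc:  # estimation failure -> documented fallback
        logger.warning("AR fit failed (%s); falling back to local mean", exc)
        return impute_local(series, gap, "mean", config.local_flank)
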
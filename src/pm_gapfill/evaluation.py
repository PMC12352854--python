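"""Unified benchmarking harness for synthetic-gap experiments.

Every registered method is scored on identical injected gap patterns within
each run; runs differ only in the gap-placement seed, while model fit seeds
stay constant, so run-to-run spread isolates placement variance.  Metrics
are computed on the raw ug/m3 scale over all gap positions pooled within a
run, then aggregated to mean +/- SD over runs.
"""

from __future__ import annotations

import hashlib
import time
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pm_gapfill.errors import ContractViolationError, InvalidConfigError, MethodInapplicableError
from pm_gapfill.gaps import GapSpec
from pm_gapfill.synthetic import GapPattern, inject_missingness
from pm_gapfill.windowed import derive_seed, split_time_based

MAPE_EPSILON = 1e-8


def _check_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ContractViolationError(f"y and yhat must be 1-D and equally long, got {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ContractViolationError("empty input")
    return y, yhat


def metric_mae(y, yhat) -> float:
    """Mean absolute error."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def metric_rmse(y, yhat) -> float:
    """Root mean square error."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def metric_mape(y, yhat, epsilon: float = MAPE_EPSILON) -> float:
    """Mean absolute percentage error with an epsilon guard, in percent."""
    y, yhat = _check_pair(y, yhat)
    return float(100.0 * np.mean(np.abs(y - yhat) / (y + epsilon)))


def metric_r2(y, yhat) -> float:
    """Coefficient of determination; NaN (with a warning) when y is constant."""
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("R^2 undefined for constant observations; returning NaN", stacklevel=2)
        return float("nan")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


def compute_metrics(y, yhat) -> dict[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2 = metric_r2(y, yhat)
    return {
        "mae": metric_mae(y, yhat),
        "rmse": metric_rmse(y, yhat),
        "mape": metric_mape(y, yhat),
        "r2": r2,
        "n_points": int(len(np.asarray(y))),
    }


@dataclass(frozen=True)
class BenchmarkConfig:
    gap_lengths: tuple[int, ...] = (5, 12, 24, 48, 72)
    missing_fraction: float = 0.05
    n_runs: int = 5
    master_seed: int = 0
    train_fraction: float = 0.8
    min_separation: int = 32

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise InvalidConfigError("n_runs must be >= 1")
        if not 0.0 < self.missing_fraction < 0.5:
            raise InvalidConfigError("missing_fraction must lie in (0, 0.5)")


#: A method factory maps a gap length to a ready-to-fit imputer exposing
#: ``name``, ``fit(train_frame)`` and ``impute(series_frame, gap) -> values``.
MethodFactory = Callable[[int], object]


def _mask_hash(gaps: Sequence[GapSpec]) -> str:
    payload = ",".join(f"{g.start}:{g.length}" for g in gaps)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_benchmark(
    config: BenchmarkConfig,
    series: pd.DataFrame,
    methods: Mapping[str, MethodFactory],
) -> pd.DataFrame:
    """Synthetic-gap benchmark over (method, gap length, run) cells.

    Gaps are injected only into the chronological test split; all methods in
    a run see the same gap pattern (the pattern hash is recorded).  Methods
    that raise :class:`MethodInapplicableError` on a gap have it excluded
    from their pooled metrics, reported via the ``coverage`` column.
    """
    train, test = split_time_based(series, config.train_fraction)
    if len(test) == 0:
        raise InvalidConfigError("empty test split; lower train_fraction")
    n_train = len(train)

    rows = []
    for gap_length in config.gap_lengths:
        # fit each method once per gap length; fits are reused across runs
        fitted = {}
        for name, factory in methods.items():
            imputer = factory(gap_length)
            imputer.fit(train)
            fitted[name] = imputer

        pattern = GapPattern(gap_length, config.missing_fraction, config.min_separation)
        for run in range(config.n_runs):
            placement_seed = derive_seed(config.master_seed, "placement", gap_length, run)
            holed_test, test_gaps = inject_missingness(test, pattern, placement_seed)
            # offset gap coordinates into the full series
            gaps = [
                GapSpec(
                    start=g.start + n_train,
                    length=g.length,
                    left_context=g.left_context,
                    right_context=g.right_context,
                    truth=g.truth,
                )
                for g in test_gaps
            ]
            holed = series.copy()
            pm_col = holed.columns.get_loc("pm25")
            for g in gaps:
                holed.iloc[g.start : g.stop, pm_col] = np.nan
            pattern_hash = _mask_hash(gaps)

            for name, imputer in fitted.items():
                t0 = time.perf_counter()
                truths, preds = [], []
                n_failed = 0
                for g in gaps:
                    try:
                        yhat = np.asarray(imputer.impute(holed, g), dtype=float)
                    except MethodInapplicableError:
                        n_failed += 1
                        continue
                    if yhat.shape != (g.length,):
                        raise ContractViolationError(
                            f"{name} returned {yhat.shape} for a length-{g.length} gap"
                        )
                    truths.append(g.truth)
                    preds.append(yhat)
                runtime = time.perf_counter() - t0
                if not truths:
                    continue
                y = np.concatenate(truths)
                yhat = np.concatenate(preds)
                row = {
                    "method": name,
                    "gap_length": gap_length,
                    "run": run,
                    **compute_metrics(y, yhat),
                    "coverage": (len(gaps) - n_failed) / len(gaps),
                    "runtime_s": runtime,
                    "pattern_hash": pattern_hash,
                }
                rows.append(row)
    return pd.DataFrame(rows)


def aggregate_results(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD over runs for each (method, gap_length) cell."""
    grouped = results.groupby(["method", "gap_length"])
    agg = grouped.agg(
        mae_mean=("mae", "mean"),
        mae_sd=("mae", "std"),
        rmse_mean=("rmse", "mean"),
        rmse_sd=("rmse", "std"),
        mape_mean=("mape", "mean"),
        mape_sd=("mape", "std"),
        r2_mean=("r2", "mean"),
        r2_sd=("r2", "std"),
        runtime_mean_s=("runtime_s", "mean"),
        n_runs=("run", "nunique"),
    ).reset_index()
    for metric in ("mae", "rmse", "mape", "r2"):
        agg[metric] = [
            f"{m:.3f} ± {0.0 if np.isnan(s) else s:.3f}"
            for m, s in zip(agg[f"{metric}_mean"], agg[f"{metric}_sd"])
        ]
    return agg


def paired_method_test(results_a: pd.DataFrame, results_b: pd.DataFrame) -> float:
    """Paired t-test on MAE over matched (gap_length, run) cells.

    Returns NaN when the paired differences have zero variance (including
    identical inputs).
    """
    a = results_a.set_index(["gap_length", "run"])["mae"].sort_index()
    b = results_b.set_index(["gap_length", "run"])["mae"].sort_index()
    if not a.index.equals(b.index):
        raise ContractViolationError("result tables cover different (gap_length, run) cells")
    diff = a.to_numpy() - b.to_numpy()
    if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
        return float("nan")
    return float(stats.ttest_rel(a.to_numpy(), b.to_numpy()).pvalue)
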
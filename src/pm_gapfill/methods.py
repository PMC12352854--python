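"""Named imputation methods with the common fit/impute interface.

Every method exposes ``name``, ``fit(train_frame)`` and
``impute(series_frame, gap) -> values``; factories parameterized by gap
length feed the benchmark harness.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from pm_gapfill import baselines
from pm_gapfill.dynamic import DynamicConfig, DynamicImputer
from pm_gapfill.gaps import GapSpec
from pm_gapfill.windowed import ImputerSpec, WindowedImputer


class BaselineImputer:
    """Wrap a stateless baseline function behind the fit/impute interface."""

    def __init__(self, name: str, fn: Callable[[pd.DataFrame, GapSpec], np.ndarray]) -> None:
        self.name = name
        self._fn = fn

    def fit(self, train: pd.DataFrame) -> "BaselineImputer":
        return self

    def impute(self, series: pd.DataFrame, gap: GapSpec) -> np.ndarray:
        return self._fn(series, gap)


def baseline_method(name: str, config: baselines.BaselineConfig | None = None) -> BaselineImputer:
    config = config or baselines.BaselineConfig()
    table: dict[str, Callable] = {
        "global-mean": lambda s, g: baselines.impute_global(s, g, "mean"),
        "global-median": lambda s, g: baselines.impute_global(s, g, "median"),
        "local-mean": lambda s, g: baselines.impute_local(s, g, "mean", config.local_flank),
        "local-median": lambda s, g: baselines.impute_local(s, g, "median", config.local_flank),
        "interp-linear": lambda s, g: baselines.impute_interpolation(s, g, "linear", config),
        "interp-polynomial": lambda s, g: baselines.impute_interpolation(s, g, "polynomial", config),
        "interp-bspline": lambda s, g: baselines.impute_interpolation(s, g, "bspline", config),
        "arima": lambda s, g: baselines.impute_ar(s, g, config),
    }
    if name not in table:
        raise KeyError(f"unknown baseline {name!r}; options: {sorted(table)}")
    return BaselineImputer(name, table[name])


def make_method(name: str, seed: int = 0):
    """Factory of factories: map a method name to gap-length-aware builder.

    Windowed method names follow ``<backend>-<strategy>-<direction>[-multi]``,
    e.g. ``gbrt-seq2seq-bi``, ``rf-autoreg-uni-multi``; dynamic methods are
    ``dynamic-uni`` / ``dynamic-multi``; everything else is a baseline.
    """
    if name.startswith("dynamic"):
        variables = "multivariate" if name.endswith("multi") else "univariate"

        def dynamic_factory(gap_length: int) -> DynamicImputer:
            return DynamicImputer(DynamicConfig(variables=variables), seed=seed, name=name)

        return dynamic_factory

    parts = name.split("-")
    if parts[0] in ("gbrt", "rf"):
        backend, strategy, direction = parts[0], parts[1], parts[2]
        variables = "multivariate" if (len(parts) > 3 and parts[3] == "multi") else "univariate"
        strategy = {"autoreg": "autoregressive", "seq2seq": "seq2seq"}[strategy]
        direction = {"uni": "unidirectional", "bi": "bidirectional"}[direction]

        def windowed_factory(gap_length: int) -> WindowedImputer:
            horizon = gap_length if strategy == "seq2seq" else 1
            spec = ImputerSpec(
                strategy=strategy,
                directionality=direction,
                variables=variables,
                backend=backend,
                horizon=horizon,
            )
            return WindowedImputer(spec, seed=seed, name=name)

        return windowed_factory

    def baseline_factory(gap_length: int) -> BaselineImputer:
        return baseline_method(name)

    return baseline_factory
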
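import numpy as np
import pandas as pd
import pytest

from pm_gapfill.synthetic import GeneratorConfig, generate_series


@pytest.fixture(scope="session")
def default_series() -> pd.DataFrame:
    """One year of synthetic hourly data with the default configuration."""
    return generate_series(GeneratorConfig(n_hours=8760, seed=1))


@pytest.fixture(scope="session")
def short_series() -> pd.DataFrame:
    """A small series for cheap structural tests."""
    return generate_series(GeneratorConfig(n_hours=600, seed=11))


@pytest.fixture()
def hourly_index():
    def _make(n: int, start: str = "2024-05-01"):
        return pd.date_range(start, periods=n, freq="h")

    return _make


@pytest.fixture()
def series_with_gap(hourly_index):
    """Factory: an hourly pm25 series with one hand-placed gap."""

    def _make(values, gap_start, gap_len):
        v = np.asarray(values, dtype=float).copy()
        v[gap_start : gap_start + gap_len] = np.nan
        return pd.Series(v, index=hourly_index(len(v)), name="pm25")

    return _make
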
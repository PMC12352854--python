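"""Detection and description of contiguous missing runs in an hourly series."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GapSpec:
    """One maximal contiguous missing run.

    ``left_context`` / ``right_context`` give the number of consecutive
    observed values between the gap and the previous/next missing value
    (or the series boundary).  ``truth`` carries held-out values when the
    gap was injected synthetically, so it can be scored later.
    """

    start: int
    length: int
    left_context: int
    right_context: int
    truth: Optional[np.ndarray] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.length < 1 or self.start < 0:
            raise ValueError(f"invalid gap: start={self.start}, length={self.length}")

    @property
    def stop(self) -> int:
        """One past the last missing index (half-open range)."""
        return self.start + self.length

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


def _as_values(series) -> np.ndarray:
    if isinstance(series, pd.DataFrame):
        return series["pm25"].to_numpy(dtype=float)
    if isinstance(series, pd.Series):
        return series.to_numpy(dtype=float)
    return np.asarray(series, dtype=float)


def find_gaps(series) -> list[GapSpec]:
    """Locate all maximal missing runs, sorted by start index.

    Context lengths count consecutive observed values flanking each gap,
    bounded by the previous/next gap or the series boundary.
    """
    values = _as_values(series)
    n = len(values)
    missing = np.isnan(values)
    if n == 0 or not missing.any():
        return []

    # run-length encode the missingness mask
    boundaries = np.flatnonzero(np.diff(missing.astype(np.int8)))
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [n]))
    runs = [(s, e) for s, e in zip(starts, ends) if missing[s]]

    gaps: list[GapSpec] = []
    for i, (s, e) in enumerate(runs):
        prev_end = runs[i - 1][1] if i > 0 else 0
        next_start = runs[i + 1][0] if i + 1 < len(runs) else n
        gaps.append(
            GapSpec(
                start=int(s),
                length=int(e - s),
                left_context=int(s - prev_end),
                right_context=int(next_start - e),
            )
        )
    return gaps


def gap_length_histogram(gaps: Iterable[GapSpec]) -> dict[int, int]:
    """Count gaps by exact length."""
    return dict(sorted(Counter(g.length for g in gaps).items()))


def gap_report(series: pd.DataFrame | pd.Series, gaps: Sequence[GapSpec] | None = None) -> pd.DataFrame:
    """Tabular gap report (start timestamp, length, available context)."""
    if gaps is None:
        gaps = find_gaps(series)
    index = series.index
    return pd.DataFrame(
        {
            "start_timestamp": [index[g.start] for g in gaps],
            "length_hours": [g.length for g in gaps],
            "left_context": [g.left_context for g in gaps],
            "right_context": [g.right_context for g in gaps],
        }
    )
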
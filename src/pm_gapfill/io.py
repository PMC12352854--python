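"""Readers and writers for the plain-text series formats used throughout.

Hourly series travel as CSV with an ISO-8601 ``timestamp`` column; missing
values are encoded as empty fields.  Minute-level raw data is accepted as
CSV or as an SQLite database with a configurable column mapping.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path
from typing import Mapping

import pandas as pd

DEFAULT_COLUMN_MAP: Mapping[str, str] = {"timestamp": "timestamp", "pm25": "pm25"}


def write_hourly_csv(series: pd.DataFrame, path: str | Path) -> None:
    out = series.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False, na_rep="")


def read_hourly_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, parse_dates=["timestamp"])
    frame = frame.set_index("timestamp")
    frame.index.name = None
    return frame


def read_minute_csv(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read minute-level records; returns a frame indexed by timestamp."""
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    frame = pd.read_csv(path)
    rename = {src: dst for dst, src in column_map.items() if src in frame.columns}
    frame = frame.rename(columns=rename)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    frame = frame.set_index("timestamp").sort_index()
    frame.index.name = None
    return frame


def read_minute_sqlite(
    path: str | Path,
    table: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read minute-level records from a one-table SQLite measurement deposit.

    When ``table`` is omitted the first user table is used.  ``column_map``
    maps canonical names (``timestamp``, ``pm25``, optionally ``temperature``,
    ``humidity``) to the column names found in the database.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    with sqlite3.connect(str(path)) as conn:
        if table is None:
            tables = [
                row[0]
                for row in conn.execute(
                    "SELECT name FROM sqlite_master WHERE type='table' AND name NOT LIKE 'sqlite_%'"
                )
            ]
            if not tables:
                raise ValueError(f"no tables found in {path}")
            table = tables[0]
        frame = pd.read_sql_query(f'SELECT * FROM "{table}"', conn)
    rename = {src: dst for dst, src in column_map.items() if src in frame.columns}
    frame = frame.rename(columns=rename)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    frame = frame.set_index("timestamp").sort_index()
    frame.index.name = None
    return frame


def read_meteorology_csv(path: str | Path, timestamp_column: str = "timestamp") -> pd.DataFrame:
    """Read an hourly meteorology table (columns such as T, P0, P, U, DD, Ff, VV)."""
    frame = pd.read_csv(path)
    frame[timestamp_column] = pd.to_datetime(frame[timestamp_column])
    frame = frame.set_index(timestamp_column).sort_index()
    frame.index.name = None
    return frame
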
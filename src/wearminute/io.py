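"""Reading minute-level CSV exports and writing the canonical per-participant CSV.

Exports arrive as one file per data stream (heart rate, steps, intensity,
sleep stage) with columns like ``Id, ActivityMinute, Value``.  Timestamps are
accepted both as ISO-8601 and as the ``M/D/YYYY H:MM:SS AM/PM`` dialect used
by Fitabase exports.  A YAML config can map file patterns to streams and
column names; without one, streams are recognized from header column names.
"""

from __future__ import annotations

import fnmatch
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import (
    HR_MAX,
    HR_MIN,
    INTENSITY_CODE,
    INTENSITY_LABELS,
    MinuteGrid,
    MinuteRecord,
    build_minute_grid,
    _round_half_up,
)

STREAMS = ("heart_rate", "steps", "intensity", "sleep")

# header value-column name (lowercase) -> stream
_VALUE_COLUMN_STREAMS = {
    "heartrate": "heart_rate",
    "heart_rate": "heart_rate",
    "bpm": "heart_rate",
    "steps": "steps",
    "intensity": "intensity",
    "sleepstage": "sleep",
    "sleep_stage": "sleep",
}
_TIME_COLUMNS = ("activityminute", "time", "date", "timestamp")
_ID_COLUMNS = ("id", "participant_id")

# Fitbit/Fitabase encodes intensity as 0..3
_INTENSITY_FROM_INT = {i: label for label, i in INTENSITY_CODE.items()}


class UnrecognizedStreamError(ValueError):
    """Raised when a CSV header matches no known stream."""


@dataclass
class StreamSpec:
    """How to read one family of CSV files."""

    stream: str
    pattern: str = "*"
    id_column: str = "Id"
    time_column: str = "ActivityMinute"
    value_column: str = "Value"

    def __post_init__(self) -> None:
        if self.stream not in STREAMS:
            raise ValueError(f"unknown stream {self.stream!r}; expected one of {STREAMS}")


@dataclass
class ParseIssue:
    """A record-level problem; the run continues past these."""

    path: str
    line: int  # 1-based line number in the file (header = line 1)
    message: str


@dataclass
class ParseResult:
    records: list[MinuteRecord]
    issues: list[ParseIssue] = field(default_factory=list)


def load_stream_config(path: str | Path) -> list[StreamSpec]:
    """Read a YAML config mapping file patterns to streams.

    Expected shape::

        streams:
          - pattern: "*heartrate*"
            stream: heart_rate
            time_column: Time     # optional overrides
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for entry in raw.get("streams", []):
        specs.append(StreamSpec(**entry))
    return specs


def _match_spec(path: str, specs: list[StreamSpec] | None) -> StreamSpec | None:
    if not specs:
        return None
    name = os.path.basename(path)
    for spec in specs:
        if fnmatch.fnmatch(name, spec.pattern):
            return spec
    return None


def _sniff_spec(path: str, columns: list[str]) -> StreamSpec:
    """Recognize the stream from header column names."""
    lower = {c.lower().strip(): c for c in columns}
    id_col = next((lower[c] for c in _ID_COLUMNS if c in lower), None)
    time_col = next((lower[c] for c in _TIME_COLUMNS if c in lower), None)
    value_col = None
    stream = None
    for key, st in _VALUE_COLUMN_STREAMS.items():
        if key in lower:
            stream, value_col = st, lower[key]
            break
    if stream is None and "value" in lower:
        # Fitabase: heart rate files are Id,Time,Value; sleep adds a logId column
        value_col = lower["value"]
        stream = "sleep" if "logid" in lower else "heart_rate"
    if id_col is None or time_col is None or stream is None:
        raise UnrecognizedStreamError(
            f"{path}: header {columns!r} matches no known minute stream"
        )
    return StreamSpec(stream=stream, id_column=id_col, time_column=time_col,
                      value_column=value_col)


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    """ISO-8601 first, then the Fitabase AM/PM dialect; NaT where unparseable."""
    ts = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    bad = ts.isna()
    if bad.any():
        fallback = pd.to_datetime(
            raw[bad], format="%m/%d/%Y %I:%M:%S %p", errors="coerce"
        )
        ts = ts.copy()
        ts[bad] = fallback
    return ts


def _parse_values(stream: str, raw: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Return (parsed values, boolean mask of invalid entries)."""
    if stream == "intensity":
        txt = raw.astype(str).str.strip()
        as_num = pd.to_numeric(txt, errors="coerce")
        labels = txt.str.lower().map(INTENSITY_CODE)
        code = as_num.where(as_num.isin(list(range(4)))).fillna(labels)
        return code, code.isna()
    num = pd.to_numeric(raw, errors="coerce")
    if stream == "sleep":
        bad = ~num.isin([1, 2, 3])
        return num, bad
    bad = num.isna() | (num < 0)
    return num, bad


def parse_minute_csvs(
    paths: list[str | Path],
    config: list[StreamSpec] | str | Path | None = None,
) -> ParseResult:
    """Parse per-stream CSV files and merge them per (participant, minute).

    Duplicate rows within one stream for one minute (including sub-minute
    heart-rate exports) are aggregated before merging: numeric values are
    averaged (half-up rounding for integers), categorical values take the
    maximum.  Rows with unparseable timestamps or values are collected as
    :class:`ParseIssue` and skipped; an unrecognizable header is a hard error.
    """
    if isinstance(config, (str, Path)):
        config = load_stream_config(config)

    issues: list[ParseIssue] = []
    # (pid, minute) -> field dict
    merged: dict[tuple[str, pd.Timestamp], dict] = {}

    for path in paths:
        path = str(path)
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
        spec = _match_spec(path, config)
        if spec is None:
            spec = _sniff_spec(path, list(df.columns))
        for col in (spec.id_column, spec.time_column, spec.value_column):
            if col not in df.columns:
                raise UnrecognizedStreamError(
                    f"{path}: expected column {col!r} not in header {list(df.columns)!r}"
                )
        ts = _parse_timestamps(df[spec.time_column])
        values, bad_value = _parse_values(spec.stream, df[spec.value_column])
        for i in np.flatnonzero(ts.isna().to_numpy()):
            issues.append(ParseIssue(path, int(i) + 2, f"unparseable timestamp "
                                                       f"{df[spec.time_column].iloc[i]!r}"))
        for i in np.flatnonzero((bad_value & ts.notna()).to_numpy()):
            issues.append(ParseIssue(path, int(i) + 2, f"invalid {spec.stream} value "
                                                       f"{df[spec.value_column].iloc[i]!r}"))
        ok = ts.notna() & ~bad_value
        sub = pd.DataFrame(
            {
                "pid": df[spec.id_column][ok].astype(str).str.strip(),
                "minute": ts[ok].dt.floor("min"),
                "value": values[ok].astype(float),
            }
        )
        if sub.empty:
            continue
        grouped = sub.groupby(["pid", "minute"], sort=False)["value"]
        agg = grouped.max() if spec.stream in ("intensity", "sleep") else grouped.mean()
        for (pid, minute), val in agg.items():
            fields = merged.setdefault((pid, minute), {})
            if spec.stream == "heart_rate":
                fields["heart_rate"] = _round_half_up(val)
            elif spec.stream == "steps":
                fields["steps"] = _round_half_up(val)
            elif spec.stream == "intensity":
                fields["intensity"] = _INTENSITY_FROM_INT[int(val)]
            else:
                fields["sleep_stage"] = int(val)

    records = [
        MinuteRecord(participant_id=pid, timestamp=minute, **fields)
        for (pid, minute), fields in sorted(merged.items())
    ]
    return ParseResult(records=records, issues=issues)


# ---------------------------------------------------------------------------
# canonical per-participant CSV

CANONICAL_COLUMNS = [
    "participant_id", "timestamp", "heart_rate", "steps", "intensity", "sleep_stage",
]


def write_minutes_csv(grid: MinuteGrid, path: str | Path) -> None:
    """Write the canonical per-participant minute CSV (empty string = absent)."""
    df = grid.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    for col in ("heart_rate", "steps"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df["intensity"] = df["intensity"].fillna("")
    df["sleep_stage"] = df["sleep_stage"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False, columns=CANONICAL_COLUMNS)


def read_minutes_csv(path: str | Path) -> MinuteGrid:
    """Read a canonical minute CSV back into a dense grid."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise UnrecognizedStreamError(f"{path}: missing canonical columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MinuteRecord(
                participant_id=row.participant_id,
                timestamp=pd.Timestamp(row.timestamp),
                heart_rate=None if _blank(row.heart_rate) else int(row.heart_rate),
                steps=None if _blank(row.steps) else int(row.steps),
                intensity=None if _blank(row.intensity) else row.intensity,
                sleep_stage=None if _blank(row.sleep_stage) else int(float(row.sleep_stage)),
            )
        )
    return build_minute_grid(records)


def _blank(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == ""
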
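"""Canonical minute-level containers.

The unit of analysis is the participant-minute: each minute of local civil
time may carry a heart rate (bpm), a step count, a device intensity label
(sedentary / lightly / moderately / very active) and a sleep-stage label
(1 = asleep, 2 = restless, 3 = awake during a sleep period; absent means
fully awake or device off).  All times are naive local clock times at
minute resolution; no timezone or DST arithmetic is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTENSITY_LABELS = ("sedentary", "lightly_active", "moderately_active", "very_active")
INTENSITY_CODE = {label: i for i, label in enumerate(INTENSITY_LABELS)}
INTENSITY_ABSENT = -1  # int8 sentinel

STAGE_ABSENT = 0
STAGE_ASLEEP = 1
STAGE_RESTLESS = 2
STAGE_AWAKE = 3

#: physiologically plausible heart-rate range (bpm); values outside are
#: treated as nonwear by the wear-time proxy
HR_MIN, HR_MAX = 20, 250

MINUTE = pd.Timedelta(minutes=1)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class MinuteRecord:
    """One participant-minute; any measurement field may be absent (None)."""

    participant_id: str
    timestamp: pd.Timestamp
    heart_rate: int | None = None
    steps: int | None = None
    intensity: str | None = None
    sleep_stage: int | None = None

    def __post_init__(self) -> None:
        self.timestamp = pd.Timestamp(self.timestamp).floor("min")
        if self.intensity is not None and self.intensity not in INTENSITY_CODE:
            raise ValueError(f"unknown intensity label {self.intensity!r}")
        if self.sleep_stage is not None and self.sleep_stage not in (1, 2, 3):
            raise ValueError(f"sleep stage must be 1, 2 or 3, got {self.sleep_stage!r}")


@dataclass
class MinuteGrid:
    """Dense per-minute arrays for one participant over [start, end).

    heart_rate and steps are float arrays with NaN for absent; intensity is
    int8 with -1 absent; sleep_stage is int8 with 0 absent.
    """

    participant_id: str
    start: pd.Timestamp
    heart_rate: np.ndarray
    steps: np.ndarray
    intensity: np.ndarray
    sleep_stage: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start).floor("min")
        n = len(self.heart_rate)
        for name in ("steps", "intensity", "sleep_stage"):
            if len(getattr(self, name)) != n:
                raise ValueError("all minute arrays must have equal length")
        self.heart_rate = np.asarray(self.heart_rate, dtype=float)
        self.steps = np.asarray(self.steps, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=np.int8)
        self.sleep_stage = np.asarray(self.sleep_stage, dtype=np.int8)

    @property
    def n_minutes(self) -> int:
        return len(self.heart_rate)

    @property
    def end(self) -> pd.Timestamp:
        return self.start + self.n_minutes * MINUTE

    def minutes(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_minutes, freq="min")

    def index_of(self, ts: pd.Timestamp) -> int:
        """Array index of a minute-aligned timestamp (may be out of range)."""
        return int((pd.Timestamp(ts) - self.start) / MINUTE)

    def to_frame(self) -> pd.DataFrame:
        """Long-form frame with one row per minute; absent encoded as NaN/empty."""
        intensity = pd.array(
            [INTENSITY_LABELS[c] if c >= 0 else None for c in self.intensity],
            dtype="string",
        )
        stage = pd.array(
            [s if s > 0 else None for s in self.sleep_stage], dtype="Int64"
        )
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "timestamp": self.minutes(),
                "heart_rate": self.heart_rate,
                "steps": self.steps,
                "intensity": intensity,
                "sleep_stage": stage,
            }
        )

    @staticmethod
    def empty(participant_id: str, start: pd.Timestamp, n_minutes: int) -> "MinuteGrid":
        return MinuteGrid(
            participant_id=participant_id,
            start=start,
            heart_rate=np.full(n_minutes, np.nan),
            steps=np.full(n_minutes, np.nan),
            intensity=np.full(n_minutes, INTENSITY_ABSENT, dtype=np.int8),
            sleep_stage=np.full(n_minutes, STAGE_ABSENT, dtype=np.int8),
        )


def build_minute_grid(records: list[MinuteRecord]) -> MinuteGrid:
    """Densify records into a MinuteGrid from the first to the last minute.

    Duplicate records for one minute are resolved deterministically
    (order-robust): numeric fields are averaged with half-up rounding,
    categorical fields take the maximal observed value.
    """
    if not records:
        raise ValueError("no data for participant")
    pids = {r.participant_id for r in records}
    if len(pids) > 1:
        raise ValueError(f"records span multiple participants: {sorted(pids)}")
    pid = records[0].participant_id

    start = min(r.timestamp for r in records)
    end = max(r.timestamp for r in records) + MINUTE
    n = int((end - start) / MINUTE)
    grid = MinuteGrid.empty(pid, start, n)

    by_minute: dict[int, list[MinuteRecord]] = {}
    for r in records:
        by_minute.setdefault(grid.index_of(r.timestamp), []).append(r)

    for i, recs in by_minute.items():
        hrs = [r.heart_rate for r in recs if r.heart_rate is not None]
        if hrs:
            grid.heart_rate[i] = _round_half_up(float(np.mean(hrs)))
        steps = [r.steps for r in recs if r.steps is not None]
        if steps:
            grid.steps[i] = _round_half_up(float(np.mean(steps)))
        intens = [r.intensity for r in recs if r.intensity is not None]
        if intens:
            grid.intensity[i] = max(INTENSITY_CODE[v] for v in intens)
        stages = [r.sleep_stage for r in recs if r.sleep_stage is not None]
        if stages:
            grid.sleep_stage[i] = max(stages)
    return grid
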
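"""Sleep-cycle extraction and main-sleep-period identification.

A sleep cycle is a maximal run of consecutive minutes carrying any sleep
stage label (1 asleep, 2 restless, 3 awake-within-sleep); unlabeled minutes
separate cycles.  Each night is anchored by the calendar date on which its
18:00 window opens (night_key): the night window is
[18:00 night_key, 06:00 night_key+1).

Rule A merges every cycle whose onset lies in the night window into one
main period spanning the first onset to the last wake; gap minutes between
merged cycles become in-period wakefulness.  Rule B (late-onset fallback)
applies when no cycle starts in the window: the longest cycle with onset in
[06:00, 18:00) of night_key+1 is taken and extended by subsequent cycles
starting within `late_merge_gap_min` of the running end.  Cycles beginning
after the main period's wake are naps and are excluded.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import MINUTE, MinuteGrid, STAGE_ABSENT

DEFAULT_LATE_MERGE_GAP_MIN = 60


@dataclass
class SleepCycle:
    """Maximal stage-labeled run over [start, end)."""

    participant_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    stages: np.ndarray  # int8, one stage per minute, all in {1,2,3}

    @property
    def n_minutes(self) -> int:
        return int((self.end - self.start) / MINUTE)


@dataclass
class MainSleepPeriod:
    participant_id: str
    night_key: datetime.date
    onset: pd.Timestamp
    wake: pd.Timestamp
    cycles: list[SleepCycle] = field(default_factory=list)
    is_late_onset: bool = False

    @property
    def span_minutes(self) -> int:
        return int((self.wake - self.onset) / MINUTE)

    def span_stages(self) -> np.ndarray:
        """Per-minute stages over [onset, wake); 0 where no cycle covers the minute."""
        out = np.zeros(self.span_minutes, dtype=np.int8)
        for c in self.cycles:
            i = int((c.start - self.onset) / MINUTE)
            out[i:i + c.n_minutes] = c.stages
        return out


def extract_sleep_cycles(grid: MinuteGrid) -> list[SleepCycle]:
    """Maximal runs of stage-labeled minutes, in time order."""
    labeled = grid.sleep_stage != STAGE_ABSENT
    if not labeled.any():
        return []
    padded = np.concatenate([[False], labeled, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [
        SleepCycle(
            participant_id=grid.participant_id,
            start=grid.start + int(s) * MINUTE,
            end=grid.start + int(e) * MINUTE,
            stages=grid.sleep_stage[s:e].copy(),
        )
        for s, e in zip(starts, ends)
    ]


def night_window(night_key: datetime.date) -> tuple[pd.Timestamp, pd.Timestamp]:
    d = pd.Timestamp(night_key)
    return d + pd.Timedelta(hours=18), d + pd.Timedelta(hours=30)


def identify_main_sleep(
    cycles: list[SleepCycle],
    night_key: datetime.date,
    late_merge_gap_min: int = DEFAULT_LATE_MERGE_GAP_MIN,
) -> MainSleepPeriod | None:
    """The night's main sleep period, or None when no cycle qualifies."""
    if not cycles:
        return None
    cycles = sorted(cycles, key=lambda c: c.start)
    win_lo, win_hi = night_window(night_key)

    in_window = [c for c in cycles if win_lo <= c.start < win_hi]
    if in_window:
        return MainSleepPeriod(
            participant_id=in_window[0].participant_id,
            night_key=night_key,
            onset=in_window[0].start,
            wake=in_window[-1].end,
            cycles=in_window,
            is_late_onset=False,
        )

    # Rule B: post-06:00 onset, [06:00, 18:00) of night_key + 1
    late_lo, late_hi = win_hi, win_hi + pd.Timedelta(hours=12)
    candidates = [c for c in cycles if late_lo <= c.start < late_hi]
    if not candidates:
        return None
    seed = max(candidates, key=lambda c: c.n_minutes)
    merged = [seed]
    gap = pd.Timedelta(minutes=late_merge_gap_min)
    for c in cycles:
        if c.start <= merged[-1].end or c is seed:
            continue
        # chain stops at the next night window so no cycle serves two nights
        if c.start - merged[-1].end <= gap and c.start < late_hi:
            merged.append(c)
    return MainSleepPeriod(
        participant_id=seed.participant_id,
        night_key=night_key,
        onset=merged[0].start,
        wake=merged[-1].end,
        cycles=merged,
        is_late_onset=True,
    )


def segment_nights(
    grid: MinuteGrid,
    late_merge_gap_min: int = DEFAULT_LATE_MERGE_GAP_MIN,
) -> list[MainSleepPeriod]:
    """All main sleep periods in a grid, one candidate night per calendar date.

    Nights are examined from the date before the grid starts through the
    grid's last date; nights with no qualifying cycles are simply absent.
    """
    cycles = extract_sleep_cycles(grid)
    if not cycles:
        return []
    first = (grid.start.normalize() - pd.Timedelta(days=1)).date()
    last = grid.end.normalize().date()
    periods = []
    claimed: set[int] = set()
    day = first
    while day <= last:
        period = identify_main_sleep(cycles, day, late_merge_gap_min)
        if period is not None:
            ids = {id(c) for c in period.cycles}
            if not ids & claimed:
                periods.append(period)
                claimed |= ids
        day = day + datetime.timedelta(days=1)
    return periods
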
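"""Wear-time validation from heart-rate presence.

A minute counts as wear time iff a physiologically plausible heart-rate
value (20-250 bpm) was observed in it.  A calendar day (midnight to
midnight) is valid under a cutoff when it has at least that many wear
minutes; a participant is valid when at least 5 days are valid, and at most
the earliest 9 valid days are retained for downstream metrics.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import HR_MAX, HR_MIN, MinuteGrid

CUTOFF_600 = 600
CUTOFF_1200 = 1200
MIN_VALID_DAYS = 5
MAX_RETAINED_DAYS = 9


@dataclass
class WearDay:
    participant_id: str
    date: datetime.date
    wear_minutes: int
    valid_600: bool
    valid_1200: bool


@dataclass
class ParticipantValidity:
    participant_id: str
    cutoff: int
    n_valid_days: int
    is_valid: bool
    retained_dates: list[datetime.date]


def wear_mask(grid: MinuteGrid) -> np.ndarray:
    """Boolean per-minute wear indicator (plausible heart rate present)."""
    hr = grid.heart_rate
    return ~np.isnan(hr) & (hr >= HR_MIN) & (hr <= HR_MAX)


def compute_wear_days(grid: MinuteGrid) -> list[WearDay]:
    """One WearDay per calendar day intersecting the grid."""
    if grid.n_minutes == 0:
        raise ValueError("empty grid")
    mask = wear_mask(grid)
    dates = grid.minutes().normalize()
    counts = pd.Series(mask).groupby(dates.values).sum()
    out = []
    for day, wear in counts.items():
        wear = int(wear)
        out.append(
            WearDay(
                participant_id=grid.participant_id,
                date=pd.Timestamp(day).date(),
                wear_minutes=wear,
                valid_600=wear >= CUTOFF_600,
                valid_1200=wear >= CUTOFF_1200,
            )
        )
    return out


def classify_participant(
    wear_days: list[WearDay], cutoff: int
) -> ParticipantValidity:
    """Apply the 5-9 valid day rule; retain the earliest 9 valid days."""
    if cutoff not in (CUTOFF_600, CUTOFF_1200):
        raise ValueError(f"cutoff must be {CUTOFF_600} or {CUTOFF_1200}")
    pids = {d.participant_id for d in wear_days}
    if len(pids) != 1:
        raise ValueError("wear_days must belong to exactly one participant")
    valid = sorted(
        (d.date for d in wear_days if d.wear_minutes >= cutoff)
    )
    return ParticipantValidity(
        participant_id=next(iter(pids)),
        cutoff=cutoff,
        n_valid_days=len(valid),
        is_valid=len(valid) >= MIN_VALID_DAYS,
        retained_dates=valid[:MAX_RETAINED_DAYS],
    )
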
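"""Daily and participant-level physical-activity metrics on retained valid days.

Total steps per day is unconditioned on wear; steps/hour is conditioned on
wear minutes.  Awake sedentary minutes are sedentary-labeled minutes outside
all detected sleep (stage-labeled minutes and the merged main-period
intervals, which also cover unlabeled gap minutes inside a night); a period
crossing midnight contributes to both days' exclusions.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import INTENSITY_CODE, MinuteGrid, STAGE_ABSENT
from .sleep import MainSleepPeriod
from .wear import wear_mask

MIN_DAYS = 5
MAX_DAYS = 9


@dataclass
class ActivityDay:
    participant_id: str
    date: datetime.date
    wear_minutes: int
    total_steps: int
    steps_per_hour_wear: float
    minutes_very: int
    minutes_moderate: int
    minutes_light: int
    minutes_awake_sedentary: int


@dataclass
class ParticipantActivitySummary:
    participant_id: str
    n_days: int
    mean_wear_minutes: float
    mean_total_steps: float
    sd_total_steps: float
    mean_steps_per_hour: float
    sd_steps_per_hour: float
    mean_minutes_very: float
    sd_minutes_very: float
    mean_minutes_moderate: float
    sd_minutes_moderate: float
    mean_minutes_light: float
    sd_minutes_light: float
    mean_minutes_awake_sedentary: float
    sd_minutes_awake_sedentary: float


def sleep_exclusion_mask(grid: MinuteGrid, periods: list[MainSleepPeriod]) -> np.ndarray:
    """Minutes belonging to any detected sleep: stage-labeled (cycles and naps)
    or inside a main period (covers merged gap minutes)."""
    mask = grid.sleep_stage != STAGE_ABSENT
    for p in periods:
        lo = max(grid.index_of(p.onset), 0)
        hi = min(grid.index_of(p.wake), grid.n_minutes)
        if hi > lo:
            mask[lo:hi] = True
    return mask


def compute_activity_day(
    grid: MinuteGrid,
    date: datetime.date,
    sleep_periods: list[MainSleepPeriod],
) -> ActivityDay:
    """Activity metrics for one retained valid calendar day."""
    day_start = pd.Timestamp(date)
    lo = grid.index_of(day_start)
    hi = grid.index_of(day_start + pd.Timedelta(days=1))
    lo_c, hi_c = max(lo, 0), min(hi, grid.n_minutes)
    if hi_c <= lo_c:
        raise ValueError(f"{date} does not intersect the grid")

    steps = grid.steps[lo_c:hi_c]
    wear = wear_mask(grid)[lo_c:hi_c]
    wear_minutes = int(wear.sum())
    if wear_minutes == 0:
        raise ValueError(f"zero wear minutes on retained day {date}")
    total_steps = int(np.nansum(steps))
    steps_on_wear = float(np.nansum(steps[wear]))
    steps_per_hour = steps_on_wear / (wear_minutes / 60)

    intensity = grid.intensity[lo_c:hi_c]
    asleep = sleep_exclusion_mask(grid, sleep_periods)[lo_c:hi_c]
    sed = intensity == INTENSITY_CODE["sedentary"]
    return ActivityDay(
        participant_id=grid.participant_id,
        date=date,
        wear_minutes=wear_minutes,
        total_steps=total_steps,
        steps_per_hour_wear=steps_per_hour,
        minutes_very=int((intensity == INTENSITY_CODE["very_active"]).sum()),
        minutes_moderate=int((intensity == INTENSITY_CODE["moderately_active"]).sum()),
        minutes_light=int((intensity == INTENSITY_CODE["lightly_active"]).sum()),
        minutes_awake_sedentary=int((sed & ~asleep).sum()),
    )


def summarize_participant_activity(
    days: list[ActivityDay],
) -> ParticipantActivitySummary:
    """Unweighted mean and sample SD across 5-9 retained days."""
    if not MIN_DAYS <= len(days) <= MAX_DAYS:
        raise ValueError(f"expected {MIN_DAYS}-{MAX_DAYS} retained days, got {len(days)}")
    pid = days[0].participant_id

    def ms(values):
        arr = np.asarray(values, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1))

    steps_m, steps_s = ms([d.total_steps for d in days])
    sph_m, sph_s = ms([d.steps_per_hour_wear for d in days])
    very_m, very_s = ms([d.minutes_very for d in days])
    mod_m, mod_s = ms([d.minutes_moderate for d in days])
    light_m, light_s = ms([d.minutes_light for d in days])
    sed_m, sed_s = ms([d.minutes_awake_sedentary for d in days])
    return ParticipantActivitySummary(
        participant_id=pid,
        n_days=len(days),
        mean_wear_minutes=float(np.mean([d.wear_minutes for d in days])),
        mean_total_steps=steps_m, sd_total_steps=steps_s,
        mean_steps_per_hour=sph_m, sd_steps_per_hour=sph_s,
        mean_minutes_very=very_m, sd_minutes_very=very_s,
        mean_minutes_moderate=mod_m, sd_minutes_moderate=mod_s,
        mean_minutes_light=light_m, sd_minutes_light=light_s,
        mean_minutes_awake_sedentary=sed_m, sd_minutes_awake_sedentary=sed_s,
    )
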
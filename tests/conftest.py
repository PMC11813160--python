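import datetime

import numpy as np
import pandas as pd
import pytest

import wearminute as wm
from wearminute.grid import INTENSITY_ABSENT, INTENSITY_CODE, STAGE_ABSENT
from wearminute.simulate import ActivityModel, HeartRateModel, SleepModel, WearModel

MONDAY = pd.Timestamp("2021-03-01")  # grids anchored on a Monday


def make_grid(
    pid: str = "P1",
    start: pd.Timestamp = MONDAY,
    n_minutes: int = 1440,
    hr=None,
    steps=None,
    intensity=None,
    stage_intervals=(),
):
    """Hand-built grid: stage_intervals are (start_offset_min, end_offset_min, stage)."""
    grid = wm.MinuteGrid.empty(pid, start, n_minutes)
    if hr is not None:
        grid.heart_rate[:] = hr
    if steps is not None:
        grid.steps[:] = steps
    if intensity is not None:
        grid.intensity[:] = INTENSITY_CODE[intensity]
    for lo, hi, st in stage_intervals:
        grid.sleep_stage[lo:hi] = st
    return grid


def noiseless_config(n_participants=3, days=8, seed=3, **sleep_overrides):
    sleep = dict(
        onset_sd_between_min=0.0,
        onset_sd_within_min=0.0,
        weekend_onset_shift_min=0.0,
        span_sd_between_hours=0.0,
        span_sd_within_hours=0.0,
        weekend_span_shift_min=0.0,
        restless_per_night=0.0,
        awake_bouts_per_night=0.0,
        p_nap=0.0,
        p_late_onset=0.0,
    )
    sleep.update(sleep_overrides)
    return wm.CohortConfig(
        n_participants=n_participants,
        days_per_participant=days,
        seed=seed,
        wear=WearModel(gaps_per_day=0.0, p_missing_day=0.0),
        activity=ActivityModel(very_sd=0.0, moderate_sd=0.0, light_sd=0.0),
        sleep=SleepModel(**sleep),
        heart_rate=HeartRateModel(wake_sd=0.0, sleep_sd=0.0),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded stochastic cohort shared by cheaper integration tests."""
    cfg = wm.CohortConfig(n_participants=12, seed=42)
    grids, truth = wm.generate_cohort(cfg)
    return cfg, grids, truth


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    cfg, grids, truth = small_cohort
    return wm.run_pipeline(grids, metadata=truth.participants)


def brute_force_cycles(stage: np.ndarray):
    """Independent run-length scan: list of (start_idx, end_idx) labeled runs."""
    runs, start = [], None
    for i, s in enumerate(stage):
        if s != STAGE_ABSENT and start is None:
            start = i
        elif s == STAGE_ABSENT and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(stage)))
    return runs


def brute_force_main_period(stage, grid_start, night_key):
    """Literal reading of the merge rule: among labeled runs, take those whose
    first minute falls in [18:00 night_key, 06:00 night_key+1); span from the
    first such run's start to the last such run's end."""
    runs = brute_force_cycles(stage)
    lo = pd.Timestamp(night_key) + pd.Timedelta(hours=18)
    hi = pd.Timestamp(night_key) + pd.Timedelta(hours=30)
    qual = [
        (s, e)
        for s, e in runs
        if lo <= grid_start + pd.Timedelta(minutes=s) < hi
    ]
    if not qual:
        return None
    return qual[0][0], qual[-1][1]
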
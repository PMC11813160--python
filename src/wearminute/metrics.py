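"""Per-night and per-participant sleep metrics.

Definitions (all within the main sleep period [onset, wake)):

* span (sleep duration) — wake minus onset, in hours;
* WASO — minutes awake after onset: stage-3 minutes plus unlabeled
  inter-cycle gap minutes (restless minutes count as asleep by default);
* efficiency — asleep minutes divided by the span;
* midpoint — clock time halfway between onset and wake;
* social jet lag — absolute difference between mean weekend-night
  (Friday/Saturday night_key) and mean weekday-night midpoints.

Clock times are averaged on a noon-anchored linear axis (minutes since the
preceding 12:00), which is wrap-free for every onset/wake the segmentation
can produce (18:00 through the following afternoon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import MINUTE, STAGE_ABSENT, STAGE_AWAKE
from .simulate import axis_to_clock  # noqa: F401  (re-exported convenience)
from .sleep import MainSleepPeriod

import pandas as pd

MIN_NIGHTS = 5
MAX_NIGHTS = 9
MIDNIGHT_AXIS = 720  # minutes from noon


def to_noon_axis(ts: pd.Timestamp, night_key) -> float:
    """Minutes from 12:00 of the night's anchor date."""
    anchor = pd.Timestamp(night_key) + pd.Timedelta(hours=12)
    return (pd.Timestamp(ts) - anchor) / MINUTE


def from_noon_axis(axis: float, night_key) -> pd.Timestamp:
    anchor = pd.Timestamp(night_key) + pd.Timedelta(hours=12)
    return anchor + pd.Timedelta(minutes=axis)


@dataclass
class NightMetrics:
    participant_id: str
    night_key: object  # datetime.date
    onset_axis_min: float
    wake_axis_min: float
    span_hours: float
    waso_hours: float
    efficiency: float
    midpoint_axis_min: float
    is_weekend_night: bool
    is_late_onset: bool


def compute_night_metrics(
    period: MainSleepPeriod, restless_as_awake: bool = False
) -> NightMetrics:
    """Span, WASO, efficiency and midpoint for one main sleep period."""
    if not period.onset < period.wake:
        raise ValueError("period onset must precede wake")
    stages = period.span_stages()
    span_min = len(stages)
    awake = (stages == STAGE_AWAKE) | (stages == STAGE_ABSENT)
    if restless_as_awake:
        awake |= stages == 2
    awake_min = int(awake.sum())
    onset_axis = to_noon_axis(period.onset, period.night_key)
    wake_axis = to_noon_axis(period.wake, period.night_key)
    weekday = pd.Timestamp(period.night_key).weekday()
    return NightMetrics(
        participant_id=period.participant_id,
        night_key=period.night_key,
        onset_axis_min=onset_axis,
        wake_axis_min=wake_axis,
        span_hours=span_min / 60,
        waso_hours=awake_min / 60,
        efficiency=(span_min - awake_min) / span_min,
        midpoint_axis_min=(onset_axis + wake_axis) / 2,
        is_weekend_night=weekday in (4, 5),  # Friday or Saturday night
        is_late_onset=period.is_late_onset,
    )


def social_jet_lag(nights: list[NightMetrics]) -> float | None:
    """|mean weekend midpoint - mean weekday midpoint| in hours.

    Returns None when the participant has no weekend (or no weekday) night
    among the retained nights; the metric is then absent, not zero.
    """
    weekend = [n.midpoint_axis_min for n in nights if n.is_weekend_night]
    weekday = [n.midpoint_axis_min for n in nights if not n.is_weekend_night]
    if not weekend or not weekday:
        return None
    return abs(float(np.mean(weekend)) - float(np.mean(weekday))) / 60


@dataclass
class ParticipantSleepSummary:
    participant_id: str
    n_nights: int
    mean_span_hours: float
    sd_span_hours: float
    mean_waso_hours: float
    mean_efficiency: float
    mean_onset_axis_min: float
    sd_onset_min: float
    mean_wake_axis_min: float
    sd_wake_min: float
    mean_midpoint_axis_min: float
    social_jet_lag_hours: float | None
    onset_group: str  # before_midnight | after_midnight

    @property
    def mean_onset_clock(self) -> str:
        return axis_to_clock(self.mean_onset_axis_min)

    @property
    def mean_wake_clock(self) -> str:
        return axis_to_clock(self.mean_wake_axis_min)


def summarize_participant_sleep(
    nights: list[NightMetrics],
) -> ParticipantSleepSummary | None:
    """Participant-level sleep summary over 5-9 retained nights.

    Returns None for participants with fewer than 5 nights (they are
    excluded from sleep summaries, to be recorded in a skip log by the
    caller).  More than 9 nights violates the retention contract upstream.
    """
    if len(nights) < MIN_NIGHTS:
        return None
    if len(nights) > MAX_NIGHTS:
        raise ValueError("more than 9 nights passed; retain the earliest 9 upstream")
    pid = nights[0].participant_id
    onset = np.array([n.onset_axis_min for n in nights], dtype=float)
    wake = np.array([n.wake_axis_min for n in nights], dtype=float)
    span = np.array([n.span_hours for n in nights], dtype=float)
    mean_onset = float(onset.mean())
    return ParticipantSleepSummary(
        participant_id=pid,
        n_nights=len(nights),
        mean_span_hours=float(span.mean()),
        sd_span_hours=float(span.std(ddof=1)),
        mean_waso_hours=float(np.mean([n.waso_hours for n in nights])),
        mean_efficiency=float(np.mean([n.efficiency for n in nights])),
        mean_onset_axis_min=mean_onset,
        sd_onset_min=float(onset.std(ddof=1)),
        mean_wake_axis_min=float(wake.mean()),
        sd_wake_min=float(wake.std(ddof=1)),
        mean_midpoint_axis_min=float(np.mean([n.midpoint_axis_min for n in nights])),
        social_jet_lag_hours=social_jet_lag(nights),
        onset_group=(
            "after_midnight" if mean_onset >= MIDNIGHT_AXIS else "before_midnight"
        ),
    )
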
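"""Night metrics (span, WASO, efficiency, midpoint) and participant summaries."""

import numpy as np
import pandas as pd
import pytest

import wearminute as wm
from wearminute.grid import MINUTE
from wearminute.metrics import NightMetrics, from_noon_axis, to_noon_axis
from wearminute.sleep import MainSleepPeriod, SleepCycle

NIGHT = pd.Timestamp("2021-03-01").date()  # a Monday night


def _period(intervals, night_key=NIGHT, pid="P1", late=False):
    """intervals: list of (onset str, end str, stage array or int)."""
    cycles = []
    for onset, end, stages in intervals:
        onset, end = pd.Timestamp(onset), pd.Timestamp(end)
        n = int((end - onset) / MINUTE)
        if isinstance(stages, int):
            stages = np.full(n, stages, dtype=np.int8)
        cycles.append(SleepCycle(pid, onset, end, np.asarray(stages, dtype=np.int8)))
    return MainSleepPeriod(
        participant_id=pid, night_key=night_key,
        onset=cycles[0].start, wake=cycles[-1].end,
        cycles=cycles, is_late_onset=late,
    )


def _night(midpoint_axis, weekend, pid="P1", key=NIGHT):
    return NightMetrics(
        participant_id=pid, night_key=key,
        onset_axis_min=midpoint_axis - 240, wake_axis_min=midpoint_axis + 240,
        span_hours=8.0, waso_hours=0.0, efficiency=1.0,
        midpoint_axis_min=midpoint_axis,
        is_weekend_night=weekend, is_late_onset=False,
    )


class TestComputeNightMetrics:
    def test_pure_sleep_period(self):
        period = _period([("2021-03-01 23:00", "2021-03-02 07:00", 1)])
        m = wm.compute_night_metrics(period)
        assert m.span_hours == 8.0
        assert m.waso_hours == 0.0
        assert m.efficiency == 1.0
        assert m.midpoint_axis_min == (660 + 1140) / 2  # 03:00

    def test_stage3_minutes_count_as_waso(self):
        stages = np.full(480, 1, dtype=np.int8)
        stages[100:124] = 3
        period = _period([("2021-03-01 23:00", "2021-03-02 07:00", stages)])
        m = wm.compute_night_metrics(period)
        assert m.efficiency == pytest.approx(0.95)
        assert m.waso_hours == pytest.approx(0.4)

    def test_restless_counts_as_asleep_by_default(self):
        stages = np.full(480, 1, dtype=np.int8)
        stages[10:40] = 2
        period = _period([("2021-03-01 23:00", "2021-03-02 07:00", stages)])
        assert wm.compute_night_metrics(period).efficiency == 1.0
        flipped = wm.compute_night_metrics(period, restless_as_awake=True)
        assert flipped.waso_hours == pytest.approx(0.5)
        assert flipped.efficiency == pytest.approx(1 - 30 / 480)

    def test_merged_gap_and_scattered_stages_match_bruteforce(self):
        rng = np.random.default_rng(0)
        s1 = rng.integers(1, 4, size=180).astype(np.int8)
        s2 = rng.integers(1, 4, size=270).astype(np.int8)
        period = _period([
            ("2021-03-01 23:30", "2021-03-02 02:30", s1),
            ("2021-03-02 03:00", "2021-03-02 07:30", s2),  # 30-min unlabeled gap
        ])
        m = wm.compute_night_metrics(period)
        # brute force: walk every minute of the span
        span = np.zeros(480, dtype=np.int8)
        span[0:180] = s1
        span[210:480] = s2
        awake = int(((span == 3) | (span == 0)).sum())
        assert m.span_hours == 8.0
        assert m.waso_hours == pytest.approx(awake / 60)
        assert m.efficiency == pytest.approx((480 - awake) / 480)
        assert m.onset_axis_min < m.midpoint_axis_min < m.wake_axis_min

    def test_conservation_asleep_plus_awake_equals_span(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(60, 600))
            stages = rng.integers(1, 4, size=n).astype(np.int8)
            period = _period([("2021-03-01 22:00",
                               str(pd.Timestamp("2021-03-01 22:00") + n * MINUTE),
                               stages)])
            m = wm.compute_night_metrics(period)
            asleep_h = m.efficiency * m.span_hours
            assert asleep_h + m.waso_hours == pytest.approx(m.span_hours)
            assert 0 <= m.efficiency <= 1


class TestSocialJetLag:
    def test_ninety_minute_shift(self):
        nights = [_night(900, False)] * 5 + [_night(990, True)] * 2
        assert wm.social_jet_lag(nights) == pytest.approx(1.5)

    def test_identical_midpoints_zero(self):
        nights = [_night(900, False)] * 5 + [_night(900, True)] * 2
        assert wm.social_jet_lag(nights) == 0.0

    def test_absent_without_weekend_nights(self):
        assert wm.social_jet_lag([_night(900, False)] * 5) is None
        assert wm.social_jet_lag([_night(900, True)] * 5) is None


class TestParticipantSummary:
    def test_before_midnight_group(self):
        onset = 660 + 11  # 23:11
        nights = [
            NightMetrics("P1", NIGHT, onset, onset + 480, 8.0, 0.0, 1.0,
                         onset + 240, weekend, False)
            for weekend in (False, False, False, True, True)
        ]
        summary = wm.summarize_participant_sleep(nights)
        assert summary.onset_group == "before_midnight"
        assert summary.mean_onset_clock == "23:11"

    def test_midnight_boundary_is_after_midnight(self):
        onsets = [710, 730] * 3  # alternating 23:50 / 00:10 -> mean exactly 00:00
        nights = [
            NightMetrics("P1", NIGHT, o, o + 480, 8.0, 0.0, 1.0, o + 240, False, False)
            for o in onsets
        ]
        summary = wm.summarize_participant_sleep(nights)
        assert summary.mean_onset_axis_min == 720
        assert summary.onset_group == "after_midnight"

    def test_fewer_than_five_nights_returns_none(self):
        nights = [_night(900, False)] * 4
        assert wm.summarize_participant_sleep(nights) is None

    def test_summary_matches_bruteforce_recompute(self):
        rng = np.random.default_rng(2)
        nights = []
        for i in range(7):
            onset = float(rng.uniform(600, 900))
            span = float(rng.uniform(6, 9))
            waso = float(rng.uniform(0, 1))
            nights.append(
                NightMetrics("P1", NIGHT, onset, onset + span * 60, span, waso,
                             1 - waso / span, onset + span * 30, i >= 5, False)
            )
        s = wm.summarize_participant_sleep(nights)
        assert s.mean_span_hours == pytest.approx(sum(n.span_hours for n in nights) / 7)
        assert s.mean_waso_hours == pytest.approx(sum(n.waso_hours for n in nights) / 7)
        onsets = [n.onset_axis_min for n in nights]
        assert s.sd_onset_min == pytest.approx(np.std(onsets, ddof=1))
        wk = np.mean([n.midpoint_axis_min for n in nights[:5]])
        we = np.mean([n.midpoint_axis_min for n in nights[5:]])
        assert s.social_jet_lag_hours == pytest.approx(abs(we - wk) / 60)


class TestNoonAxis:
    def test_round_trip_lossless_for_evening_through_noon(self):
        # every minute from 18:00 of the anchor to noon the next day
        for axis in range(360, 1440):
            ts = from_noon_axis(axis, NIGHT)
            assert to_noon_axis(ts, NIGHT) == axis
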
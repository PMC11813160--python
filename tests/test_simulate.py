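"""Synthetic cohort generator: determinism, structure, truth consistency."""

import numpy as np
import pandas as pd
import pytest

import wearminute as wm
from wearminute.grid import STAGE_ABSENT
from wearminute.simulate import SleepModel, clock_to_axis, axis_to_clock

from conftest import noiseless_config


def test_same_seed_gives_identical_cohorts(small_cohort):
    cfg, grids, truth = small_cohort
    grids2, truth2 = wm.generate_cohort(
        wm.CohortConfig(n_participants=cfg.n_participants, seed=cfg.seed)
    )
    for a, b in zip(grids, grids2):
        assert np.array_equal(a.heart_rate, b.heart_rate, equal_nan=True)
        assert np.array_equal(a.steps, b.steps, equal_nan=True)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(a.sleep_stage, b.sleep_stage)
    assert truth.nights.equals(truth2.nights)
    assert truth.days.equals(truth2.days)


def test_participant_streams_stable_under_cohort_growth():
    small, _ = wm.generate_cohort(wm.CohortConfig(n_participants=3, seed=9))
    large, _ = wm.generate_cohort(wm.CohortConfig(n_participants=6, seed=9))
    for a, b in zip(small, large[:3]):
        assert np.array_equal(a.heart_rate, b.heart_rate, equal_nan=True)
        assert np.array_equal(a.sleep_stage, b.sleep_stage)


def test_noiseless_cohort_is_degenerate():
    grids, truth = wm.generate_cohort(noiseless_config())
    assert (truth.days["wear_min"] == 1440).all()
    # identical nights: one onset clock time, one span, zero interruptions
    assert truth.nights["span_min"].nunique() == 1
    assert (truth.nights["waso_min"] == 0).all()
    onsets = truth.nights["onset"].dt.strftime("%H:%M").unique()
    assert list(onsets) == ["00:16"]
    for g in grids:
        assert not np.isnan(g.heart_rate).any()


def test_all_late_when_p_late_is_one():
    grids, truth = wm.generate_cohort(
        wm.CohortConfig(n_participants=4, seed=2, sleep=SleepModel(p_late_onset=1.0))
    )
    clock = truth.nights["onset"].dt.hour * 60 + truth.nights["onset"].dt.minute
    assert ((clock >= 6 * 60) & (clock < 18 * 60)).all()


def test_wear_plus_nonwear_conserved_per_day(small_cohort):
    _, grids, _ = small_cohort
    for g in grids:
        worn = ~np.isnan(g.heart_rate)
        per_day = worn.reshape(-1, 1440).sum(axis=1)
        assert ((per_day >= 0) & (per_day <= 1440)).all()
        nonwear = np.isnan(g.heart_rate).reshape(-1, 1440).sum(axis=1)
        assert (per_day + nonwear == 1440).all()


def test_stage_labels_only_inside_truth_intervals(small_cohort):
    _, grids, truth = small_cohort
    for g in grids:
        allowed = np.zeros(g.n_minutes, dtype=bool)
        for df, lo_col, hi_col in ((truth.nights, "onset", "wake"),
                                   (truth.naps, "start", "end")):
            sub = df[df["participant_id"] == g.participant_id]
            for lo, hi in zip(sub[lo_col], sub[hi_col]):
                allowed[g.index_of(lo):g.index_of(hi)] = True
        labeled = g.sleep_stage != STAGE_ABSENT
        assert not (labeled & ~allowed).any()
        # and nonwear minutes never carry a stage label
        assert not (labeled & np.isnan(g.heart_rate)).any()


def test_truth_onset_precedes_wake(small_cohort):
    _, _, truth = small_cohort
    assert (truth.nights["onset"] < truth.nights["wake"]).all()


def test_nightly_span_mean_near_configured_value():
    cfg = wm.CohortConfig(n_participants=120, seed=17)
    _, truth = wm.generate_cohort(cfg)
    weekday = truth.nights[~truth.nights["is_weekend"]]
    spans = weekday["span_min"] / 60
    se = spans.std(ddof=1) / np.sqrt(len(spans))
    assert abs(spans.mean() - cfg.sleep.span_mean_hours) <= 3 * se


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(n_participants=0), "n_participants"),
        (dict(days_per_participant=1), "2 days"),
        (dict(sleep=SleepModel(span_mean_hours=25)), "24 h"),
        (dict(sleep=SleepModel(p_nap=1.5)), "p_nap"),
        (dict(sleep=SleepModel(onset_sd_within_min=-1)), "non-negative"),
        (dict(sleep=SleepModel(onset_mean="14:00")), "night window"),
    ],
)
def test_infeasible_configs_rejected_before_generation(kwargs, match):
    with pytest.raises(ValueError, match=match):
        wm.generate_cohort(wm.CohortConfig(seed=1, **kwargs))


class TestClockAxis:
    @pytest.mark.parametrize("clock, axis", [("12:00", 0), ("18:00", 360),
                                             ("00:16", 736), ("06:00", 1080),
                                             ("11:59", 1439)])
    def test_known_conversions(self, clock, axis):
        assert clock_to_axis(clock) == axis
        assert axis_to_clock(axis) == clock

    def test_round_trip_all_minutes(self):
        for axis in range(1440):
            assert clock_to_axis(axis_to_clock(axis)) == axis


class TestTruthSummary:
    def _truth(self, nights, days=None):
        parts = pd.DataFrame(
            {"participant_id": sorted({n["participant_id"] for n in nights}),
             "sex": "female", "is_late_onset": False}
        )
        return wm.GroundTruth(
            participants=parts,
            nights=pd.DataFrame(nights),
            naps=pd.DataFrame(columns=["participant_id", "night_key", "start", "end"]),
            days=pd.DataFrame(days or [],
                              columns=["participant_id", "date", "wear_min", "steps",
                                       "very_min", "moderate_min", "light_min",
                                       "awake_sedentary_min"]),
        )

    @staticmethod
    def _night(pid, key, onset, wake, waso=0, weekend=False):
        onset, wake = pd.Timestamp(onset), pd.Timestamp(wake)
        span = int((wake - onset) / pd.Timedelta(minutes=1))
        return {"participant_id": pid, "night_key": pd.Timestamp(key).date(),
                "onset": onset, "wake": wake, "span_min": span, "waso_min": waso,
                "stage3_min": waso, "restless_min": 0, "is_weekend": weekend,
                "is_late_onset": False}

    def test_single_night_span(self):
        truth = self._truth(
            [self._night("A", "2021-03-01", "2021-03-01 23:00", "2021-03-02 07:00")]
        )
        row = wm.truth_summary(truth).iloc[0]
        assert row["true_span_h"] == 8.0
        assert row["true_midpoint_axis"] == (660 + 1140) / 2

    def test_equal_midpoints_give_zero_jet_lag(self):
        nights = [
            self._night("A", "2021-03-01", "2021-03-01 23:00", "2021-03-02 07:00"),
            self._night("A", "2021-03-05", "2021-03-05 23:00", "2021-03-06 07:00",
                        weekend=True),
        ]
        row = wm.truth_summary(self._truth(nights)).iloc[0]
        assert row["true_social_jet_lag_h"] == 0.0

    def test_three_night_truth_matches_hand_computation(self):
        # hand computation: spans 8h, 7h, 9.5h -> mean 8.1666..; WASO 10/20/0 min;
        # weekday midpoints 03:00 (900) and 02:00 (840) -> mean 870;
        # weekend midpoint 04:45 (1005); jet lag (1005-870)/60 = 2.25 h
        nights = [
            self._night("A", "2021-03-01", "2021-03-01 23:00", "2021-03-02 07:00", 10),
            self._night("A", "2021-03-02", "2021-03-02 22:30", "2021-03-03 05:30", 20),
            self._night("A", "2021-03-05", "2021-03-06 00:00", "2021-03-06 09:30", 0,
                        weekend=True),
        ]
        row = wm.truth_summary(self._truth(nights)).iloc[0]
        assert row["true_span_h"] == pytest.approx((8 + 7 + 9.5) / 3)
        assert row["true_waso_h"] == pytest.approx((10 + 20 + 0) / 180)
        assert row["true_social_jet_lag_h"] == pytest.approx(2.25)
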
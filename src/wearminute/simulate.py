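"""Synthetic minute-level cohort generator with known ground truth.

Generates per-participant minute grids (heart rate, steps, intensity and
sleep-stage labels) that emulate the behavioral structure of an adolescent
free-living wearable cohort: ~8 days of near-continuous wear with short
nonwear gaps, a circadian activity profile, one main nightly sleep period
with restless/awake interruptions, occasional morning/afternoon naps,
weekend onset shifts, and a small fraction of "late onset" participants
whose main sleep begins after 06:00.

Clock times are handled on a noon-anchored axis: minutes elapsed since the
preceding 12:00 of a night's anchor date, so a night window of
18:00..06:00 maps to [360, 1080) and never wraps around midnight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .grid import (
    INTENSITY_ABSENT,
    INTENSITY_CODE,
    MinuteGrid,
    STAGE_ABSENT,
    STAGE_ASLEEP,
    STAGE_AWAKE,
    STAGE_RESTLESS,
)

DAY = 1440
NOON = 720
#: night window on the noon axis: [18:00, 06:00 next day)
WINDOW_LO, WINDOW_HI = 360, 1080
LATE_LO, LATE_HI = 1080, 1800


def clock_to_axis(clock: str) -> int:
    """Clock time 'HH:MM' -> minutes since the preceding noon (in [0, 1440))."""
    h, m = clock.split(":")
    mod = int(h) * 60 + int(m)
    return mod - NOON if mod >= NOON else mod + NOON


def axis_to_clock(axis: float) -> str:
    """Noon-axis minutes -> 'HH:MM' clock time."""
    mod = int(round(axis) + NOON) % DAY
    return f"{mod // 60:02d}:{mod % 60:02d}"


@dataclass
class WearModel:
    """Daily nonwear structure; gaps never cut into sleep periods."""

    gaps_per_day: float = 3.0          # Poisson rate
    gap_len_log_mu: float = 3.7        # log-minutes; median ~40 min
    gap_len_log_sigma: float = 0.7
    p_missing_day: float = 0.02        # whole day absent (device off / not synced)


@dataclass
class ActivityModel:
    """Per-participant daily minute budgets per intensity and steps-per-minute rates.

    Defaults target cohort means near 20/23/235 active minutes per day and
    ~9000 steps/day; budgets are drawn once per participant (between-person
    variation), steps per minute are Poisson within intensity.
    """

    very_mean: float = 20.0
    very_sd: float = 18.0
    moderate_mean: float = 23.0
    moderate_sd: float = 16.0
    light_mean: float = 235.0
    light_sd: float = 65.0
    steps_light: float = 20.0
    steps_moderate: float = 80.0
    steps_very: float = 130.0
    active_window: tuple[str, str] = ("07:00", "22:00")  # clock bounds for active minutes


@dataclass
class SleepModel:
    """Nightly main-sleep structure.

    Onset and span have between-participant and within-participant (nightly)
    noise components.  Awake interruptions are bouts that appear either as
    stage-3 minutes or as unlabeled gaps (the device deciding the sleep
    period ended), which splits the night into multiple cycles.
    """

    onset_mean: str = "00:16"
    onset_sd_between_min: float = 80.0
    onset_sd_within_min: float = 30.0
    weekend_onset_shift_min: float = 45.0
    span_mean_hours: float = 7.9
    span_sd_between_hours: float = 0.7
    span_sd_within_hours: float = 0.6
    weekend_span_shift_min: float = 30.0
    restless_per_night: float = 6.0       # Poisson; minutes of stage 2
    awake_bouts_per_night: float = 5.0    # Poisson; bouts of stage 3 / gap
    awake_bout_geom_p: float = 1 / 6      # bout length ~ Geometric(p), capped
    p_gap_bout: float = 0.3               # bout rendered as unlabeled gap
    p_nap: float = 0.10
    nap_len_mean: float = 40.0
    nap_len_sd: float = 10.0
    p_late_onset: float = 0.05            # participant sleeps after 06:00
    late_onset_mean: str = "09:30"
    late_onset_sd_min: float = 45.0

    MAX_BOUT_LEN: int = 45  # keeps merge gaps under the 60-min chaining rule


@dataclass
class HeartRateModel:
    wake_mean: float = 75.0
    wake_sd: float = 8.0
    sleep_mean: float = 60.0
    sleep_sd: float = 6.0
    ar1: float = 0.9


@dataclass
class CohortConfig:
    n_participants: int = 50
    days_per_participant: int = 8
    seed: int = 0
    start_date: str = "2021-03-01"  # a Monday: 8 days span 5 weekday + 2 weekend nights
    p_female: float = 0.5
    wear: WearModel = field(default_factory=WearModel)
    activity: ActivityModel = field(default_factory=ActivityModel)
    sleep: SleepModel = field(default_factory=SleepModel)
    heart_rate: HeartRateModel = field(default_factory=HeartRateModel)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.days_per_participant < 2:
            raise ValueError("need at least 2 days to contain one night")
        for name, p in [
            ("p_female", self.p_female),
            ("p_missing_day", self.wear.p_missing_day),
            ("p_gap_bout", self.sleep.p_gap_bout),
            ("p_nap", self.sleep.p_nap),
            ("p_late_onset", self.sleep.p_late_onset),
            ("awake_bout_geom_p", self.sleep.awake_bout_geom_p),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        sds = [
            self.wear.gap_len_log_sigma,
            self.activity.very_sd, self.activity.moderate_sd, self.activity.light_sd,
            self.sleep.onset_sd_between_min, self.sleep.onset_sd_within_min,
            self.sleep.span_sd_between_hours, self.sleep.span_sd_within_hours,
            self.sleep.nap_len_sd, self.sleep.late_onset_sd_min,
            self.heart_rate.wake_sd, self.heart_rate.sleep_sd,
        ]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")
        if self.sleep.span_mean_hours * 60 >= DAY:
            raise ValueError("sleep span must be under 24 h")
        budget = (self.activity.very_mean + self.activity.moderate_mean
                  + self.activity.light_mean)
        if budget > DAY:
            raise ValueError("per-day intensity budgets exceed 1440 minutes")
        axis = clock_to_axis(self.sleep.onset_mean)
        if not WINDOW_LO < axis < WINDOW_HI:
            raise ValueError("onset_mean must lie inside the 18:00-06:00 night window")
        late = clock_to_axis(self.sleep.late_onset_mean)
        if not LATE_LO <= late < LATE_HI:
            raise ValueError("late_onset_mean must lie in 06:00-18:00")


@dataclass
class GroundTruth:
    """Latent truth the generator used; the oracle for recovery tests."""

    participants: pd.DataFrame  # participant_id, sex, is_late_onset
    nights: pd.DataFrame        # onset/wake timestamps, span/waso/stage minutes
    naps: pd.DataFrame          # nap intervals
    days: pd.DataFrame          # wear, steps, intensity minutes per calendar day


def _nonoverlapping_bout(rng, lo: int, hi: int, length: int, occupied: np.ndarray):
    """Pick a bout start in [lo, hi - length] avoiding occupied gap minutes."""
    if hi - length < lo:
        return None
    for _ in range(8):
        s = int(rng.integers(lo, hi - length + 1))
        if not occupied[max(s - 1, 0):s + length + 1].any():
            return s
    return None


def generate_participant(
    config: CohortConfig, index: int
) -> tuple[MinuteGrid, dict, list[dict], list[dict], list[dict]]:
    """Generate one participant's grid and truth rows (deterministic in (seed, index))."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, index)))
    pid = f"P{index:04d}"
    days = config.days_per_participant
    n = days * DAY
    start = pd.Timestamp(config.start_date).normalize()
    sl, act, wear, hrm = config.sleep, config.activity, config.wear, config.heart_rate

    sex = "female" if rng.random() < config.p_female else "male"
    is_late = rng.random() < sl.p_late_onset
    if is_late:
        onset_mu = clock_to_axis(sl.late_onset_mean) + rng.normal(0, sl.late_onset_sd_min)
    else:
        onset_mu = clock_to_axis(sl.onset_mean) + rng.normal(0, sl.onset_sd_between_min)
    span_mu = (sl.span_mean_hours + rng.normal(0, sl.span_sd_between_hours)) * 60
    budgets = {
        "very": max(0.0, rng.normal(act.very_mean, act.very_sd)),
        "moderate": max(0.0, rng.normal(act.moderate_mean, act.moderate_sd)),
        "light": max(0.0, rng.normal(act.light_mean, act.light_sd)),
    }

    missing = rng.random(days) < wear.p_missing_day

    stage = np.zeros(n, dtype=np.int8)
    in_span = np.zeros(n, dtype=bool)  # main sleep spans + naps

    night_rows: list[dict] = []
    nap_rows: list[dict] = []

    for d in range(days - 1):
        night_date = start + pd.Timedelta(days=d)
        weekend = night_date.weekday() in (4, 5)  # Friday / Saturday night
        onset_axis = onset_mu + rng.normal(0, sl.onset_sd_within_min)
        if weekend:
            onset_axis += sl.weekend_onset_shift_min
        span = span_mu + rng.normal(0, sl.span_sd_within_hours) * 60
        if weekend:
            span += sl.weekend_span_shift_min
        if is_late:
            onset_axis = float(np.clip(onset_axis, LATE_LO + 1, 1500))
            span = float(np.clip(span, 120, 1790 - onset_axis))
        else:
            onset_axis = float(np.clip(onset_axis, WINDOW_LO + 1, WINDOW_HI - 1))
            span = float(np.clip(span, 120, 1700 - onset_axis))
        onset_axis = int(onset_axis)  # round down to the minute
        span = int(round(span))
        noon_idx = d * DAY + NOON
        onset_idx = noon_idx + onset_axis
        wake_idx = onset_idx + span
        if wake_idx >= n:
            continue
        if missing[onset_idx // DAY: (wake_idx - 1) // DAY + 1].any():
            continue  # device absent: the night is simply not recorded

        stage[onset_idx:wake_idx] = STAGE_ASLEEP
        interior_lo, interior_hi = onset_idx + 1, wake_idx - 1
        # restless minutes (stage 2), scattered inside the span
        k = int(rng.poisson(sl.restless_per_night))
        if k and interior_hi > interior_lo:
            pos = rng.choice(
                np.arange(interior_lo, interior_hi),
                size=min(k, interior_hi - interior_lo), replace=False,
            )
            stage[pos] = STAGE_RESTLESS
        # awake bouts: stage-3 runs, or unlabeled gaps that split the cycle
        gap_mask = np.zeros(n, dtype=bool)
        n_bouts = int(rng.poisson(sl.awake_bouts_per_night))
        for _ in range(n_bouts):
            length = min(int(rng.geometric(sl.awake_bout_geom_p)), sl.MAX_BOUT_LEN)
            # late-onset sleep stays one cycle: the fallback rule keeps only the
            # longest cycle and its forward chain, so pre-gap fragments of a split
            # late night would be unrecoverable by design
            as_gap = rng.random() < sl.p_gap_bout and not is_late
            hi = interior_hi
            if as_gap:
                # a post-gap cycle must still begin inside the night window
                hi = min(hi, noon_idx + WINDOW_HI - 1)
            s = _nonoverlapping_bout(rng, interior_lo, hi, length, gap_mask)
            if s is None:
                continue
            if as_gap:
                stage[s:s + length] = STAGE_ABSENT
                gap_mask[s:s + length] = True
            else:
                stage[s:s + length] = STAGE_AWAKE
        in_span[onset_idx:wake_idx] = True

        seg = stage[onset_idx:wake_idx]
        night_rows.append(
            {
                "participant_id": pid,
                "night_key": night_date.date(),
                "onset": start + pd.Timedelta(minutes=onset_idx),
                "wake": start + pd.Timedelta(minutes=wake_idx),
                "span_min": span,
                "waso_min": int(((seg == STAGE_AWAKE) | (seg == STAGE_ABSENT)).sum()),
                "stage3_min": int((seg == STAGE_AWAKE).sum()),
                "restless_min": int((seg == STAGE_RESTLESS).sum()),
                "is_weekend": weekend,
                "is_late_onset": is_late,
            }
        )

        # nap after the main sleep, morning/afternoon only
        if rng.random() < sl.p_nap:
            nap_start_axis = max(onset_axis + span + int(rng.uniform(120, 360)),
                                 LATE_LO + 1)
            nap_len = max(10, int(round(rng.normal(sl.nap_len_mean, sl.nap_len_sd))))
            nap_end_axis = nap_start_axis + nap_len
            ns, ne = noon_idx + nap_start_axis, noon_idx + nap_end_axis
            if (nap_end_axis <= 1740 and ne <= n and ns > wake_idx
                    and not missing[ns // DAY: (ne - 1) // DAY + 1].any()):
                stage[ns:ne] = STAGE_ASLEEP
                in_span[ns:ne] = True
                nap_rows.append(
                    {
                        "participant_id": pid,
                        "night_key": night_date.date(),
                        "start": start + pd.Timedelta(minutes=ns),
                        "end": start + pd.Timedelta(minutes=ne),
                    }
                )

    # --- nonwear gaps (awake minutes only) and missing days ------------------
    nonwear = np.zeros(n, dtype=bool)
    for d in range(days):
        if missing[d]:
            continue
        for _ in range(int(rng.poisson(wear.gaps_per_day))):
            length = int(np.clip(
                round(rng.lognormal(wear.gap_len_log_mu, wear.gap_len_log_sigma)),
                5, 600,
            ))
            s = int(rng.integers(d * DAY, (d + 1) * DAY - length + 1)) \
                if length <= DAY else d * DAY
            sel = slice(s, s + length)
            nonwear[sel] |= ~in_span[sel]
    for d in np.flatnonzero(missing):
        nonwear[d * DAY:(d + 1) * DAY] = True

    # --- intensity labels and steps ------------------------------------------
    intensity = np.full(n, INTENSITY_ABSENT, dtype=np.int8)
    steps = np.full(n, np.nan)
    minute_of_day = np.arange(n) % DAY
    lo_clk, hi_clk = (clock_to_axis(c) for c in act.active_window)
    # active window given as clock times; convert back to minute-of-day bounds
    lo_mod = (lo_clk + NOON) % DAY
    hi_mod = (hi_clk + NOON) % DAY
    in_window = (minute_of_day >= lo_mod) & (minute_of_day < hi_mod)

    day_rows: list[dict] = []
    sed_code = INTENSITY_CODE["sedentary"]
    icode = {k: INTENSITY_CODE[v] for k, v in
             [("very", "very_active"), ("moderate", "moderately_active"),
              ("light", "lightly_active")]}
    srate = {"very": act.steps_very, "moderate": act.steps_moderate,
             "light": act.steps_light}
    for d in range(days):
        date = (start + pd.Timedelta(days=d)).date()
        sel = slice(d * DAY, (d + 1) * DAY)
        if missing[d]:
            day_rows.append({"participant_id": pid, "date": date, "wear_min": 0,
                             "steps": 0, "very_min": 0, "moderate_min": 0,
                             "light_min": 0, "awake_sedentary_min": 0})
            continue
        idx = np.arange(d * DAY, (d + 1) * DAY)
        span_day = in_span[sel]
        wearable = ~nonwear[sel]
        awake_wear = wearable & ~span_day
        # sleep-period minutes read as sedentary with zero steps on the device
        intensity[idx[span_day & wearable]] = sed_code
        steps[idx[span_day & wearable]] = 0.0

        candidates = idx[awake_wear & in_window[sel]]
        fallback = idx[awake_wear & ~in_window[sel]]
        order = np.concatenate([rng.permutation(candidates), rng.permutation(fallback)])
        counts = {}
        pos = 0
        for name in ("very", "moderate", "light"):
            want = int(round(budgets[name]))
            take = min(want, len(order) - pos)
            chosen = order[pos:pos + take]
            intensity[chosen] = icode[name]
            steps[chosen] = rng.poisson(srate[name], size=take).astype(float)
            counts[name] = take
            pos += take
        rest = order[pos:]
        intensity[rest] = sed_code
        steps[rest] = 0.0
        day_rows.append(
            {
                "participant_id": pid, "date": date,
                "wear_min": int(wearable.sum()),
                "steps": int(np.nansum(steps[sel])),
                "very_min": counts["very"],
                "moderate_min": counts["moderate"],
                "light_min": counts["light"],
                "awake_sedentary_min": int(len(rest)),
            }
        )

    # --- heart rate: AR(1) around wake/sleep means ----------------------------
    mean = np.where(in_span, hrm.sleep_mean, hrm.wake_mean)
    sd = np.where(in_span, hrm.sleep_sd, hrm.wake_sd)
    innov = rng.normal(0.0, 1.0, size=n) * sd * np.sqrt(max(1 - hrm.ar1 ** 2, 0.0))
    dev = lfilter([1.0], [1.0, -hrm.ar1], innov)
    hr = np.clip(np.round(mean + dev), 30, 220)
    hr[nonwear] = np.nan
    steps[nonwear] = np.nan
    intensity[nonwear] = INTENSITY_ABSENT
    stage[nonwear] = STAGE_ABSENT  # no-op by construction; gaps avoid sleep

    grid = MinuteGrid(
        participant_id=pid, start=start,
        heart_rate=hr, steps=steps, intensity=intensity, sleep_stage=stage,
    )
    part_row = {"participant_id": pid, "sex": sex, "is_late_onset": is_late}
    return grid, part_row, night_rows, nap_rows, day_rows


NIGHT_COLUMNS = ["participant_id", "night_key", "onset", "wake", "span_min",
                 "waso_min", "stage3_min", "restless_min", "is_weekend",
                 "is_late_onset"]
NAP_COLUMNS = ["participant_id", "night_key", "start", "end"]
DAY_COLUMNS = ["participant_id", "date", "wear_min", "steps", "very_min",
               "moderate_min", "light_min", "awake_sedentary_min"]


def generate_cohort(config: CohortConfig) -> tuple[list[MinuteGrid], GroundTruth]:
    """Generate the full cohort; deterministic given config.seed."""
    config.validate()
    grids, parts, nights, naps, days = [], [], [], [], []
    for i in range(config.n_participants):
        grid, part, night_rows, nap_rows, day_rows = generate_participant(config, i)
        grids.append(grid)
        parts.append(part)
        nights.extend(night_rows)
        naps.extend(nap_rows)
        days.extend(day_rows)
    truth = GroundTruth(
        participants=pd.DataFrame(parts),
        nights=pd.DataFrame(nights, columns=NIGHT_COLUMNS),
        naps=pd.DataFrame(naps, columns=NAP_COLUMNS),
        days=pd.DataFrame(days, columns=DAY_COLUMNS),
    )
    return grids, truth


def truth_summary(truth: GroundTruth) -> pd.DataFrame:
    """Per-participant true metrics, computed directly from truth intervals.

    Uses the same metric definitions the pipeline estimates (span, WASO,
    efficiency, noon-axis onset/wake/midpoint, social jet lag, steps/day,
    intensity minutes) so recovery tests can compare like with like.
    """
    nights = truth.nights.copy()
    out_rows = []
    if not nights.empty:
        anchor = pd.to_datetime(nights["night_key"]) + pd.Timedelta(hours=12)
        nights["onset_axis"] = (nights["onset"] - anchor).dt.total_seconds() / 60
        nights["wake_axis"] = (nights["wake"] - anchor).dt.total_seconds() / 60
        nights["midpoint_axis"] = (nights["onset_axis"] + nights["wake_axis"]) / 2
        nights["span_h"] = nights["span_min"] / 60
        nights["waso_h"] = nights["waso_min"] / 60
        nights["efficiency"] = 1 - nights["waso_min"] / nights["span_min"]
    days = truth.days
    active_days = days[days["wear_min"] > 0]
    for pid, part in truth.participants.set_index("participant_id").iterrows():
        pn = nights[nights["participant_id"] == pid] if not nights.empty else nights
        pdays = active_days[active_days["participant_id"] == pid]
        row = {
            "participant_id": pid,
            "n_nights": len(pn),
            "true_span_h": pn["span_h"].mean() if len(pn) else np.nan,
            "true_waso_h": pn["waso_h"].mean() if len(pn) else np.nan,
            "true_efficiency": pn["efficiency"].mean() if len(pn) else np.nan,
            "true_onset_axis": pn["onset_axis"].mean() if len(pn) else np.nan,
            "true_wake_axis": pn["wake_axis"].mean() if len(pn) else np.nan,
            "true_midpoint_axis": pn["midpoint_axis"].mean() if len(pn) else np.nan,
            "true_steps_day": pdays["steps"].mean() if len(pdays) else np.nan,
            "true_wear_min": pdays["wear_min"].mean() if len(pdays) else np.nan,
            "true_very_min": pdays["very_min"].mean() if len(pdays) else np.nan,
            "true_moderate_min": pdays["moderate_min"].mean() if len(pdays) else np.nan,
            "true_light_min": pdays["light_min"].mean() if len(pdays) else np.nan,
            "true_awake_sedentary_min": (
                pdays["awake_sedentary_min"].mean() if len(pdays) else np.nan
            ),
        }
        if len(pn):
            wk = pn[~pn["is_weekend"]]["midpoint_axis"]
            we = pn[pn["is_weekend"]]["midpoint_axis"]
            row["true_social_jet_lag_h"] = (
                abs(we.mean() - wk.mean()) / 60 if len(wk) and len(we) else np.nan
            )
        else:
            row["true_social_jet_lag_h"] = np.nan
        out_rows.append(row)
    return pd.DataFrame(out_rows)
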
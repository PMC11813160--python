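"""End-to-end pipeline and cohort-level tables.

Runs wear validation, activity metrics, sleep segmentation and sleep
metrics over a set of minute grids under one declared wear cutoff, then
aggregates participant summaries into descriptive cohort tables
(participant-equally-weighted means and sample SDs), an attrition flow
count, and a 15-minute clock matrix of participants asleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import compute_activity_day, summarize_participant_activity
from .grid import MINUTE, MinuteGrid, STAGE_ASLEEP, STAGE_RESTLESS
from .metrics import (
    MAX_NIGHTS,
    MIN_NIGHTS,
    compute_night_metrics,
    summarize_participant_sleep,
)
from .sleep import DEFAULT_LATE_MERGE_GAP_MIN, segment_nights
from .wear import CUTOFF_600, CUTOFF_1200, classify_participant, compute_wear_days

CLOCK_BIN_MIN = 15
N_CLOCK_BINS = 1440 // CLOCK_BIN_MIN


@dataclass
class PipelineResult:
    cutoff: int
    wear_days: pd.DataFrame
    participants: pd.DataFrame
    activity_days: pd.DataFrame
    activity_participants: pd.DataFrame
    sleep_periods: pd.DataFrame
    sleep_nights: pd.DataFrame
    sleep_participants: pd.DataFrame
    skip_log: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: pd.DataFrame | None = None

    FRAME_NAMES = (
        "wear_days", "participants", "activity_days", "activity_participants",
        "sleep_periods", "sleep_nights", "sleep_participants", "skip_log",
    )
    TABLE_NAMES = ("table_activity", "table_sleep", "flow_counts", "clock_matrix")


def run_pipeline(
    grids: list[MinuteGrid],
    cutoff: int = CUTOFF_600,
    late_merge_gap_min: int = DEFAULT_LATE_MERGE_GAP_MIN,
    restless_as_awake: bool = False,
    metadata: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full minute-to-tables pipeline under one wear cutoff."""
    wear_rows, part_rows, act_day_rows, act_part_rows = [], [], [], []
    period_rows, night_rows, sleep_part_rows, skip_rows = [], [], [], []
    clock_asleep: dict[str, np.ndarray] = {}

    for grid in grids:
        pid = grid.participant_id
        wd = compute_wear_days(grid)
        for d in wd:
            wear_rows.append(
                {"participant_id": pid, "date": d.date, "wear_minutes": d.wear_minutes,
                 "valid_600": d.valid_600, "valid_1200": d.valid_1200}
            )
        v600 = classify_participant(wd, CUTOFF_600)
        v1200 = classify_participant(wd, CUTOFF_1200)
        part_rows.append(
            {"participant_id": pid,
             "n_valid_days_600": v600.n_valid_days, "is_valid_600": v600.is_valid,
             "n_valid_days_1200": v1200.n_valid_days, "is_valid_1200": v1200.is_valid}
        )
        validity = v600 if cutoff == CUTOFF_600 else v1200
        if not validity.is_valid:
            skip_rows.append({"participant_id": pid,
                              "reason": f"fewer than {MIN_NIGHTS} valid wear days"})
            continue
        retained = validity.retained_dates

        periods = segment_nights(grid, late_merge_gap_min)
        for p in periods:
            period_rows.append(
                {"participant_id": pid, "night_key": p.night_key,
                 "onset": p.onset, "wake": p.wake, "n_cycles": len(p.cycles),
                 "is_late_onset": p.is_late_onset}
            )

        days = [compute_activity_day(grid, date, periods) for date in retained]
        summary = summarize_participant_activity(days)
        for d in days:
            act_day_rows.append(vars(d).copy())
        act_part_rows.append(vars(summary).copy())

        retained_set = set(retained)
        nights = [
            compute_night_metrics(p, restless_as_awake)
            for p in periods
            if p.night_key in retained_set
        ]
        nights.sort(key=lambda nm: nm.night_key)
        nights = nights[:MAX_NIGHTS]
        for nm in nights:
            row = vars(nm).copy()
            row["efficiency_pct"] = round(nm.efficiency * 100, 1)
            night_rows.append(row)
        sleep_summary = summarize_participant_sleep(nights)
        if sleep_summary is None:
            skip_rows.append({"participant_id": pid,
                              "reason": f"fewer than {MIN_NIGHTS} retained nights"})
        else:
            row = vars(sleep_summary).copy()
            row["mean_onset_clock"] = sleep_summary.mean_onset_clock
            row["mean_wake_clock"] = sleep_summary.mean_wake_clock
            row["mean_efficiency_pct"] = round(sleep_summary.mean_efficiency * 100, 1)
            if row["social_jet_lag_hours"] is None:
                row["social_jet_lag_hours"] = np.nan
            sleep_part_rows.append(row)
            clock_asleep[pid] = _participant_clock_profile(
                [p for p in periods if p.night_key in retained_set][:MAX_NIGHTS]
            )

    result = PipelineResult(
        cutoff=cutoff,
        wear_days=pd.DataFrame(wear_rows),
        participants=pd.DataFrame(part_rows),
        activity_days=pd.DataFrame(act_day_rows),
        activity_participants=pd.DataFrame(act_part_rows),
        sleep_periods=pd.DataFrame(period_rows),
        sleep_nights=pd.DataFrame(night_rows),
        sleep_participants=pd.DataFrame(sleep_part_rows),
        skip_log=pd.DataFrame(skip_rows, columns=["participant_id", "reason"]),
        metadata=metadata,
    )
    result.tables = build_cohort_tables(
        result.activity_participants, result.sleep_participants,
        result.participants, metadata,
    )
    result.tables["clock_matrix"] = _clock_matrix(
        clock_asleep, result.sleep_participants
    )
    return result


def _participant_clock_profile(periods) -> np.ndarray:
    """Per 15-min clock bin: fraction of the participant's nights asleep in it."""
    bins = np.zeros(N_CLOCK_BINS)
    if not periods:
        return bins
    for p in periods:
        stages = p.span_stages()
        onset_mod = int((p.onset - p.onset.normalize()) / MINUTE)
        asleep = np.isin(stages, (STAGE_ASLEEP, STAGE_RESTLESS))
        mods = (onset_mod + np.flatnonzero(asleep)) % 1440
        night_bins = np.zeros(N_CLOCK_BINS, dtype=bool)
        night_bins[np.unique(mods // CLOCK_BIN_MIN)] = True
        bins += night_bins
    return bins / len(periods)


def _clock_matrix(
    clock_asleep: dict[str, np.ndarray], sleep_participants: pd.DataFrame
) -> pd.DataFrame:
    labels = [f"{(b * CLOCK_BIN_MIN) // 60:02d}:{(b * CLOCK_BIN_MIN) % 60:02d}"
              for b in range(N_CLOCK_BINS)]
    out = pd.DataFrame({"clock_bin": labels})
    groups = {"overall": None, "before_midnight": "before_midnight",
              "after_midnight": "after_midnight"}
    for col, grp in groups.items():
        total = np.zeros(N_CLOCK_BINS)
        if not sleep_participants.empty:
            sel = sleep_participants
            if grp is not None:
                sel = sel[sel["onset_group"] == grp]
            for pid in sel["participant_id"]:
                total += clock_asleep.get(pid, 0)
        out[col] = total
    return out


# ---------------------------------------------------------------------------
# cohort tables

_ACTIVITY_METRICS = [
    ("wear_days", "n_days"),
    ("daily_wear_min", "mean_wear_minutes"),
    ("steps_per_hour", "mean_steps_per_hour"),
    ("steps_per_day", "mean_total_steps"),
    ("very_active_min", "mean_minutes_very"),
    ("moderately_active_min", "mean_minutes_moderate"),
    ("lightly_active_min", "mean_minutes_light"),
    ("awake_sedentary_min", "mean_minutes_awake_sedentary"),
]

_SLEEP_METRICS = [
    ("nights_with_data", "n_nights"),
    ("sleep_duration_h", "mean_span_hours"),
    ("sleep_efficiency_pct", "mean_efficiency_pct"),
    ("waso_h", "mean_waso_hours"),
    ("social_jet_lag_h", "social_jet_lag_hours"),
    ("onset_axis_min", "mean_onset_axis_min"),
    ("wake_axis_min", "mean_wake_axis_min"),
]


def _stat_rows(df: pd.DataFrame, metrics, stratum: str) -> list[dict]:
    rows = []
    for name, col in metrics:
        if df.empty or col not in df.columns:
            rows.append({"stratum": stratum, "metric": name, "n": 0,
                         "mean": np.nan, "sd": np.nan})
            continue
        vals = pd.to_numeric(df[col], errors="coerce").dropna()
        rows.append(
            {"stratum": stratum, "metric": name, "n": int(len(vals)),
             "mean": float(vals.mean()) if len(vals) else np.nan,
             "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan}
        )
    return rows


def build_cohort_tables(
    activity_participants: pd.DataFrame,
    sleep_participants: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Descriptive cohort tables from per-participant summary frames.

    Strata: overall plus sex (when metadata provides it) for the activity
    table; overall plus onset group for the sleep table.  Means are
    unweighted across participants; SDs are sample (n-1) SDs.
    """
    act_rows = _stat_rows(activity_participants, _ACTIVITY_METRICS, "overall")
    if (metadata is not None and "sex" in metadata.columns
            and not activity_participants.empty):
        joined = activity_participants.merge(
            metadata[["participant_id", "sex"]], on="participant_id", how="left"
        )
        for sex in sorted(joined["sex"].dropna().unique()):
            act_rows += _stat_rows(joined[joined["sex"] == sex], _ACTIVITY_METRICS, sex)
    table_activity = pd.DataFrame(act_rows)

    sleep_rows = _stat_rows(sleep_participants, _SLEEP_METRICS, "overall")
    for grp in ("before_midnight", "after_midnight"):
        sel = (
            sleep_participants[sleep_participants["onset_group"] == grp]
            if not sleep_participants.empty else sleep_participants
        )
        sleep_rows += _stat_rows(sel, _SLEEP_METRICS, grp)
    table_sleep = pd.DataFrame(sleep_rows)

    flow = pd.DataFrame(
        [
            {"stage": "received",
             "n": int(len(participants)) if participants is not None else 0},
            {"stage": "valid_600",
             "n": int(participants["is_valid_600"].sum())
             if participants is not None and not participants.empty else 0},
            {"stage": "valid_1200",
             "n": int(participants["is_valid_1200"].sum())
             if participants is not None and not participants.empty else 0},
            {"stage": "sleep_5plus_nights", "n": int(len(sleep_participants))},
        ]
    )
    return {"table_activity": table_activity, "table_sleep": table_sleep,
            "flow_counts": flow}


# ---------------------------------------------------------------------------
# output files

def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in PipelineResult.FRAME_NAMES:
        getattr(result, name).to_csv(outdir / f"{name}.csv", index=False)
    if result.metadata is not None:
        result.metadata.to_csv(outdir / "metadata.csv", index=False)
    for name, table in result.tables.items():
        table.to_csv(outdir / f"{name}.csv", index=False)


def rebuild_tables_from_csv(outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Recompute the cohort tables from the written per-participant CSVs."""
    outdir = Path(outdir)
    read = lambda name: pd.read_csv(outdir / f"{name}.csv",
                                    float_precision="round_trip")
    metadata = read("metadata") if (outdir / "metadata.csv").exists() else None
    return build_cohort_tables(
        read("activity_participants"), read("sleep_participants"),
        read("participants"), metadata,
    )
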
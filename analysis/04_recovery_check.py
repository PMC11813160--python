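#!/usr/bin/env python
"""Compare pipeline estimates with the generator's ground truth.

Joins the per-participant pipeline summaries against truth_summary() and
reports cohort-mean discrepancies for the headline metrics — the same
comparison the recovery tests assert on.
"""

import argparse
from pathlib import Path

import pandas as pd

import wearminute as wm
from wearminute.simulate import GroundTruth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--pipeline", type=Path, default=Path("results/pipeline"))
    ap.add_argument("--out", type=Path, default=Path("results/recovery.csv"))
    args = ap.parse_args()

    truth = GroundTruth(
        participants=pd.read_csv(args.cohort / "participants_meta.csv"),
        nights=pd.read_csv(args.cohort / "truth_nights.csv",
                           parse_dates=["onset", "wake"]),
        naps=pd.read_csv(args.cohort / "truth_naps.csv"),
        days=pd.read_csv(args.cohort / "truth_days.csv"),
    )
    ts = wm.truth_summary(truth)
    sleep = pd.read_csv(args.pipeline / "sleep_participants.csv").merge(
        ts, on="participant_id")
    act = pd.read_csv(args.pipeline / "activity_participants.csv").merge(
        ts, on="participant_id")

    pairs = [
        ("sleep duration (h)", sleep, "mean_span_hours", "true_span_h"),
        ("WASO (h)", sleep, "mean_waso_hours", "true_waso_h"),
        ("onset (min after noon)", sleep, "mean_onset_axis_min", "true_onset_axis"),
        ("wake (min after noon)", sleep, "mean_wake_axis_min", "true_wake_axis"),
        ("social jet lag (h)", sleep, "social_jet_lag_hours", "true_social_jet_lag_h"),
        ("steps/day", act, "mean_total_steps", "true_steps_day"),
        ("very active (min/d)", act, "mean_minutes_very", "true_very_min"),
        ("lightly active (min/d)", act, "mean_minutes_light", "true_light_min"),
    ]
    rows = []
    for label, df, est, tru in pairs:
        sub = df.dropna(subset=[est, tru])
        rows.append({"metric": label, "estimated": sub[est].mean(),
                     "truth": sub[tru].mean(),
                     "bias": sub[est].mean() - sub[tru].mean(),
                     "n": len(sub)})
        print(f"{label:28s} est {rows[-1]['estimated']:9.3f}  "
              f"truth {rows[-1]['truth']:9.3f}  bias {rows[-1]['bias']:+.4f}")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
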
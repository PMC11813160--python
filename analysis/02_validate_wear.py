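#!/usr/bin/env python
"""Wear-time validation: heart-rate presence per day, 600/1200-min cutoffs.

Reads the canonical minute CSVs written by 01_simulate.py, counts wear
minutes per calendar day, applies both valid-day cutoffs and the 5-9 day
participant rule, and reports the attrition under each cutoff.
"""

import argparse
from pathlib import Path

import pandas as pd

import wearminute as wm


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    wear_rows, part_rows = [], []
    for path in sorted(args.indir.glob("minutes_*.csv")):
        grid = wm.read_minutes_csv(path)
        days = wm.compute_wear_days(grid)
        wear_rows += [vars(d).copy() for d in days]
        v600 = wm.classify_participant(days, 600)
        v1200 = wm.classify_participant(days, 1200)
        part_rows.append(
            {"participant_id": grid.participant_id,
             "n_valid_days_600": v600.n_valid_days, "is_valid_600": v600.is_valid,
             "n_valid_days_1200": v1200.n_valid_days, "is_valid_1200": v1200.is_valid}
        )

    wear_days = pd.DataFrame(wear_rows)
    participants = pd.DataFrame(part_rows)
    args.out.mkdir(parents=True, exist_ok=True)
    wear_days.to_csv(args.out / "wear_days.csv", index=False)
    participants.to_csv(args.out / "participants.csv", index=False)

    n = len(participants)
    print(f"{n} participants, {len(wear_days)} participant-days")
    for cutoff in (600, 1200):
        k = int(participants[f"is_valid_{cutoff}"].sum())
        print(f"valid at {cutoff} min/day for 5+ days: {k}/{n} ({100 * k / n:.0f}%)")
    print(f"mean daily wear: {wear_days['wear_minutes'].mean():.0f} min")


if __name__ == "__main__":
    main()
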
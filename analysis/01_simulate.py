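#!/usr/bin/env python
"""Generate a synthetic minute-level cohort and write it as canonical CSVs.

Writes one minutes_<id>.csv per participant plus the generator's ground
truth (truth_nights.csv, truth_naps.csv, truth_days.csv, participants.csv)
so later stages can be checked against what was actually simulated.
"""

import argparse
from pathlib import Path

import wearminute as wm


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=50, help="participants")
    ap.add_argument("--days", type=int, default=8, help="days per participant")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    cfg = wm.CohortConfig(n_participants=args.n, days_per_participant=args.days,
                          seed=args.seed)
    grids, truth = wm.generate_cohort(cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    for g in grids:
        wm.write_minutes_csv(g, args.out / f"minutes_{g.participant_id}.csv")
    truth.nights.to_csv(args.out / "truth_nights.csv", index=False)
    truth.naps.to_csv(args.out / "truth_naps.csv", index=False)
    truth.days.to_csv(args.out / "truth_days.csv", index=False)
    truth.participants.to_csv(args.out / "participants_meta.csv", index=False)

    n_min = sum(g.n_minutes for g in grids)
    print(f"simulated {args.n} participants x {args.days} days "
          f"({n_min:,} minutes) with seed {args.seed}")
    print(f"truth: {len(truth.nights)} nights, {len(truth.naps)} naps")
    print(f"wrote cohort to {args.out}/")


if __name__ == "__main__":
    main()
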
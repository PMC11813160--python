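#!/usr/bin/env python
"""Full pipeline: wear validation, activity metrics, sleep segmentation and
sleep metrics, then cohort tables, from the canonical minute CSVs."""

import argparse
from pathlib import Path

import pandas as pd

import wearminute as wm
from wearminute.cohort import write_outputs


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/pipeline"))
    ap.add_argument("--cutoff", type=int, choices=(600, 1200), default=600)
    ap.add_argument("--late-merge-gap-min", type=int, default=60)
    ap.add_argument("--restless-as-awake", action="store_true",
                    help="count restless (stage 2) minutes as wakefulness")
    args = ap.parse_args()

    grids = [wm.read_minutes_csv(p) for p in sorted(args.indir.glob("minutes_*.csv"))]
    meta_path = args.indir / "participants_meta.csv"
    metadata = pd.read_csv(meta_path) if meta_path.exists() else None

    res = wm.run_pipeline(
        grids, cutoff=args.cutoff, late_merge_gap_min=args.late_merge_gap_min,
        restless_as_awake=args.restless_as_awake, metadata=metadata,
    )
    write_outputs(res, args.out)

    flow = res.tables["flow_counts"].set_index("stage")["n"]
    print(f"cutoff {args.cutoff} min/day; wrote outputs to {args.out}/")
    print(f"flow: received {flow['received']} -> valid@600 {flow['valid_600']} "
          f"-> valid@1200 {flow['valid_1200']} "
          f"-> 5+ sleep nights {flow['sleep_5plus_nights']}")
    sp = res.sleep_participants
    if not sp.empty:
        print(f"sleep: duration {sp['mean_span_hours'].mean():.2f} h, "
              f"efficiency {100 * sp['mean_efficiency'].mean():.1f}%, "
              f"WASO {sp['mean_waso_hours'].mean():.2f} h, "
              f"social jet lag {sp['social_jet_lag_hours'].mean():.2f} h")
    apf = res.activity_participants
    if not apf.empty:
        print(f"activity: {apf['mean_total_steps'].mean():.0f} steps/day, "
              f"awake sedentary {apf['mean_minutes_awake_sedentary'].mean():.0f} min/day")


if __name__ == "__main__":
    main()
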
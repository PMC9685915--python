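#!/usr/bin/env python
"""Kinetics summaries of the batch-fermentation time courses: glucose
consumption and ethanol production rates over 0-24 h, end-point ethanol
yield (% of the 0.511 g/g theoretical maximum), glycerol yield, and
residual glucose."""

import argparse
from pathlib import Path

import pandas as pd

import lowph
from lowph.fermentation import carbon_balance_ok


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--t0", type=float, default=0.0)
    ap.add_argument("--t1", type=float, default=24.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for path in sorted(args.data.glob("fermentation_*.tsv")):
        strain, condition = path.stem.split("_")[1:3]
        tc = lowph.read_timecourse(path, strain=strain, condition=condition)
        ks = lowph.kinetics_summary(tc, args.t0, args.t1)
        row = ks.to_dict()
        row["carbon_balance_ok"] = carbon_balance_ok(tc)
        rows.append(row)
    if not rows:
        raise SystemExit(f"no fermentation_*.tsv under {args.data}; run 01_simulate.py first")
    frame = pd.DataFrame(rows)
    frame.to_csv(args.out / "kinetics_summary.tsv", sep="\t", index=False)
    show = frame[["strain", "condition", "glucose_consumption_rate_gLh",
                  "ethanol_production_rate_gLh", "ethanol_yield_percent",
                  "glycerol_yield_gg", "residual_glucose_gL"]]
    print(show.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
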
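#!/usr/bin/env python
"""Replicate averaging and fold-change contrasts: each mutant strain vs KF-7
at both pH levels, then DEG calling at FC >= 2 / <= 0.5.

Reads results/data/ (run 01_simulate.py first), writes one contrast table
per strain and a DEG count summary."""

import argparse
from pathlib import Path

import pandas as pd

import lowph


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    if not (args.data / "expression.tsv").exists():
        raise SystemExit(f"no expression matrix under {args.data}; run 01_simulate.py first")
    args.out.mkdir(parents=True, exist_ok=True)

    matrix = lowph.read_matrix(args.data / "expression.tsv", args.data / "sample_sheet.tsv")
    contrasts = lowph.build_contrasts(matrix)
    rows = []
    for strain, contrast in contrasts.items():
        contrast.write(args.out / f"contrast_{strain}.tsv")
        for cond_key, cond_label in (("stress", "pH2.5"), ("control", "pH4.5")):
            calls = lowph.call_degs(contrast, cond_key)
            n_up = int((calls["direction"] == "up").sum())
            n_down = int((calls["direction"] == "down").sum())
            rows.append({"strain": strain, "condition": cond_label,
                         "up": n_up, "down": n_down, "total": n_up + n_down})
            print(f"{strain} vs KF-7 at {cond_label}: {n_up + n_down} DEGs "
                  f"({n_up} up, {n_down} down)")
        if contrast.undefined["stress"] or contrast.undefined["control"]:
            print(f"  {strain}: undefined fold changes excluded: "
                  f"{contrast.undefined}")
    pd.DataFrame(rows).to_csv(args.out / "deg_totals.tsv", sep="\t", index=False)
    print(f"\ncontrast tables and deg_totals.tsv written to {args.out}")


if __name__ == "__main__":
    main()
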
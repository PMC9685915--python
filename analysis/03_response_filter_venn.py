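#!/usr/bin/env python
"""The pH-specific response filter and the cross-strain set analysis.

Stress-condition DEGs are partitioned into unique-at-pH2.5 /
shared-amplified / shared-flat per strain; the selected sets
(unique + amplified) are intersected across B3, C3 and BC3 per direction.
When the data came from the simulator, recovery of the planted classes is
reported against the truth table."""

import argparse
from pathlib import Path

import pandas as pd

import lowph
from lowph.plotting import plot_venn3


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--figures", action="store_true", help="also write Venn PNGs")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    matrix = lowph.read_matrix(args.data / "expression.tsv", args.data / "sample_sheet.tsv")
    response_sets = {}
    for strain, contrast in lowph.build_contrasts(matrix).items():
        rs = lowph.classify_response(
            lowph.call_degs(contrast, "stress"),
            lowph.call_degs(contrast, "control"),
            contrast,
        )
        rs.write(args.out / f"response_{strain}.tsv")
        response_sets[strain] = rs

    counts = lowph.summarize_counts(response_sets)
    counts.to_csv(args.out / "deg_counts.tsv", sep="\t", index=False)
    print(counts.to_string(index=False))

    for d in ("up", "down"):
        sets = {s: rs.selected(d) for s, rs in response_sets.items()}
        vs = lowph.venn_analysis(sets, direction=d)
        vs.write(args.out / f"venn_{d}.tsv")
        b3c3 = len(vs.intersection("B3", "C3"))
        triple = len(vs.intersection("B3", "C3", "BC3"))
        print(f"\n{d}-regulated selected DEGs: B3&C3 share {b3c3}, "
              f"of which {triple} also in BC3")
        if args.figures:
            fig_dir = args.out / "figures"
            fig_dir.mkdir(exist_ok=True)
            plot_venn3(vs, fig_dir / f"venn_{d}.png", title=f"{d}-regulated selected DEGs")

    truth_path = args.data / "truth_table.tsv"
    if truth_path.exists():
        truth = lowph.read_truth_table(truth_path)
        rs = response_sets["B3"]
        called = truth.join(rs.table["response_class"].rename("called"), how="left")
        called["called"] = called["called"].fillna("null")
        planted = called[called["response_class"] != "null"]
        rec = (planted["called"] == planted["response_class"]).mean()
        print(f"\nplanted-label recovery (B3 contrast): {100 * rec:.1f}% "
              f"of {len(planted)} planted genes")


if __name__ == "__main__":
    main()
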
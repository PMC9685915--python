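#!/usr/bin/env python
"""2^-ddCt fold changes for the validation panel and their concordance with
the array fold changes (per mutant strain, at pH 2.5)."""

import argparse
import json
from pathlib import Path

import lowph


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    matrix = lowph.read_matrix(args.data / "expression.tsv", args.data / "sample_sheet.tsv")
    reference = _infer_reference(args.data)
    ct = lowph.read_ct_table(args.data / "qpcr_ct.tsv", reference_gene=reference)
    contrasts = lowph.build_contrasts(matrix)
    panel = sorted(set(ct.data["gene"]) - {ct.reference_gene})
    print(f"panel: {panel} (reference {ct.reference_gene})\n")

    summary = {}
    for strain in lowph.MUTANT_STRAINS:
        qpcr_fc = {
            g: lowph.ddct_fold_change(
                ct, g,
                [f"{strain}_pH2.5_r{r}" for r in (1, 2)],
                [f"KF-7_pH2.5_r{r}" for r in (1, 2)],
            )
            for g in panel
        }
        array_fc = {g: float(contrasts[strain].table.at[g, "fc_stress"]) for g in panel}
        rep = lowph.concordance(qpcr_fc, array_fc)
        rep.per_gene.to_csv(args.out / f"qpcr_concordance_{strain}.tsv", sep="\t")
        summary[strain] = rep.to_dict()
        print(f"{strain}: sign agreement {rep.sign_agreement:.2f}, "
              f"Spearman rho {rep.spearman_rho:.3f}")
    (args.out / "qpcr_concordance.json").write_text(json.dumps(summary, indent=2))


def _infer_reference(data_dir: Path) -> str:
    """The simulated reference is the gene present in the Ct table whose truth
    class is null; fall back to ACT1 for real tables."""
    import pandas as pd

    truth_path = data_dir / "truth_table.tsv"
    ct = pd.read_csv(data_dir / "qpcr_ct.tsv", sep="\t")
    if truth_path.exists():
        truth = lowph.read_truth_table(truth_path)
        for gene in ct["gene"].unique():
            if gene in truth.index and truth.at[gene, "response_class"] == "null":
                return gene
    return "ACT1"


if __name__ == "__main__":
    main()
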
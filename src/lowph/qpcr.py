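"""2^-ddCt relative quantification and microarray concordance.

Ct values are normalized within each sample to the reference gene ACT1
(dCt = Ct_target - Ct_reference, technical replicates averaged on the Ct
scale first), referenced to the control sample group (ddCt) and converted to
a fold change as 2^-ddCt.  Plate-wide Ct offsets cancel in dCt, and the
reference gene's own fold change is identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_GENE = "ACT1"

CT_COLUMNS = ("gene", "sample", "replicate", "ct")


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold measurements.

    ``data`` has one row per (gene, sample, technical replicate) with the
    measured Ct in cycles; ``reference_gene`` must be measured in every
    sample.  Ct values far outside the usual 5-40 cycle window trigger a
    warning but are kept.
    """

    data: pd.DataFrame
    reference_gene: str = REFERENCE_GENE

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)):
            raise ValueError("Ct values must be finite")
        if ((ct < 5) | (ct > 40)).any():
            import warnings

            warnings.warn("Ct values outside the typical 5-40 cycle range")
        samples_with_ref = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample"])
        all_samples = set(self.data["sample"])
        if all_samples - samples_with_ref:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing from samples: "
                f"{sorted(all_samples - samples_with_ref)[:5]}"
            )

    def mean_ct(self, gene: str, sample: str) -> float:
        """Technical-replicate mean Ct for one gene in one sample."""
        sub = self.data[(self.data["gene"] == gene) & (self.data["sample"] == sample)]
        if sub.empty:
            raise KeyError(f"no Ct for gene={gene!r} in sample={sample!r}")
        return float(sub["ct"].mean())

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_ct_table(source: str | Path, reference_gene: str = REFERENCE_GENE) -> CtTable:
    return CtTable(pd.read_csv(source, sep="\t"), reference_gene=reference_gene)


def ddct_fold_change(
    ct: CtTable,
    target: str,
    treatment_samples: Sequence[str],
    control_samples: Sequence[str],
) -> float:
    """Relative expression of ``target`` in treatment vs control as 2^-ddCt.

    dCt is computed per biological sample (technical replicates averaged on
    the Ct scale); the control group is summarized by its mean dCt and the
    treatment group by the mean of per-sample fold changes
    2^-(dCt_i - mean dCt_control).
    """
    if not treatment_samples or not control_samples:
        raise ValueError("both sample groups must be non-empty")

    def dct(sample: str) -> float:
        return ct.mean_ct(target, sample) - ct.mean_ct(ct.reference_gene, sample)

    dct_control = np.mean([dct(s) for s in control_samples])
    fcs = [2.0 ** -(dct(s) - dct_control) for s in treatment_samples]
    return float(np.mean(fcs))


@dataclass
class ConcordanceReport:
    """Agreement between qPCR and microarray fold changes over a gene panel."""

    per_gene: pd.DataFrame
    sign_agreement: float
    spearman_rho: float
    spearman_p: float

    def to_dict(self) -> dict:
        return {
            "n_genes": int(len(self.per_gene)),
            "sign_agreement": self.sign_agreement,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
        }


def concordance(
    qpcr_fc: Mapping[str, float],
    array_fc: Mapping[str, float],
    panel: Iterable[str] | None = None,
) -> ConcordanceReport:
    """Sign agreement (log2 scale) and Spearman correlation of two fold-change sets."""
    genes = set(qpcr_fc) & set(array_fc)
    if panel is not None:
        genes &= set(panel)
    genes = sorted(genes)
    if len(genes) < 2:
        raise ValueError("need >= 2 overlapping genes for concordance")
    q = np.array([qpcr_fc[g] for g in genes], dtype=float)
    a = np.array([array_fc[g] for g in genes], dtype=float)
    if (q <= 0).any() or (a <= 0).any():
        raise ValueError("fold changes must be positive")
    lq, la = np.log2(q), np.log2(a)
    agreement = float(np.mean(np.sign(lq) == np.sign(la)))
    rho, p = stats.spearmanr(lq, la)
    per_gene = pd.DataFrame(
        {
            "gene": genes,
            "qpcr_fc": q,
            "array_fc": a,
            "log2_qpcr": lq,
            "log2_array": la,
            "sign_agree": np.sign(lq) == np.sign(la),
        }
    ).set_index("gene")
    return ConcordanceReport(
        per_gene=per_gene,
        sign_agreement=agreement,
        spearman_rho=float(rho),
        spearman_p=float(p),
    )
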
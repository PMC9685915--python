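"""Expression matrices, replicate averaging and mutant-vs-reference fold changes.

The experimental design is fixed by the study: four *Saccharomyces cerevisiae*
strains (the reference KF-7 and the low-pH-tolerant derivatives B3, C3 and
BC3), each profiled at a stress pH (2.5) and a control pH (4.5) with two
biological replicates — 16 arrays in total.  All arithmetic is performed on
the linear intensity scale: a fold change is a ratio of replicate-averaged
intensities, mutant over reference.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STRAINS = ("KF-7", "B3", "C3", "BC3")
REFERENCE_STRAIN = "KF-7"
MUTANT_STRAINS = ("B3", "C3", "BC3")
CONDITIONS = ("pH2.5", "pH4.5")
STRESS_CONDITION = "pH2.5"
CONTROL_CONDITION = "pH4.5"

SAMPLE_SHEET_COLUMNS = ("sample_id", "strain", "condition", "replicate")


class MatrixFormatError(ValueError):
    """The expression matrix itself is malformed (duplicate genes, bad values)."""


class DesignError(ValueError):
    """The sample sheet does not describe a valid strain x condition design."""


@dataclass
class ExpressionMatrix:
    """A gene x sample intensity matrix with its sample metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative linear-scale intensities, genes as the
        index, sample identifiers as columns.
    samples
        DataFrame indexed by sample identifier with columns ``strain``,
        ``condition`` and ``replicate``; must cover every column of
        ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise MatrixFormatError(f"duplicate gene identifiers: {list(dupes)[:5]}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise MatrixFormatError("expression values must be finite")
        if (vals < 0).any():
            raise MatrixFormatError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise DesignError(f"samples missing from sample sheet: {sorted(missing)}")
        bad_strain = set(self.samples["strain"]) - set(STRAINS)
        if bad_strain:
            raise DesignError(f"unknown strains: {sorted(bad_strain)}")
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise DesignError(f"unknown conditions: {sorted(bad_cond)}")
        counts = self.samples.loc[list(self.values.columns)].groupby(
            ["strain", "condition"], observed=True
        ).size()
        if counts.nunique() > 1:
            raise DesignError(
                "unbalanced design: replicate counts differ across "
                f"strain x condition cells:\n{counts}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_replicates(self) -> int:
        return int(
            self.samples.loc[list(self.values.columns)]
            .groupby(["strain", "condition"], observed=True)
            .size()
            .iloc[0]
        )

    def columns_for(self, strain: str, condition: str) -> list[str]:
        """Sample identifiers belonging to one strain x condition cell."""
        sub = self.samples.loc[list(self.values.columns)]
        mask = (sub["strain"] == strain) & (sub["condition"] == condition)
        cols = list(sub.index[mask])
        if not cols:
            raise DesignError(f"no samples for strain={strain!r}, condition={condition!r}")
        return cols

    def write(self, matrix_path: str | Path, sample_sheet_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene")
        self.samples.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")


@dataclass
class ContrastTable:
    """Per-gene fold changes of one mutant strain against KF-7 at both pH levels.

    ``table`` is indexed by gene with float columns ``fc_stress`` (pH 2.5) and
    ``fc_control`` (pH 4.5); undefined fold changes (zero reference mean) are
    stored as NaN and listed in ``undefined``.
    """

    mutant: str
    reference: str
    table: pd.DataFrame
    undefined: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"fc_stress", "fc_control"} - set(self.table.columns)
        if missing:
            raise ValueError(f"contrast table missing columns: {sorted(missing)}")

    def write(self, path: str | Path) -> None:
        out = self.table.rename(
            columns={"fc_stress": "fc_pH2.5", "fc_control": "fc_pH4.5"}
        )
        out.to_csv(path, sep="\t", index_label="gene")


def read_matrix(
    matrix_source: str | Path | io.TextIOBase,
    sample_sheet_source: str | Path | io.TextIOBase,
) -> ExpressionMatrix:
    """Read and validate an expression TSV plus its sample sheet.

    The matrix TSV has gene identifiers in the first column and one column
    per sample; the sample sheet has columns ``sample_id``, ``strain``,
    ``condition``, ``replicate``.
    """
    values = pd.read_csv(matrix_source, sep="\t", index_col=0)
    if values.index.has_duplicates:
        raise MatrixFormatError("duplicate gene identifiers in matrix")
    sheet = pd.read_csv(sample_sheet_source, sep="\t", dtype={"replicate": int})
    missing_cols = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing_cols:
        raise DesignError(f"sample sheet missing columns: {sorted(missing_cols)}")
    sheet = sheet.set_index("sample_id")
    return ExpressionMatrix(values=values, samples=sheet)


def average_replicates(m: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic mean over replicates on the linear scale.

    Returns a DataFrame indexed by gene whose columns are a MultiIndex of
    (strain, condition) — one column per design cell.
    """
    pieces = {}
    present = m.samples.loc[list(m.values.columns)]
    for (strain, condition), grp in present.groupby(["strain", "condition"], observed=True):
        pieces[(strain, condition)] = m.values[list(grp.index)].mean(axis=1)
    out = pd.DataFrame(pieces)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["strain", "condition"])
    return out


def fold_change(
    reduced: pd.DataFrame,
    mutant: str,
    reference: str,
    condition: str,
) -> pd.Series:
    """FC(g) = mean_mutant(g) / mean_reference(g) at one condition.

    A zero reference mean makes the ratio undefined; such genes get NaN
    (0/0 likewise) and are excluded from downstream DEG calling.
    """
    for strain in (mutant, reference):
        if (strain, condition) not in reduced.columns:
            raise KeyError(f"no averaged column for strain={strain!r}, condition={condition!r}")
    num = reduced[(mutant, condition)].to_numpy(dtype=float)
    den = reduced[(reference, condition)].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(den > 0, num / den, np.nan)
    return pd.Series(fc, index=reduced.index, name=f"fc_{condition}")


def build_contrasts(
    m: ExpressionMatrix,
    mutants: Iterable[str] = MUTANT_STRAINS,
    reference: str = REFERENCE_STRAIN,
) -> dict[str, ContrastTable]:
    """One ContrastTable per mutant strain versus the reference at both pH levels."""
    present = set(m.samples.loc[list(m.values.columns), "strain"])
    if reference not in present:
        raise DesignError(f"reference strain {reference!r} absent from matrix")
    reduced = average_replicates(m)
    out: dict[str, ContrastTable] = {}
    for mutant in mutants:
        if mutant not in present:
            raise DesignError(f"mutant strain {mutant!r} absent from matrix")
        fc_stress = fold_change(reduced, mutant, reference, STRESS_CONDITION)
        fc_control = fold_change(reduced, mutant, reference, CONTROL_CONDITION)
        table = pd.DataFrame({"fc_stress": fc_stress, "fc_control": fc_control})
        undefined = {
            "stress": list(table.index[fc_stress.isna()]),
            "control": list(table.index[fc_control.isna()]),
        }
        out[mutant] = ContrastTable(
            mutant=mutant, reference=reference, table=table, undefined=undefined
        )
    return out
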
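"""DEG calling, the pH-specific response filter, and cross-strain set analysis.

A gene is differentially expressed (DEG) in a mutant-vs-KF-7 contrast when its
replicate-averaged fold change is >= 2 (up) or <= 0.5 (down).  Of the DEGs
found under the stress condition (pH 2.5), only two kinds are considered part
of the specific low-pH response and carried forward:

* ``unique_stress`` — a DEG at pH 2.5 that is not a same-direction DEG at
  pH 4.5;
* ``shared_amplified`` — a DEG at both pH levels whose fold-change ratio
  R = FC(pH2.5) / FC(pH4.5) exceeds 1.5 (up) or falls below 0.67 (down),
  i.e. the response is markedly stronger under stress.

The remainder (``shared_flat``) responds similarly at both pH levels — the
general stress response rather than an acid-specific one — and is excluded.
Uniqueness and sharing are evaluated within a direction stratum (up or down);
genes that flip direction between conditions land in ``unique_stress`` for
their stress-condition direction and are logged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ContrastTable

THETA_UP = 2.0
THETA_DOWN = 0.5
RHO_UP = 1.5
RHO_DOWN = 0.67

#: relative tolerance for comparisons that land exactly on a threshold
REL_TOL = 1e-9

DIRECTIONS = ("up", "down")
RESPONSE_CLASSES = ("unique_stress", "shared_amplified", "shared_flat")


def _ge(a: float, b: float) -> bool:
    return a >= b * (1.0 - REL_TOL)


def _le(a: float, b: float) -> bool:
    return a <= b * (1.0 + REL_TOL)


def _gt(a: float, b: float) -> bool:
    return a > b * (1.0 + REL_TOL)


def _lt(a: float, b: float) -> bool:
    return a < b * (1.0 - REL_TOL)


def call_direction(fc: float, theta_up: float = THETA_UP, theta_down: float = THETA_DOWN) -> str:
    """Classify one fold change as ``up``, ``down`` or ``none`` (thresholds inclusive)."""
    if np.isnan(fc):
        return "none"
    if _ge(fc, theta_up):
        return "up"
    if _le(fc, theta_down):
        return "down"
    return "none"


def call_degs(
    contrast: ContrastTable,
    condition: str,
    theta_up: float = THETA_UP,
    theta_down: float = THETA_DOWN,
) -> pd.DataFrame:
    """Apply the fold-change DEG rule to one condition of a contrast.

    Parameters
    ----------
    condition
        ``"stress"`` (pH 2.5) or ``"control"`` (pH 4.5).

    Returns a DataFrame indexed by gene with columns ``fc`` and ``direction``;
    genes with undefined fold changes are skipped (they appear in the
    contrast's ``undefined`` log, not here).
    """
    col = {"stress": "fc_stress", "control": "fc_control"}.get(condition)
    if col is None:
        raise KeyError(f"condition must be 'stress' or 'control', got {condition!r}")
    fc = contrast.table[col]
    defined = fc.dropna()
    direction = np.where(
        defined.to_numpy() >= theta_up * (1.0 - REL_TOL),
        "up",
        np.where(defined.to_numpy() <= theta_down * (1.0 + REL_TOL), "down", "none"),
    )
    return pd.DataFrame({"fc": defined, "direction": direction}, index=defined.index)


@dataclass
class ResponseSet:
    """Direction-stratified classification of one strain's stress-condition DEGs.

    ``table`` is indexed by the stress-condition DEGs and has columns
    ``direction``, ``fc_stress``, ``fc_control``, ``ratio``,
    ``response_class`` and ``selected``.  ``selected`` marks the genes used
    for downstream analysis: unique_stress plus shared_amplified.
    """

    strain: str
    table: pd.DataFrame
    control_deg_counts: dict[str, int] = field(default_factory=dict)
    direction_flips: list[str] = field(default_factory=list)

    def genes(self, response_class: str, direction: str | None = None) -> set[str]:
        mask = self.table["response_class"] == response_class
        if direction is not None:
            mask &= self.table["direction"] == direction
        return set(self.table.index[mask])

    def selected(self, direction: str | None = None) -> set[str]:
        mask = self.table["selected"]
        if direction is not None:
            mask = mask & (self.table["direction"] == direction)
        return set(self.table.index[mask])

    def write(self, path: str | Path) -> None:
        out = self.table.rename(
            columns={"fc_stress": "fc_pH2.5", "fc_control": "fc_pH4.5"}
        )
        out.to_csv(path, sep="\t", index_label="gene")


def classify_response(
    calls_stress: pd.DataFrame,
    calls_control: pd.DataFrame,
    contrast: ContrastTable,
    rho_up: float = RHO_UP,
    rho_down: float = RHO_DOWN,
) -> ResponseSet:
    """Partition the stress-condition DEGs into unique / shared-amplified / shared-flat.

    ``calls_stress`` and ``calls_control`` must come from :func:`call_degs`
    on the same contrast; a gene present in one call table but absent from
    the contrast is a consistency error.
    """
    for name, calls in (("stress", calls_stress), ("control", calls_control)):
        stray = set(calls.index) - set(contrast.table.index)
        if stray:
            raise ValueError(
                f"{name} calls contain genes absent from the contrast: {sorted(stray)[:5]}"
            )

    stress_degs = calls_stress[calls_stress["direction"] != "none"]
    control_dir = calls_control["direction"]

    rows = []
    flips = []
    for gene, row in stress_degs.iterrows():
        d = row["direction"]
        fc_s = float(row["fc"])
        fc_c = float(contrast.table.at[gene, "fc_control"])
        ctrl_d = control_dir.get(gene, "none")
        ratio = fc_s / fc_c if (not np.isnan(fc_c) and fc_c > 0) else np.nan
        if ctrl_d != d:
            cls = "unique_stress"
            if ctrl_d != "none":
                flips.append(gene)
        else:
            if d == "up":
                amplified = _gt(ratio, rho_up)
            else:
                amplified = _lt(ratio, rho_down)
            cls = "shared_amplified" if amplified else "shared_flat"
        rows.append((gene, d, fc_s, fc_c, ratio, cls, cls != "shared_flat"))

    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "direction", "fc_stress", "fc_control",
            "ratio", "response_class", "selected",
        ],
    ).set_index("gene")
    control_counts = {
        d: int((calls_control["direction"] == d).sum()) for d in DIRECTIONS
    }
    return ResponseSet(
        strain=contrast.mutant,
        table=table,
        control_deg_counts=control_counts,
        direction_flips=flips,
    )


@dataclass
class VennSummary:
    """Region memberships of a three-set comparison of selected DEGs."""

    direction: str
    set_names: tuple[str, ...]
    #: exclusive regions keyed by frozenset of member set names
    regions: dict[frozenset, set[str]]
    #: plain (non-exclusive) intersections keyed by frozenset of names
    intersections: dict[frozenset, set[str]]

    def region_counts(self) -> dict[str, int]:
        out = {}
        for key, members in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            out["&".join(sorted(key))] = len(members)
        return out

    def intersection(self, *names: str) -> set[str]:
        return self.intersections[frozenset(names)]

    def write(self, path: str | Path) -> None:
        rows = []
        for key, members in self.regions.items():
            label = "&".join(sorted(key))
            for g in sorted(members):
                rows.append((label, g))
        pd.DataFrame(rows, columns=["region", "gene"]).to_csv(path, sep="\t", index=False)


def venn_analysis(sets: Mapping[str, set[str]], direction: str = "up") -> VennSummary:
    """Exact region memberships and intersections over named gene sets."""
    names = tuple(sets)
    regions: dict[frozenset, set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set().union(*(set(sets[n]) for n in names if n not in combo)) if len(combo) < len(names) else set()
            regions[frozenset(combo)] = inside - outside
    intersections = {
        frozenset(combo): set.intersection(*(set(sets[n]) for n in combo))
        for r in range(1, len(names) + 1)
        for combo in itertools.combinations(names, r)
    }
    return VennSummary(direction=direction, set_names=names, regions=regions, intersections=intersections)


def summarize_counts(response_sets: Mapping[str, ResponseSet]) -> pd.DataFrame:
    """Count report per strain: DEG totals and the unique/shared partition.

    One row per strain x direction with the stress-condition DEG total, the
    three response-class counts, the selected count and the control-condition
    DEG count.  The partition identity
    ``stress_degs == unique_stress + shared_amplified + shared_flat`` holds by
    construction and is re-asserted here.
    """
    rows = []
    for strain, rs in response_sets.items():
        for d in DIRECTIONS:
            sub = rs.table[rs.table["direction"] == d]
            n_unique = int((sub["response_class"] == "unique_stress").sum())
            n_amp = int((sub["response_class"] == "shared_amplified").sum())
            n_flat = int((sub["response_class"] == "shared_flat").sum())
            assert n_unique + n_amp + n_flat == len(sub)
            rows.append(
                {
                    "strain": strain,
                    "direction": d,
                    "stress_degs": len(sub),
                    "unique_stress": n_unique,
                    "shared_amplified": n_amp,
                    "shared_flat": n_flat,
                    "selected": n_unique + n_amp,
                    "control_degs": rs.control_deg_counts.get(d, 0),
                }
            )
    return pd.DataFrame(rows)
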
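"""Hypergeometric pathway over-representation with the dual P / enrichment-ratio rule.

For a term containing K of the N annotated genes, with n selected DEGs in the
universe of which k fall in the term, the P value is the upper tail
P(X >= k) of Hypergeometric(N, K, n) and the enrichment ratio is ER = k / K.
A term is significantly enriched when P <= 0.05 AND ER >= 0.2; no
multiple-testing correction enters the significance call (a Benjamini-
Hochberg q-value column is emitted for information only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
MIN_ENRICHMENT_RATIO = 0.2

_REL_TOL = 1e-9


class GmtFormatError(ValueError):
    """A GMT line does not have the term/description/genes... shape."""


@dataclass
class PathwayAnnotation:
    """Term -> gene-set mapping with its implied gene universe."""

    terms: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, g in self.terms.items() if not g]
        if empty:
            raise ValueError(f"empty terms not allowed: {empty[:5]}")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return out

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term in self.terms:
                desc = self.descriptions.get(term, "na")
                genes = "\t".join(sorted(self.terms[term]))
                fh.write(f"{term}\t{desc}\t{genes}\n")


def read_gmt(source: str | Path) -> PathwayAnnotation:
    """Parse a GMT file: one term per line, tab-separated term, description, genes."""
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtFormatError(
                    f"line {lineno}: expected term, description and >= 1 gene, "
                    f"got {len(parts)} fields"
                )
            term, desc, genes = parts[0], parts[1], parts[2:]
            if term in terms:
                raise GmtFormatError(f"line {lineno}: duplicate term {term!r}")
            if len(set(genes)) < len(genes):
                warnings.warn(f"term {term!r}: duplicate genes deduplicated")
            terms[term] = set(genes)
            descriptions[term] = desc
    return PathwayAnnotation(terms=terms, descriptions=descriptions)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` genes in the universe, ``K`` of them in the term, ``n`` drawn
    (the selected DEGs), ``k`` of the draws inside the term.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    # sf(k-1) = P(X >= k); includes k itself per the over-representation convention
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    term: str
    k: int
    K: int
    n: int
    N: int
    pvalue: float
    enrichment_ratio: float
    qvalue: float
    significant: bool


def enrich(
    selected: Iterable[str],
    annotation: PathwayAnnotation,
    alpha: float = ALPHA,
    min_er: float = MIN_ENRICHMENT_RATIO,
    background: Iterable[str] | None = None,
    restrict_terms_to_background: bool = False,
) -> list[EnrichmentResult]:
    """Test every term for over-representation of the selected genes.

    The universe defaults to all genes in the annotation; pass ``background``
    (e.g. all genes on the array) to use a different one.  With
    ``restrict_terms_to_background`` the term size K counts only genes also
    present in the universe, otherwise all annotated genes per term.
    Selected genes outside the universe are dropped (their count is recorded
    in the warning log).  Results are sorted by P value.
    """
    universe = set(background) if background is not None else annotation.universe
    if not universe:
        raise ValueError("empty gene universe")
    selected = set(selected)
    dropped = selected - universe
    if dropped:
        warnings.warn(f"{len(dropped)} selected genes outside the universe were dropped")
    selected &= universe
    N = len(universe)
    n = len(selected)

    results = []
    for term, genes in annotation.terms.items():
        term_in_universe = genes & universe
        K = len(term_in_universe) if restrict_terms_to_background else len(genes)
        k = len(selected & term_in_universe)
        if K == 0:
            continue
        p = hypergeom_pvalue(k, len(term_in_universe), n, N)
        er = k / K
        results.append(
            EnrichmentResult(
                term=term, k=k, K=K, n=n, N=N,
                pvalue=p, enrichment_ratio=er, qvalue=np.nan,
                significant=(
                    p <= alpha * (1.0 + _REL_TOL)
                    and er >= min_er * (1.0 - _REL_TOL)
                ),
            )
        )
    if results:
        qvals = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            r.qvalue = float(q)
    results.sort(key=lambda r: (r.pvalue, r.term))
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (term, k, K, n, N, ER, P, BH-q, significant)."""
    return pd.DataFrame(
        [
            {
                "term": r.term, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "enrichment_ratio": r.enrichment_ratio, "pvalue": r.pvalue,
                "qvalue": r.qvalue, "significant": r.significant,
            }
            for r in results
        ]
    )
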
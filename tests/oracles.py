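"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most literal route available —
exhaustive enumeration, direct scans applying the published rules verbatim —
and share no code with the implementation they check.
"""

from itertools import combinations

import numpy as np


def hypergeom_upper_tail_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws from a universe of N genes.

    The first K genes form the term; every subset of size n is counted and
    the fraction with >= k term members returned.
    """
    term = set(range(K))
    total = hits = 0
    for subset in combinations(range(N), n):
        total += 1
        if len(term.intersection(subset)) >= k:
            hits += 1
    return hits / total


def hypergeom_pmf_by_enumeration(K: int, n: int, N: int) -> dict[int, float]:
    """Full pmf of the term-overlap count by exhaustive enumeration."""
    term = set(range(K))
    counts: dict[int, int] = {}
    total = 0
    for subset in combinations(range(N), n):
        total += 1
        k = len(term.intersection(subset))
        counts[k] = counts.get(k, 0) + 1
    return {k: c / total for k, c in counts.items()}


def classify_by_direct_scan(fc_stress: dict, fc_control: dict) -> dict[str, str]:
    """Apply the published rules verbatim, one gene at a time.

    DEG: fold change >= 2 or <= 0.5.  Of the stress-condition (pH 2.5) DEGs:
    unique if not a same-direction DEG at control pH; else amplified if
    FC(pH2.5)/FC(pH4.5) > 1.5 (up) or < 0.67 (down); else flat.  Returns
    gene -> class for stress DEGs only.
    """
    out = {}
    for gene, fs in fc_stress.items():
        fc = fc_control[gene]
        if fs >= 2:
            d = "up"
        elif fs <= 0.5:
            d = "down"
        else:
            continue
        shared = (fc >= 2) if d == "up" else (fc <= 0.5)
        if not shared:
            out[gene] = "unique_stress"
        else:
            r = fs / fc
            amplified = (r > 1.5) if d == "up" else (r < 0.67)
            out[gene] = "shared_amplified" if amplified else "shared_flat"
    return out


def venn_regions_by_membership_scan(sets: dict) -> dict[str, set]:
    """Exclusive Venn regions by scanning each element's memberships."""
    universe = set().union(*sets.values())
    regions: dict[str, set] = {}
    for el in universe:
        members = frozenset(name for name, s in sets.items() if el in s)
        regions.setdefault("&".join(sorted(members)), set()).add(el)
    return regions


def random_contrast_pair(rng: np.random.Generator, n_genes: int) -> tuple[dict, dict]:
    """Random defined fold-change pairs spanning the interesting range."""
    genes = [f"r{i}" for i in range(n_genes)]
    fs = np.exp(rng.uniform(np.log(0.02), np.log(20), n_genes))
    fc = np.exp(rng.uniform(np.log(0.02), np.log(20), n_genes))
    return dict(zip(genes, fs)), dict(zip(genes, fc))
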
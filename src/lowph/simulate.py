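"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design — 16 microarrays (4 strains x 2 pH x
2 biological replicates), a panel of qPCR Ct measurements normalized to a
reference gene, a GMT pathway annotation, and batch-fermentation time
courses — with known, planted effects so that each downstream stage can be
validated against a truth table.

Planted response classes
------------------------
unique_stress      DEG at pH 2.5 only (control fold change 1)
shared_amplified   DEG at both pH levels, stress/control ratio beyond 1.5 (up)
                   or 0.67 (down)
shared_flat        DEG at both pH levels with a near-constant fold change
null               no planted effect (fold change 1 everywhere)

Planted classes are split evenly between up- and down-regulation by using the
reciprocal fold-change pair for the "down" half; because the ratio thresholds
are reciprocal (0.67 ~ 1/1.5), the same pair works in both directions.
Replicate noise is multiplicative log-normal with unit mean and a stated
coefficient of variation, the usual model for linear-scale array intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import PathwayAnnotation
from .expression import (
    CONDITIONS,
    CONTROL_CONDITION,
    MUTANT_STRAINS,
    REFERENCE_STRAIN,
    STRAINS,
    STRESS_CONDITION,
    ExpressionMatrix,
)
from .fermentation import THEORETICAL_ETHANOL_YIELD, FermentationTimecourse
from .qpcr import CtTable

RESPONSE_CLASSES = ("unique_stress", "shared_amplified", "shared_flat", "null")


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted expression simulation.

    ``fc_unique`` is the stress-condition fold change of unique responders
    (their control fold change is 1); the shared classes use
    (stress, control) fold-change pairs whose ratio is above 1.5 for the
    amplified class and between 0.67 and 1.5 for the flat class.  Genes not
    assigned to a planted class are null.  ``noise_cv`` is the coefficient
    of variation of the multiplicative log-normal replicate noise.
    """

    n_genes: int = 1000
    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {
            "unique_stress": 100,
            "shared_amplified": 50,
            "shared_flat": 50,
        }
    )
    # pairs sit well inside their class regions: every planted value keeps a
    # clear margin from the DEG boundaries (2, 0.5) and the ratio boundaries
    # (1.5, 0.67), so reciprocal (down) genes are safe too
    fc_unique: float = 4.0
    fc_shared_amplified: tuple[float, float] = (5.0, 2.5)
    fc_shared_flat: tuple[float, float] = (3.0, 2.5)
    noise_cv: float = 0.1
    baseline_mean: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_per_class) - set(RESPONSE_CLASSES)
        if unknown:
            raise ConfigError(f"unknown response classes: {sorted(unknown)}")
        if any(c < 0 for c in self.n_per_class.values()):
            raise ConfigError("class counts must be >= 0")
        planted = sum(self.n_per_class.get(c, 0) for c in RESPONSE_CLASSES if c != "null")
        if planted > self.n_genes:
            raise ConfigError(
                f"planted classes ({planted} genes) exceed n_genes={self.n_genes}"
            )
        for fc in (self.fc_unique, *self.fc_shared_amplified, *self.fc_shared_flat):
            if fc <= 0:
                raise ConfigError("fold changes must be > 0")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be > 0")


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=shape)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def read_truth_table(path) -> pd.DataFrame:
    """Read a written truth table; 'null' is a class label, not a missing value."""
    return pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)


def make_truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Planted per-gene truth: direction, response class, and fold-change pair.

    Indexed by gene with columns ``direction`` (up/down/none),
    ``response_class``, ``fc_stress`` and ``fc_control``.  Null genes have
    both fold changes equal to 1.
    """
    genes = _gene_names(config.n_genes)
    cls = np.full(config.n_genes, "null", dtype=object)
    fc_s = np.ones(config.n_genes)
    fc_c = np.ones(config.n_genes)
    pairs = {
        "unique_stress": (config.fc_unique, 1.0),
        "shared_amplified": config.fc_shared_amplified,
        "shared_flat": config.fc_shared_flat,
    }
    start = 0
    for name in ("unique_stress", "shared_amplified", "shared_flat"):
        count = config.n_per_class.get(name, 0)
        s, c = pairs[name]
        idx = np.arange(start, start + count)
        cls[idx] = name
        n_up = count - count // 2  # odd counts: the extra gene is upregulated
        fc_s[idx[:n_up]], fc_c[idx[:n_up]] = s, c
        fc_s[idx[n_up:]], fc_c[idx[n_up:]] = 1.0 / s, 1.0 / c
        start += count
    direction = np.where(cls == "null", "none", np.where(fc_s > 1.0, "up", "down"))
    return pd.DataFrame(
        {"direction": direction, "response_class": cls, "fc_stress": fc_s, "fc_control": fc_c},
        index=pd.Index(genes, name="gene"),
    )


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the 16-array design with planted fold changes.

    The reference strain's mean intensity is ``baseline_mean`` for every gene
    at both pH levels; each mutant strain's mean is baseline times the
    planted fold change of the corresponding condition.  Replicate values are
    the means perturbed by unit-mean log-normal noise, so with ``noise_cv=0``
    recomputed fold changes equal the planted ones exactly.
    """
    truth = make_truth_table(config)
    rng = np.random.default_rng(config.seed)

    sample_ids, meta_rows = [], []
    cols = {}
    for strain in STRAINS:
        for condition in CONDITIONS:
            fc = (
                np.ones(config.n_genes)
                if strain == REFERENCE_STRAIN
                else truth["fc_stress" if condition == STRESS_CONDITION else "fc_control"].to_numpy()
            )
            mean = config.baseline_mean * fc
            for rep in (1, 2):
                sid = f"{strain}_{condition}_r{rep}"
                noise = _lognormal_factors(rng, config.noise_cv, config.n_genes)
                cols[sid] = mean * noise
                sample_ids.append(sid)
                meta_rows.append((sid, strain, condition, rep))
    values = pd.DataFrame(cols, index=truth.index)
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "strain", "condition", "replicate"]
    ).set_index("sample_id")
    return ExpressionMatrix(values=values, samples=samples), truth


def simulate_annotation(
    truth: pd.DataFrame,
    n_terms: int = 30,
    enriched_terms: int = 5,
    seed: int = 0,
    term_size: int = 20,
    planted_fraction: float = 0.5,
) -> PathwayAnnotation:
    """Toy pathway annotation over the simulated genes.

    ``enriched_terms`` of the ``n_terms`` terms draw ``planted_fraction`` of
    their members from the planted responders (unique_stress and
    shared_amplified genes), guaranteeing k/K >= 0.2 by construction; the
    remaining terms sample genes uniformly.
    """
    if enriched_terms > n_terms:
        raise ConfigError("enriched_terms cannot exceed n_terms")
    if term_size <= 0:
        raise ConfigError("term size must be > 0")
    if not 0.2 <= planted_fraction <= 1.0:
        raise ConfigError("planted_fraction must be in [0.2, 1] to guarantee k/K >= 0.2")
    rng = np.random.default_rng(seed)
    genes = np.array(truth.index)
    responders = np.array(
        truth.index[truth["response_class"].isin(["unique_stress", "shared_amplified"])]
    )
    n_planted = int(round(planted_fraction * term_size))
    if enriched_terms > 0 and len(responders) < n_planted:
        raise ConfigError(
            f"need >= {n_planted} planted responders to build enriched terms, "
            f"have {len(responders)}"
        )
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_terms):
        if i < enriched_terms:
            chosen = set(rng.choice(responders, size=n_planted, replace=False))
            others = np.array([g for g in genes if g not in chosen])
            chosen |= set(rng.choice(others, size=term_size - n_planted, replace=False))
            name, desc = f"term_enriched_{i + 1:02d}", "planted enriched term"
        else:
            chosen = set(rng.choice(genes, size=term_size, replace=False))
            name, desc = f"term_null_{i + 1:02d}", "uniform background term"
        terms[name] = chosen
        descriptions[name] = desc
    return PathwayAnnotation(terms=terms, descriptions=descriptions)


def simulate_qpcr(
    truth: pd.DataFrame,
    genes: Sequence[str],
    reference_gene: str,
    seed: int = 0,
    noise_sd: float = 0.1,
    n_technical: int = 3,
    ct_offset: float = 35.0,
    baseline_mean: float = 500.0,
) -> CtTable:
    """Ct table consistent with the planted fold changes.

    Ct = ct_offset - log2(expression) + Gaussian cycle noise, so on the
    noiseless table 2^-ddCt recovers the planted fold change exactly.  The
    reference gene must be a null gene of the truth table (planted fold
    change 1 in every contrast).
    """
    if reference_gene not in truth.index:
        raise ValueError(f"reference gene {reference_gene!r} not in truth table")
    if truth.at[reference_gene, "response_class"] != "null":
        raise ValueError("reference gene must have no planted effect (class null)")
    missing = set(genes) - set(truth.index)
    if missing:
        raise ValueError(f"genes not in truth table: {sorted(missing)}")
    panel = list(dict.fromkeys([*genes, reference_gene]))
    rng = np.random.default_rng(seed)
    rows = []
    for strain in STRAINS:
        for condition in CONDITIONS:
            col = "fc_stress" if condition == STRESS_CONDITION else "fc_control"
            for rep in (1, 2):
                sid = f"{strain}_{condition}_r{rep}"
                for gene in panel:
                    fc = 1.0 if strain == REFERENCE_STRAIN else float(truth.at[gene, col])
                    expr = baseline_mean * fc
                    ct_true = ct_offset - math.log2(expr)
                    for tech in range(1, n_technical + 1):
                        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                        rows.append((gene, sid, tech, ct_true + noise, strain, condition, rep))
    data = pd.DataFrame(
        rows,
        columns=["gene", "sample", "replicate", "ct", "strain", "condition", "bio_replicate"],
    )
    return CtTable(data=data, reference_gene=reference_gene)


@dataclass(frozen=True)
class FermentationParams:
    """Closed-form batch fermentation: logistic biomass, uptake proportional to it.

    Defaults emulate a vigorous pH 4.5 fermentation of a 130 g/L glucose
    medium: glucose exhausted within ~24 h and ~90% of the theoretical
    ethanol yield.  ``ethanol_yield_fraction`` scales the 0.511 g/g
    stoichiometric maximum; ``glycerol_fraction`` is g glycerol per g glucose
    consumed.
    """

    initial_glucose: float = 130.0
    duration_h: float = 72.0
    n_points: int = 13
    x0: float = 2e6  # initial cell density, cells/mL
    carrying_capacity: float = 2e8  # cells/mL
    growth_rate: float = 0.35  # 1/h
    uptake_per_cell: float = 7.5e-8  # g glucose /(cell·h) · mL
    ethanol_yield_fraction: float = 0.90
    glycerol_fraction: float = 0.03
    noise_sd_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_glucose <= 0:
            raise ConfigError("initial glucose must be > 0")
        if not 0 < self.ethanol_yield_fraction <= 1:
            raise ConfigError("ethanol_yield_fraction must be in (0, 1]")
        if not 0 <= self.glycerol_fraction <= 1:
            raise ConfigError("glycerol_fraction must be in [0, 1]")
        if self.duration_h <= 0 or self.n_points < 2:
            raise ConfigError("time grid must span > 0 h with >= 2 points")
        if self.x0 <= 0 or self.carrying_capacity < self.x0 or self.growth_rate < 0:
            raise ConfigError("invalid biomass parameters")
        if self.uptake_per_cell < 0:
            raise ConfigError("uptake_per_cell must be >= 0")


def simulate_fermentation(
    params: FermentationParams = FermentationParams(),
    seed: int = 0,
    strain: str = "KF-7",
    condition: str = "pH4.5",
) -> FermentationTimecourse:
    """Monotone glucose/ethanol/glycerol/biomass curves from the closed-form model.

    Biomass follows the logistic solution; cumulative glucose uptake is
    ``uptake_per_cell`` times the integrated biomass (capped at the initial
    glucose); ethanol equals ``ethanol_yield_fraction x 0.511 x consumed`` at
    every time point and glycerol is ``glycerol_fraction x consumed``.
    Optional measurement noise is re-monotonized so the invariants hold.
    """
    p = params
    t = np.linspace(0.0, p.duration_h, p.n_points)
    K, x0, r = p.carrying_capacity, p.x0, p.growth_rate
    if r > 0:
        ert = np.exp(r * t)
        cells = K * x0 * ert / (K + x0 * (ert - 1.0))
        integral = (K / r) * np.log(1.0 + x0 * (ert - 1.0) / K)  # ∫X dτ, cells·h/mL
    else:
        cells = np.full_like(t, x0)
        integral = x0 * t
    consumed = np.minimum(p.uptake_per_cell * integral, p.initial_glucose)
    glucose = p.initial_glucose - consumed
    ethanol = p.ethanol_yield_fraction * THEORETICAL_ETHANOL_YIELD * consumed
    glycerol = p.glycerol_fraction * consumed

    if p.noise_sd_frac > 0:
        rng = np.random.default_rng(seed)

        def jitter(x: np.ndarray) -> np.ndarray:
            return np.clip(x * (1.0 + rng.normal(0, p.noise_sd_frac, x.shape)), 0, None)

        cells, glucose, ethanol, glycerol = (
            jitter(x) for x in (cells, glucose, ethanol, glycerol)
        )
        # pin the known initial state, then re-monotonize the jittered curves
        cells[0], glucose[0], ethanol[0], glycerol[0] = p.x0, p.initial_glucose, 0.0, 0.0
        cells = np.maximum.accumulate(cells)
        glucose = np.minimum.accumulate(glucose)
        ethanol = np.maximum.accumulate(ethanol)
        glycerol = np.maximum.accumulate(glycerol)

    data = pd.DataFrame(
        {
            "time_h": t,
            "cells_per_ml": cells,
            "glucose_gL": glucose,
            "ethanol_gL": ethanol,
            "glycerol_gL": glycerol,
        }
    )
    return FermentationTimecourse(data=data, strain=strain, condition=condition)
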
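"""End-to-end orchestration: simulate (or load) data, run every stage, write a report.

``run_pipeline`` chains the stages — expression matrix, contrasts, DEG
calls, response classification, cross-strain Venn analysis, pathway
enrichment, qPCR concordance, and fermentation kinetics — and writes their
tables plus a machine-readable run manifest under the output directory.
Everything is deterministic given the configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .expression import (
    CONTROL_CONDITION,
    MUTANT_STRAINS,
    STRESS_CONDITION,
    ExpressionMatrix,
    build_contrasts,
    read_matrix,
)
from .enrichment import enrich, read_gmt, results_frame
from .fermentation import kinetics_summary, read_timecourse
from .qpcr import concordance, ddct_fold_change, read_ct_table
from .response import (
    DIRECTIONS,
    call_degs,
    classify_response,
    summarize_counts,
    venn_analysis,
)
from .simulate import (
    FermentationParams,
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_fermentation,
    simulate_qpcr,
)

log = logging.getLogger("lowph")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seed for one pipeline run.

    In simulate mode (``simulate=True``) all inputs are generated; otherwise
    the path fields must point at existing files.  Thresholds default to the
    study's printed values.
    """

    out_dir: str = "results"
    simulate: bool = True
    seed: int = 0
    # input paths (ignored in simulate mode)
    matrix_path: str | None = None
    sample_sheet_path: str | None = None
    gmt_path: str | None = None
    ct_path: str | None = None
    timecourse_paths: Mapping[str, str] = field(default_factory=dict)
    # thresholds
    theta_up: float = 2.0
    theta_down: float = 0.5
    rho_up: float = 1.5
    rho_down: float = 0.67
    alpha: float = 0.05
    min_er: float = 0.2
    rate_interval: tuple[float, float] = (0.0, 24.0)
    # simulation knobs
    sim: SimulationConfig | None = None
    qpcr_panel_size: int = 6

    def __post_init__(self) -> None:
        if not (self.theta_up > 1.0 > self.theta_down > 0.0):
            raise ValueError("need theta_up > 1 > theta_down > 0")
        if self.rho_up <= 0 or self.rho_down <= 0:
            raise ValueError("ratio thresholds must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimulationConfig(**sim)
        return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle; returns the in-memory report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {}

    # --- stage: inputs -----------------------------------------------------
    try:
        if config.simulate:
            sim = config.sim or SimulationConfig(seed=config.seed)
            matrix, truth = simulate_expression(sim)
            truth.to_csv(out / "truth_table.tsv", sep="\t")
            matrix.write(out / "expression.tsv", out / "sample_sheet.tsv")
            annotation = simulate_annotation(truth, seed=sim.seed + 1)
            annotation.write_gmt(out / "annotation.gmt")
            null_genes = truth.index[truth["response_class"] == "null"]
            reference_gene = null_genes[-1]
            # spread the validation panel across planted classes and directions
            # so its fold changes span the dynamic range
            planted = truth[truth["direction"] != "none"]
            per_group = max(1, config.qpcr_panel_size // 6)
            panel = list(
                planted.groupby(["response_class", "direction"], observed=True)
                .head(per_group)
                .index[: config.qpcr_panel_size]
            )
            ct = simulate_qpcr(truth, panel, reference_gene, seed=sim.seed + 2)
            ct.write(out / "qpcr_ct.tsv")
            timecourses = {
                "KF-7_pH4.5": simulate_fermentation(
                    FermentationParams(), seed=sim.seed + 3, strain="KF-7", condition="pH4.5"
                )
            }
        else:
            matrix = read_matrix(config.matrix_path, config.sample_sheet_path)
            truth = None
            annotation = read_gmt(config.gmt_path) if config.gmt_path else None
            ct = read_ct_table(config.ct_path) if config.ct_path else None
            panel = None
            timecourses = {
                label: read_timecourse(p, *label.split("_", 1))
                for label, p in config.timecourse_paths.items()
            }
        log.info("inputs: %d genes x %d samples", *matrix.values.shape)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'inputs' failed: {e}") from e

    # --- stage: contrasts + DEG calling + response filter ------------------
    try:
        contrasts = build_contrasts(matrix)
        response_sets = {}
        for strain, contrast in contrasts.items():
            contrast.write(out / f"contrast_{strain}.tsv")
            calls_s = call_degs(contrast, "stress", config.theta_up, config.theta_down)
            calls_c = call_degs(contrast, "control", config.theta_up, config.theta_down)
            rs = classify_response(calls_s, calls_c, contrast, config.rho_up, config.rho_down)
            rs.write(out / f"response_{strain}.tsv")
            response_sets[strain] = rs
            for d in DIRECTIONS:
                log.info(
                    "%s %s: %d stress DEGs -> %d unique + %d amplified + %d flat",
                    strain, d,
                    len(rs.table[rs.table["direction"] == d]),
                    len(rs.genes("unique_stress", d)),
                    len(rs.genes("shared_amplified", d)),
                    len(rs.genes("shared_flat", d)),
                )
        counts = summarize_counts(response_sets)
        counts.to_csv(out / "deg_counts.tsv", sep="\t", index=False)
        report["deg_counts"] = counts
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'deg_response' failed: {e}") from e

    # --- stage: cross-strain Venn analysis ---------------------------------
    try:
        venns = {}
        for d in DIRECTIONS:
            sets = {s: rs.selected(d) for s, rs in response_sets.items()}
            summary = venn_analysis(sets, direction=d)
            summary.write(out / f"venn_{d}.tsv")
            venns[d] = summary
        report["venn"] = venns
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'venn' failed: {e}") from e

    # --- stage: enrichment --------------------------------------------------
    try:
        enrichment_tables = {}
        if annotation is not None:
            for strain, rs in response_sets.items():
                res = enrich(rs.selected(), annotation, config.alpha, config.min_er)
                frame = results_frame(res)
                frame.to_csv(out / f"enrichment_{strain}.tsv", sep="\t", index=False)
                enrichment_tables[strain] = frame
        report["enrichment"] = enrichment_tables
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'enrichment' failed: {e}") from e

    # --- stage: qPCR concordance -------------------------------------------
    try:
        if ct is not None:
            strain = MUTANT_STRAINS[0]
            qpcr_fc, array_fc = {}, {}
            genes = panel if panel is not None else sorted(
                set(ct.data["gene"]) - {ct.reference_gene}
            )
            for gene in genes:
                qpcr_fc[gene] = ddct_fold_change(
                    ct, gene,
                    [f"{strain}_{STRESS_CONDITION}_r{r}" for r in (1, 2)],
                    [f"KF-7_{STRESS_CONDITION}_r{r}" for r in (1, 2)],
                )
                array_fc[gene] = float(contrasts[strain].table.at[gene, "fc_stress"])
            conc = concordance(qpcr_fc, array_fc)
            conc.per_gene.to_csv(out / "qpcr_concordance.tsv", sep="\t")
            (out / "qpcr_concordance.json").write_text(json.dumps(conc.to_dict(), indent=2))
            report["qpcr_concordance"] = conc
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'qpcr' failed: {e}") from e

    # --- stage: fermentation kinetics ---------------------------------------
    try:
        summaries = []
        for label, tc in timecourses.items():
            ks = kinetics_summary(tc, *config.rate_interval)
            summaries.append(ks.to_dict())
        if summaries:
            pd.DataFrame(summaries).to_csv(out / "kinetics_summary.tsv", sep="\t", index=False)
        report["kinetics"] = summaries
    except Exception as e:  # noqa: BLE001
        raise StageError(f"stage 'fermentation' failed: {e}") from e

    # --- manifest ------------------------------------------------------------
    manifest = {
        "lowph_version": __version__,
        "seed": config.seed,
        "simulate": config.simulate,
        "thresholds": {
            "theta_up": config.theta_up,
            "theta_down": config.theta_down,
            "rho_up": config.rho_up,
            "rho_down": config.rho_down,
            "alpha": config.alpha,
            "min_er": config.min_er,
        },
        "rate_interval_h": list(config.rate_interval),
    }
    if config.simulate:
        sim = config.sim or SimulationConfig(seed=config.seed)
        manifest["simulation"] = {
            k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(sim).items()
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report["manifest"] = manifest
    if config.simulate:
        report["truth"] = truth
        report["response_sets"] = response_sets
    else:
        report["response_sets"] = response_sets
    return report
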
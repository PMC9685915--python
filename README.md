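# lowph

Condition-specific differential-expression and fermentation-kinetics
analysis of low-pH-tolerant *Saccharomyces cerevisiae* strains.

Industrial ethanol fermentations are run acidic to suppress contaminants,
which pushes yeast toward its tolerance limits. This package re-implements,
as a tested pipeline, the transcriptome comparison of three acid-tolerant
strains (haploids B3 and C3, and their diploid BC3) against their parent
KF-7 at pH 2.5 (stress) and pH 4.5 (control), plus the supporting qPCR and
batch-fermentation analyses. It is aimed at anyone who wants to re-run,
audit or adapt that style of fold-change analysis — including directly on
the deposited microarray matrix (GEO accession GSE210964).

## The method in brief

For each mutant strain *m* and pH condition *c*, with replicate-averaged
intensities on the linear scale,

    FC_c(g) = mean_m,c(g) / mean_KF-7,c(g)

and a gene is a DEG when FC >= 2 (up) or FC <= 0.5 (down). Per direction,
each pH 2.5 DEG is then classified by the acid-specificity filter with
R = FC_pH2.5 / FC_pH4.5:

| class            | rule                                               | kept? |
|------------------|----------------------------------------------------|-------|
| unique_stress    | not a same-direction DEG at pH 4.5                 | yes   |
| shared_amplified | DEG at both pH; R > 1.5 (up) or R < 0.67 (down)    | yes   |
| shared_flat      | DEG at both pH, similar magnitude                  | no    |

Selected sets (unique ∪ amplified) are intersected across strains, and
pathway over-representation uses the upper-tail hypergeometric P with the
dual rule P <= 0.05 and enrichment ratio k/K >= 0.2 (no multiple-testing
correction, matching the original rule). qPCR fold changes use 2^−ΔΔCT
normalized to ACT1; fermentation time courses are summarized by 0–24 h
volumetric rates and end-point yields, with ethanol yield expressed as a
percentage of the 0.511 g/g stoichiometric maximum. A synthetic-data
generator plants all four response classes, enriched pathway terms,
consistent Ct values and monotone fermentation curves, so the whole pipeline
is testable against known ground truth. Details and design rationale:
[docs/methods.md](docs/methods.md).

## Worked example

The analysis is organized as numbered drivers under `analysis/` that write
their tables under `results/`:

```sh
python analysis/01_simulate.py --seed 0     # synthetic inputs + truth table
python analysis/02_differential_expression.py
python analysis/03_response_filter_venn.py
python analysis/04_pathway_enrichment.py
python analysis/05_qpcr_concordance.py
python analysis/06_fermentation_kinetics.py
```

Driver 02 reports the DEG totals per contrast, e.g.

```
B3 vs KF-7 at pH2.5: 200 DEGs (100 up, 100 down)
B3 vs KF-7 at pH4.5: 98 DEGs (50 up, 48 down)
```

— the 200 pH 2.5 DEGs are exactly the planted responders. Driver 03 then
applies the acid-specificity filter:

```
strain direction  stress_degs  unique_stress  shared_amplified  shared_flat  selected
    B3        up          100             50                26           24        76
    B3      down          100             52                23           25        75
...
planted-label recovery (B3 contrast): 95.5% of 200 planted genes
```

so at the default noise level (CV 0.1) about 95% of planted class labels are
recovered; the few misses are shared genes whose fold-change ratio crossed
the 1.5 boundary under noise. Driver 04 flags exactly the five planted
pathway terms for every strain (top term: k=12 of K=20, ER 0.60,
P = 4.0e-05) and none of the 25 null terms; driver 05 reports perfect sign
agreement and rank correlation between 2^−ΔΔCT and array fold changes on the
six-gene panel; driver 06 prints the kinetics table, where at pH 2.5 the
haploids consume glucose at ~3.1 g/(L·h) against ~1.9 for KF-7, mirroring
the strains' tolerance ranking.

The same stages run as one call via `lowph.run_pipeline(PipelineConfig(...))`,
and `lowph.geo.fetch_accession` loads a cached GEO series matrix into the
identical entry point for reanalysis of deposited data.

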
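# Methods

`lowph` analyses how low-pH-tolerant *Saccharomyces cerevisiae* strains (B3,
C3 and the diploid BC3) rewire transcription relative to their parent KF-7
under strong acid stress (pH 2.5) versus a control pH (4.5), and how the
strains compare as ethanol fermenters. The pipeline is a faithful, tested
re-implementation of a fold-change-based microarray analysis; all of its
stages run on synthetic data with planted ground truth, so every rule can be
verified end to end without the original chips.

## Differential expression and the acid-specific filter

The design is 4 strains x 2 pH x 2 biological replicates (16 arrays).
Replicates are averaged arithmetically on the linear intensity scale, and a
per-gene fold change FC = mean(mutant) / mean(KF-7) is computed for each
mutant at each pH. A gene is a DEG when FC >= 2 (up) or FC <= 0.5 (down);
the thresholds are inclusive, taken literally from the rule they implement.
Genes with a zero reference mean have no defined ratio; they are excluded
from calling and surfaced in a QC log rather than silently dropped.

The analysis is interested in the *acid-specific* response, not the general
stress response. Per direction stratum (up or down), each pH 2.5 DEG is
classified as:

* **unique_stress** — not a same-direction DEG at pH 4.5;
* **shared_amplified** — a DEG at both pH levels with ratio
  R = FC(pH2.5)/FC(pH4.5) > 1.5 (up) or < 0.67 (down);
* **shared_flat** — a DEG at both pH levels responding similarly at both
  (excluded from downstream analysis).

The "selected" set is unique_stress ∪ shared_amplified. Ratio thresholds are
strict and applied to raw fold changes (the ratio of the two FCs as printed,
not of their logarithms). Genes that are DEGs in *opposite* directions at
the two pH levels are not same-direction shared, so they land in
unique_stress for their stress-condition direction; because the original
rule is silent on this case, such genes are additionally logged
(`ResponseSet.direction_flips`) rather than asserted as intended behaviour.
Comparisons that land exactly on a threshold use a relative tolerance of
1e-9 so floating-point representation cannot flip a boundary call.

Selected sets are intersected across B3/C3/BC3 per direction
(`venn_analysis`), with exact exclusive-region memberships emitted; counts
are checked in tests against a brute-force membership scan.

## Pathway enrichment

For a term with K of the N annotated genes and k of the n selected DEGs, the
P value is the upper tail P(X >= k) of Hypergeometric(N, K, n) (computed via
`scipy.stats.hypergeom.sf`) and the enrichment ratio is ER = k/K. A term is
significant iff P <= 0.05 **and** ER >= 0.2 (both inclusive); no
multiple-testing correction enters the call, mirroring the raw-P rule this
reproduces, though a Benjamini–Hochberg q-value column is emitted for
information. The default universe is all annotated genes; an explicit
background (e.g. all array genes) can be passed instead, and whether term
size K counts all annotated genes or only those in the background is an
option (`restrict_terms_to_background`), since either reading of
"total genes involved in each term" is defensible.

## qPCR validation

Ct tables are normalized within sample to the reference gene ACT1 after
averaging technical replicates on the Ct scale: dCt = Ct_target − Ct_ref.
The control group is summarized by its mean dCt; each treatment biological
replicate yields 2^−(dCt_i − mean dCt_control), and the reported fold change
is the mean of those per-replicate values. Plate-wide Ct offsets cancel in
dCt and the reference gene's fold change is identically 1 (both are tested
as invariants). Concordance with array fold changes is reported as the
log2-scale sign-agreement fraction and a Spearman rank correlation;
concordance is reporting-only, with no pass/fail gate, because agreement
between the platforms is a qualitative check. Primer-efficiency correction
is out of scope — the plain 2^−ddCt estimator is the contract.

## Fermentation kinetics

Time courses (time, cell density, glucose, ethanol, glycerol) are summarized
by interval volumetric rates |C(t1) − C(t0)|/(t1 − t0) with linear
interpolation (default window 0–24 h), ethanol yield as a percentage of the
stoichiometric maximum 0.511 g ethanol per g glucose, glycerol yield in g/g,
and residual glucose. Glucose consumed is measured from the observed initial
concentration, not a nominal recipe. Yields are scale-invariant; a carbon
balance (product carbon <= consumed substrate carbon) is reported as a
sanity flag, never enforced, since measured curves can violate it within
noise. Mechanistic growth models (Monod, Luedeking–Piret) are deliberately
not fitted.

## The synthetic-data generator

`simulate_expression` plants, among `n_genes = 1000` genes, 100
unique-at-pH2.5 responders (FC pair 4.0 / 1.0), 50 shared-amplified
(5.0 / 2.5, ratio 2.0) and 50 shared-flat (3.0 / 2.5, ratio 1.2), each class
split evenly between up- and down-regulation via reciprocal pairs (the ratio
thresholds are mutually reciprocal, 0.67 ≈ 1/1.5, so reciprocals stay in
class). The pairs keep a clear margin from every decision boundary — a
planted value sitting exactly on a threshold would make its class unstable
under noise by construction. Replicate noise is multiplicative log-normal
with unit mean and CV 0.1, the conventional model for linear-scale array
intensities; KF-7 sits at a flat baseline of 500 intensity units, and the
matrix is emitted on the linear scale (recorded in the sample-sheet
convention). The truth table is per-gene, so all three mutant contrasts
carry the same planted effects; cross-strain Venn structure in simulations
is therefore degenerate (near-total triple overlap), and the set analysis is
instead validated on random sets against a brute-force oracle.

`simulate_annotation` builds GMT terms of 20 genes; enriched terms draw half
their members from planted responders (guaranteeing k/K >= 0.2 by
construction), null terms sample uniformly. `simulate_qpcr` writes
Ct = 35 − log2(expression) + N(0, 0.1 cycles) over 3 technical replicates,
which makes 2^−ddCt exact in the noiseless limit. `simulate_fermentation`
uses logistic biomass with uptake proportional to integrated biomass (closed
form), ethanol = yield_fraction x 0.511 x consumed and glycerol a fixed
fraction of consumed at every time point; defaults emulate a vigorous
control-pH batch (130 g/L glucose gone within ~24 h, 90% of theoretical
yield). Optional measurement jitter is re-monotonized so the curve
invariants always hold. All four generators are deterministic given seed and
config, to the byte in their serialized outputs.

What the generator does **not** emulate: probe-level effects and
normalization artifacts, per-strain differences in the transcriptional
response (the truth table is shared), correlated noise across genes, qPCR
primer efficiencies, and the late-phase stalling of inhibited fermentations
(the logistic model keeps consuming; only the summary-statistic contracts
are modeled). Passing tests therefore demonstrate the correctness of the
rules and estimators, not robustness to those real-data complications.

## Calibration and problem sizes

A one-off Monte-Carlo calibration (10 seeds x 3 contrasts, default
configuration) measured planted-label recovery at noise CV 0.1: minimum
0.955, mean 0.975. The regression bound frozen into the tests is 0.95.
Noise-free simulations must be recovered with 100% class accuracy.

Test problem sizes are chosen for exactness and speed: hypergeometric
P values are checked against exhaustive draw enumeration for every
(N <= 12, K, n, k) and pmf normalization for N <= 15; the response filter is
checked against a literal rule-by-rule scan on 1000 random tables of up to
50 genes; null enrichment calibration uses 200 annotation seeds (the
empirical false-positive rate at P <= 0.05 must stay within binomial
tolerance of 5% — hypergeometric discreteness makes it conservative in
practice). The whole suite runs in well under a minute.

## Reproducing from the deposited accession

`lowph.geo.fetch_accession` ingests a GEO series matrix (cache-first; the
deposited accession for this design is GSE210964) and maps GSM samples to
the strain x pH x replicate design through a user-edited TSV template —
sample titles are not guessed. Whether deposited probe-set rows correspond
one-to-one to genes is left to the caller: rows are counted as given, and
probe-to-gene collapsing is intentionally not performed, so counts derived
from a deposited matrix may differ from published per-gene counts.
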
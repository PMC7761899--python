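# Methods

This note documents the models implemented in `mammosig`, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the numerical conventions that make results deterministic.

## Synthetic single-cell data

`synthetic.simulate_sc` draws a genes × cells UMI count matrix from a
negative binomial parameterized by mean μ and a single shared dispersion
α (variance μ + αμ²). Per-gene baseline expression weights are
log-normal (σ = 1) across genes; a cell of type *t* has mean
μ<sub>ij</sub> = L<sub>j</sub> · w<sub>it</sub> / Σ<sub>i</sub> w<sub>it</sub>,
where the library size L<sub>j</sub> is log-normal. Each type owns a
disjoint block of marker genes whose weights are multiplied by
exp(marker_logfc) in that type only. A contiguous block of genes named
with the `MT-` prefix is sized to `frac_mito_genes` of the gene universe
and its weights rescaled to carry that same fraction of baseline
expression, so the expected per-cell mitochondrial count fraction equals
the configured value. "Aggregate" cells — sums of two sampled cells —
stand in for cell aggregates/doublets; they exist only to give the
detected-gene QC rule something to remove, not as a calibrated doublet
model.

Defaults mirror the tissue the pipeline targets: 3193 cells in 10 types
at the observed type proportions (24.1% … 1.0%), 20,345 genes, 100
markers per type, dispersion 0.3 and median library ~5000 UMIs (typical
droplet-data values). The analysis drivers and the test suite run a
scaled-down rendition — 1300 cells × 1500 genes, 10 equal types, 50
markers per type at 8-fold — chosen so each study keeps ≥ 100 cells per
type while running in seconds. One consequence of the smaller gene
universe is that gene detection saturates (~1060 of 1500 genes detected
per cell), so the drivers scale the detected-gene QC cap to 1250; the
library default stays 6500, the value appropriate to a ~20k-gene
universe.

Not emulated: batch effects, ambient RNA, cell-cycle structure,
copy-number variation, read-level noise (the generator starts at UMI
counts). Passing recovery tests therefore show the pipeline's
correctness under a clean mixture model, not robustness to those
artifacts.

`synthetic.simulate_bulk` builds each tumor's log2 expression as
purity · profile(type) + (1 − purity) · mean profile + N(0, noise_sd²),
with the generating type drawn uniformly. Survival times are
exponential with rate baseline_hazard × hazard_multipliers[type] —
exponential so the true hazard ratio between types is the constant
multiplier ratio, giving closed-form recovery targets. Censoring is an
independent exponential competing time whose rate is calibrated so the
expected censored fraction equals `censor_rate`; being independent of
the event process it does not bias the Kaplan–Meier or hazard-ratio
estimators.

## Single-cell pipeline

- **QC**: cells are kept iff detected genes ≤ max_genes (default 6500)
  AND mitochondrial fraction ≤ max_mito (default 0.1). Both thresholds
  are read as strict removal rules — boundary cells stay. Mitochondrial
  genes are recognized by a configurable symbol prefix, default `MT-`.
- **Normalization**: x = ln(1 + 10⁴ c/C), natural log with pseudocount
  1 (the standard convention when only "log-transformed" is specified).
  Zero counts map to exactly zero and expm1 recovers the count fraction
  to 1e-10.
- **Highly variable genes**: dispersion (variance/mean of de-logged
  expression) z-scored within 20 mean-expression bins, top 2000 by
  default (750 in the scaled studies — half the gene universe).
- **PCA**: genes centered and unit-scaled, exact SVD, 10 components.
  Each component's sign is fixed so its largest-magnitude loading is
  positive, making the embedding fully deterministic.
- **Clustering**: 20-NN graph in PC space (each cell a neighbor of
  itself), edges reweighted by Jaccard overlap of neighbor sets and
  pruned below 1/15, then Leiden with the RB-configuration modularity
  objective at resolution 0.8. The paper trail for these defaults is
  thin in any source; they are the widely used Jaccard-SNN conventions
  and are exposed as configuration, not constants. Labels are
  renumbered by decreasing cluster size; equal-sized clusters keep
  their original community order and a warning is logged.

## Marker signatures

One-vs-rest two-sided Wilcoxon rank-sum per gene. scipy's `auto` method
is used: the exact null distribution for small tie-free groups, the
tie-corrected, continuity-corrected normal approximation otherwise.
(The plain normal approximation deviates from exact enumeration by up
to ~0.04 at group sizes of 3; the exact path removes that error where
it matters, and at realistic cluster sizes the asymptotic regime
applies anyway.) Fold change is
ln((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1)). Multiple testing is
Bonferroni across genes within each cluster contrast; a signature keeps
the ≤ 100 significant (adj. p < 0.05) positive-fold genes with the
largest fold change, ties broken by smaller p then symbol, so output is
deterministic. No minimum-detection prefilter is applied by default and
no fold-change floor beyond positivity. Clusters with no qualifying
marker yield an empty set plus a warning rather than vanishing.

## GSVA

Implemented from scratch in `gsva.py` (see the module docstring for the
three-step definition). Conventions:

- Gaussian kernel with bandwidth h = s/4 (sample SD, ddof = 1); the
  input must be on a continuous (log) scale — there is no
  count-kernel variant because the classification input is declared
  log2.
- A constant gene (s = 0) carries no ranking information: z = 0.5
  everywhere, logged, rather than an error; a fully constant matrix is
  an error.
- Ties in z are broken by input gene order (stable sort).
- Both score modes are implemented: `max_diff` (max ν + min ν, the
  default used by the classification pipeline) and `max_dev` (ν at the
  largest |ν|). In `max_dev`, when the positive peak and negative
  trough tie in magnitude to rounding error, the reported sign is
  summation-order dependent; the tests account for this.
- A set weight denominator of zero (every member gene exactly at rank
  p/2) falls back to uniform hit steps.
- Signature genes missing from the expression matrix are intersected
  out; the per-set missing counts are reported because symbol matching
  between independently produced gene lists is never guaranteed. A set
  with no genes left, or covering the whole matrix, is an error naming
  the set.
- The gene universe p is whatever the input matrix contains; since ES
  depends on p, the score matrix carries the per-set effective sizes.
- Scores are computed per sample and bounded in [−1, 1]; this is
  fuzz-tested and checked against a naive cumulative-sum oracle.

## Tumor classification

Argmax over each tumor's score column; exact ties are flagged and
broken toward the lowest cluster label. Receptor subtype mapping: ER+
HER2− and ER+HER2+ (luminal A/B), ER−HER2+, and TNBC (ER−PR−HER2−).
PR enters only the TNBC rule; combinations outside the four groups
(including any unknown status) map to `unknown`, which is excluded from
subtype cross-tabs but retained in all-tumor coverage. Coverage reports
counts and one-decimal percentages per cluster plus a named-subset
aggregate (sum of member percentages alongside the raw count fraction).

## Expression summaries

Per-cluster mean/SD/median and detection fraction for a chosen gene,
with a >0.1 shading flag on the cluster mean. The summary scale is
declared configuration: log-normalized values by default, or values
rescaled by the gene's all-cell maximum (`relmax`) for cross-gene
comparability — the published table's exact normalization is not
derivable from its description, so fold ratios between printed table
values are computed from those values directly (`reported.py`), not
from a recomputed transform. Fold ratios use half-up rounding to one
decimal. The expressed-gene partition marks a gene expressed in a
cluster iff nonzero in ≥ min_frac (default 0.1) of its cells, and emits
all 2^m − 1 Venn regions, which are pairwise disjoint and cover the
detected universe.

## Survival statistics

Kaplan–Meier with the standard convention that subjects censored at an
event time count as at risk at that time. The log-rank test is the
score form (O−E)ᵀV⁻¹(O−E) with the hypergeometric covariance summed
over event times, df = G − 1 (pseudo-inverse on the first G − 1
groups); the trend variant is (Σc(O−E))²/(cᵀVc) with df = 1, scores
defaulting to equally spaced cluster ranks. With these forms the
two-group statistic equals the squared (0,1)-scores trend statistic
exactly, and the implementation is cross-checked against lifelines.
Hazard ratios are Mantel–Haenszel, HR = (O₁/E₁)/(O₂/E₂), with 95% CI
exp(ln HR ± 1.96·√(1/E₁ + 1/E₂)) — chosen over Cox regression because
it needs no iterative fit and matches the reporting convention of
common survival-plot software; note the estimator attenuates toward 1
for large effects (a true 3× ratio is typically estimated around
2.4–2.8 at n = 400 with 10% censoring, within the documented recovery
band of [2.2, 4.0]). Zero total events yields p = 1 with a warning
rather than an error.

## Study sizes used by tests and the acceptance script

- Recovery study: 1300 cells × 1500 genes, 10 types, 50 markers at
  8-fold; 300 bulk tumors at purity 0.8, noise SD 0.8 (log2).
- Log-rank calibration: 500 replicates of 60 tumors under equal
  hazards, nominal α = 0.05.
- Hazard-ratio recovery: 400 tumors, true ratio 3, 10% censoring.

These sizes are the package's own defaults for its validation studies;
all randomness flows through one seeded generator per call, and
identical seeds reproduce outputs bit for bit.

## Known limitations

- The mixture model behind the bulk simulation is linear on the log2
  scale — a deliberate simplification; real bulk deconvolution mixes on
  the linear scale.
- The Jaccard-SNN + Leiden stage recovers well-separated types; the
  resolution parameter, as in any modularity method, must be chosen for
  the granularity of interest and is not estimated from data.
- Published-table arithmetic in `reported.py` validates the package's
  ratio/percentage/HR routines against printed values; the underlying
  patient-level data are not redistributable, so those quantities are
  recomputed from the printed tables, not from raw data.
- No batch integration, pseudotime, intrinsic-subtype calling, or
  multivariable (Cox) survival models.
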
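# Methods

## Model

A bulk sample's expression over a set of signature genes is assumed to be
a non-negative linear combination of pure cell-type expression profiles,

    G = β₁·P₁ + … + β_c·P_c,   βᵢ ≥ 0,

with both *G* and each *Pᵢ* normalized to a library size of 10⁶ over the
genes they share. Under that common scaling the coefficients are
comparable across fits; each fit's coefficients are renormalized to sum
to one before any averaging, so the ensemble combination
βᵢ = Σⱼ βᵢʲ·wʲ (a convex combination of per-set proportion vectors) is
itself a proportion vector. The model ignores differences in cell size
and RNA content per cell: estimated fractions are fractions of RNA mass,
not of cell counts.

## Pipeline stages and defaults

**Pure pseudo-bulks.** Per dataset and cell type, counts are summed over
a uniform random subset of at least 50% of the type's cells; if the
subset's total is below the 2·10⁶-count floor, cells are added at random
until the floor is met or all cells are used (the replicate is then
flagged). The two constraints interact in no prescribed order, so the
grow-until-met rule is this package's choice. Datasets marked
`bulk_as_pseudobulk` (bulk RNA-seq of purified cells, e.g. isolated
muscle fibers) skip sampling: each column is one replicate. Full-length
protocol datasets are converted to TPM (counts over transcript length)
before normalization; 3′ UMI datasets use UMI counts directly. Default
replicates per type: 4.

**Low-expression filter.** After 1 M normalization, a gene is "low" in a
cell type when more than 20% of that type's pseudo-bulks carry fewer than
4 counts. The default drops a gene only when it is low in *every* type
(preserving markers of rare types, which the DE stage needs); a strict
mode drops on any type. Filtering after normalization follows the order
of the pipeline's narrative description; both the mode and the ordering
are configurable because the prose rule is ambiguous on both points.

**Batch correction.** Parametric empirical-Bayes ComBat (location/scale
standardization per gene, shrinkage of per-batch means and variances
toward across-gene priors, back-transformation), implemented in-package
and operating on log₂(CPM + 1); corrected linear values are recovered by
back-transform with flooring at 0. Strategy selection: the mean pairwise
Jaccard similarity of the datasets' cell-type sets is compared with a
0.5 threshold — below it each cell type is corrected independently
(batch = dataset), above it a single correction runs with cell type as a
protected covariate. Protecting the covariate in the all-in-one mode is
a design choice: without it, correction across unbalanced datasets
demonstrably erodes true cell-type differences (asserted by test).
Degenerate cases: single batch → identity; singleton batches pass
through; zero-variance genes pass through; when a batch's within-batch
scale is not estimable (identical replicates), a location-only
adjustment is applied.

**Signature genes.** One-vs-rest DE per cell type on corrected pure
pseudo-bulks. Fold change: log₂ of the target type's mean over the
*average of the other types' per-type means* (pseudo-count 1), so a
large "rest" type cannot drown out small ones. Test: a negative-binomial
score statistic of target vs pooled rest under the pooled-mean null,
with tagwise method-of-moments dispersion shrunk toward the across-gene
median (prior weight 10); χ²₁ p-values, BH-adjusted within the contrast.
This engine is deliberately simple and deterministic; its contract is
calibration (false-positive rate at or below the nominal level under
permuted labels; planted-marker recovery ≥ 80% at default effect sizes),
both asserted by tests — not equivalence with any particular published
DE framework. Thresholds: log₂FC > 1, adjusted p < 0.05. A gene
significant for several types is assigned to the type with the largest
fold change (disjointness prevents one gene from inflating two
coefficients). Per-type lists are truncated to the smallest candidate
count, clamped into [100, 350] by default — the window observed for
real profile groups; scaled-down simulations must scale `min_genes`
with their planted marker count.

**Profile sets and training.** Candidate sets take one corrected pure
replicate per cell type over the union of profile genes (full Cartesian
enumeration when ≤ `max_sets` = 200, else uniform seeded sampling of
distinct combinations). Each candidate is scored by the mean composition
RMSE of single-set NNLS on mixed pseudo-bulks with known composition
(20 Dirichlet(1) mixtures per dataset by default); the top 50 survive,
then — when real bulk training samples exist — are re-scored and cut to
20. If the best score exceeds the 0.1 target, fresh candidates are drawn
with a derived seed and merged, up to 5 iterations. The two-step
structure, the RMSE criterion and the iteration cap are fixed; the k
values, target, and candidate-regeneration scheme are this package's
reconstruction and are recorded in every bundle's `config_snapshot`.

**Deconvolution.** Query and profiles are intersected on gene ids (fits
with < 50% profile-gene coverage are refused rather than silently
degraded), renormalized, and solved by NNLS per profile set. The
goodness-of-fit RMSE_f = √(mean over genes of squared residual) ranks the
sets; the best N = 5 enter the ensemble. Weights follow the published
absolute-deviation-from-mean form

    wʲ = |RMSE_fʲ − mean(RMSE_f)| / Σₖ |RMSE_fᵏ − mean(RMSE_f)|

with uniform weights when all deviations vanish (including N = 1). Note
this formula gives maximal weight to *both* extremes of the RMSE range
for N ≥ 3, which conflicts with the accompanying claim that the
lowest-RMSE set contributes most; both cannot hold simultaneously. The
default keeps the printed formula for fidelity; an `inverse_rmse` scheme
(wʲ ∝ 1/(RMSE_fʲ + ε)) that does guarantee the claimed monotonicity is
offered alongside. Query bulk samples are *not* batch-corrected against
the profiles — only the references are corrected.

**Coefficient significance and the undetermined fraction.** The
significance machinery is a reconstruction (only its existence is
prescribed): ordinary least squares is refit on the cell types with
strictly positive NNLS coefficients, each coefficient gets a two-sided
t-test against zero with df = genes − active types, boundary types get
p = 1, and per-type p-values are combined across the ensemble with the
same weights wʲ. The undetermined fraction is the summed proportion of
types whose combined p ≥ α (default 0.05); significant proportions plus
undetermined sum to 1.

**Stepwise refinement.** Bundles form a two-level hierarchy: the coarse
bundle always runs; a fine bundle runs only when its parent type's
significant coarse proportion reaches `refine_threshold` (default 0.2).
Fine proportions are reported both within the fine bundle and rescaled
by the parent fraction. Cycles are rejected.

## Synthetic data

The generator emulates exactly the structure the method assumes: a
log-normal per-gene baseline shared across datasets; disjoint planted
signature-gene blocks whose means are multiplied by 2^log2FC (default
2.5) in their type; per-(dataset, gene) log-normal multiplicative batch
effects (default σ = 0.3 on the natural-log scale); negative-binomial
counts with var = μ + φμ² (default φ = 0.3, shared across genes); per-cell
depths uniform in a configurable range; an optional presence mask for
non-identical repertoires (warning below 3 datasets per type, error in
strict mode); an optional gene-length bias emulating full-length
protocols. Mixtures draw a fixed number of cells per contributing type,
normalize each type's sum, and weight by the drawn composition, so the
recorded composition is exact in normalized-expression space.

It does **not** emulate doublets, ambient RNA, zero inflation beyond the
NB, annotation errors, cell-size/RNA-content differences, or
platform-specific gene dropout. Passing tests therefore demonstrate
correctness of the machinery and robustness to NB noise and
location/scale batch effects — not performance on real tissue, where
mislabeled reference cells and unmodeled covariance are the dominant
error sources.

## Numerical choices

- NNLS via active-set (`scipy.optimize.nnls`); solutions cross-checked
  in tests against an exhaustive 0.01-step simplex grid search.
- ComBat EB fixed point iterated to relative change < 1e-8 (max 2000
  iterations); verified against an independently coded scalar-loop
  reference at 1e-6.
- BH adjustment by the standard step-up construction; dispersion floor 0,
  cap 100.
- Profile-set sampling uses rejection of duplicate combinations, so set
  identity (not just count) is seed-reproducible.
- Bundle serialization writes 6-significant-digit decimal TSVs: one
  write-read round trip is lossless at that precision and every further
  round trip is exact.
- Ties: equal training scores rank by set id; equal fit RMSEs by set
  rank; equal fold changes assign a shared gene by lexicographic type
  order.
- Gene ids are upper-cased at read sites; duplicates collapse by
  summation. In-memory vectors are taken as-is.

## Problem sizes used in the shipped studies

The bundled simulation studies (acceptance script and end-to-end tests)
use 5 reference datasets × 9 (or 6) cell types, 2000 genes, 60 signature
genes per type, 200–400 cells per type at 2000–6000 counts per cell, 200
candidate sets, and 100 (or 30) query mixtures — sizes chosen so a
complete profile build plus deconvolution runs in minutes on one CPU
while every pipeline stage still operates in its intended regime.

## Known limitations

- RNA-mass proportions, not cell-count proportions.
- Performance depends on reference quality and labeling consistency;
  inconsistent annotations across references blur profiles (label
  transfer / re-annotation is out of scope).
- An unprofiled cell type in the query is largely *redistributed* to the
  most similar profiled types rather than surfacing as undetermined mass
  (typically 0–5%); the reliable symptom is a worsened goodness-of-fit
  RMSE and weaker p-values.
- Contributions below ~5% are frequently non-significant and land in the
  undetermined fraction.
- The per-cell-type correction mode can only align datasets within types
  they share; types present in a single dataset pass through uncorrected.
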
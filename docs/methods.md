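# Methods

`lrcrosstalk` implements a two-part analysis for B-cell precursor acute
lymphoblastic leukemia (BCP-ALL) transcriptomics: (1) inference of
tumor-associated ligand–receptor (L-R) crosstalk from single-cell
differential expression cross-validated by bulk-cohort co-expression, and
(2) a prognostic *LR score* built by a leave-10%-out LASSO-Cox stability
ensemble, dichotomized by a survival tree and evaluated with Kaplan–Meier,
log-rank and Cox statistics.  A linked synthetic-data generator supplies
single-cell, bulk, and survival inputs with known ground truth.

## Quality control and normalization

Cells are removed when they detect fewer than 500 genes, more than 5,000
genes (doublet proxy), or when mitochondrial counts (genes prefixed `MT-`)
exceed 10% of the cell's total counts.  Boundary semantics are strict:
exactly 500 detected genes, exactly 5,000, or a mitochondrial fraction of
exactly 0.10 are all kept.  The "10% mitochondrial" rule is computed on the
*count* fraction (the field convention); a `mito_basis="genes"` option
computes the detected-gene fraction instead.  Cells failing several rules
are attributed to the first failing rule in the order low_genes →
high_genes → high_mito (reporting only; retention is unaffected).

Downstream testing uses library-size log-normalization,
`log(1 + count / total × 10⁴)`, rather than a variance-stabilizing
regression: the hurdle test and the crosstalk logic depend only on
normalized expression, and the choice is recorded in the QC report metadata.

## Hurdle differential expression

For each gene in one cell type, tumor vs. normal is tested with a two-part
hurdle model:

* detection part — likelihood-ratio test of the detection indicator
  (expr > 0) on the group under a Bernoulli/logistic model (1 df);
* continuous part — likelihood-ratio test of the group effect on the
  normalized expression of detected cells under a Gaussian linear model
  (1 df, computed as n·log(RSS₀/RSS₁)).

The combined statistic is the sum of the two chi-squares with summed df;
degenerate parts (all/none detected; fewer than two detected cells in a
group) contribute 0 with 0 df, and a fully degenerate gene gets p = 1.
With a single binary covariate both parts have closed forms, so a whole
matrix is tested in a few vectorized passes.  No cellular-detection-rate
covariate is included (hooks exist in the interface).  Genes detected in
fewer than `min_cells = 10` cells are not tested.  Multiple testing is
controlled per cell type with Benjamini–Hochberg (statsmodels); genes with
adjusted p < 0.05 are called, split by the sign of the log2 fold change
(difference of group means of normalized values, rescaled to log2).

## Crosstalk networks

Candidate edges come from the intersection of significant DE gene lists with
a directed L-R pair table.  Autocrine candidates (B→B) require ligand and
receptor significant in B cells with *concordant* direction, which the pair
inherits; discordant pairs are excluded (a relaxation flag exists).
Paracrine candidates (B→myeloid and myeloid→B) require the ligand up in the
source type and the receptor up in the target type; down-regulated paracrine
pairs are not considered.

Each candidate is then validated in a bulk cohort: Spearman correlation
(mid-ranks, p from the t approximation with n−2 df) of ligand and receptor
across the selected samples, BH-adjusted across the candidates of the run.
An edge is kept when rho > 0.3 (strict) and adjusted p < 0.05 (strict).
Candidates missing from the bulk gene universe are dropped with a logged
count, not failed.  A pair may appear in several networks.  The bulk sample
subset used for the correlation is a parameter (`sample_subset`), applied
identically to all three networks.

## LASSO-Cox stability ensemble and LR score

The solver minimizes the Breslow negative log partial likelihood plus
λ·Σ|β| by cyclic coordinate descent on the IRLS quadratic approximation,
with covariates standardized internally and coefficients reported on the
original scale.  Backtracking protects against quadratic-model overshoot;
KKT residuals are checked at convergence (tolerance 1e−6; numerically-zero
coordinates below 1e−12 are snapped to exact zero).  λ_max — the max
absolute null-model gradient on the standardized scale — yields the exactly
zero solution.  λ is chosen per fit by k-fold (default 10) cross-validated
partial-likelihood deviance (Verweij–van Houwelingen) over a 30-point
log-spaced grid spanning two decades below λ_max, using the one-standard-
error parsimony rule (heaviest penalty within one SE of the deviance
minimum; the deviance-minimum rule is available as `rule="min"`).  The
parsimony rule matters for stability selection: because 90% subsamples
share almost all of the data, a noise covariate that correlates with the
outcome by dataset-level chance would be kept by the minimum-deviance rule
in nearly every replicate, defeating the retention filter.  CV path fits run at
loosened tolerances (they only rank λ values); reported fits are re-solved
tightly.  An optional numba kernel accelerates the inner loop; the pure
numpy path is the reference implementation.

The stability ensemble repeats, for each of 1,000 replicates (default), a
uniform 90% patient subsample without replacement, inner CV λ selection,
and a LASSO-Cox fit.  *Retention* of a gene is the number of replicates
with a nonzero coefficient; genes retained in ≥ 950 replicates (default)
enter the final model.  Final coefficients are means over **all**
replicates, zeros included (`average="selected"` averages over selecting
replicates only).  More than 5% failed replicates aborts the run.  All
randomness derives from a single seed via spawned substreams.

The LR score of a patient is Σ coefficient·expression over the model genes;
genes missing from the expression input contribute zero with a warning.
The packaged published model carries the 11 printed gene coefficients
verbatim (ITGB4 −0.263, SDC1 0.177, GPC2 −0.13, TLR6 −0.0838, CEACAM1
−0.0607, JAG1 0.058, NOTCH3 0.0501, LDLR −0.0469, ACVR2B −0.0511, SLIT2
−0.0191, TIE1 −0.00592).  The expression scale those coefficients apply to
is not standardized; apply-mode asks the caller to declare the scale and
records it in the output.

## Survival-tree dichotomization

`partition_cut` scans the midpoints of consecutive sorted unique scores
whose two groups each hold at least 10% of the cohort and picks the
cutpoint maximizing the log-rank chi-square — the single-split analog of a
recursive-partitioning survival tree.  Because the cutpoint is *selected*
to maximize the statistic, the naive p-value of the best split is strongly
anticonservative under the null (the maximally-selected-statistic problem);
a naive p < 0.05 pruning rule would "find" splits in roughly half of null
datasets.  The pruning decision therefore uses the Lausen–Schumacher
approximation for maximally selected rank statistics over the scanned
quantile window (ε = 0.1), with the naive p of the chosen split reported
alongside.  A non-significant adjusted p returns a null split.

## Survival statistics

Kaplan–Meier estimation, the two-group log-rank test and Cox
proportional-hazards fits are delegated to lifelines behind the module
surface.  Cox fits use Efron's tie approximation (the modern default; the
synthetic generator breaks ties with deterministic 1e−9 jitter, so a
dedicated tied fixture exercises the handling).  Hazard ratios are reported
with 1.96·SE Wald intervals and the model-level likelihood-ratio p.
Single-gene prognosis uses mean-expression dichotomization; expression
exactly at the mean goes to the high group.

## Synthetic data: what it emulates, what it does not

The generators provide the minimal structure the pipeline's assumptions
require — none of the distributional choices is claimed to be inferred from
real data:

* **Single-cell counts**: per-gene negative binomial with a single shared
  dispersion (0.5) and per-gene base means log-uniform on (0.1, 4); tumor
  condition multiplies the mean of planted (gene, cell type) entries by
  2^lfc.  Genes named in the DE plan draw base means from (2, 5) by default
  — ligands and receptors under study are expressed genes; planting strong
  fold changes on barely-detected genes would conflate effect size with
  detectability.  The default design mirrors the target study: 7 tumor and
  4 normal samples, with desk-scale cells per sample.  QC violators are
  planted explicitly (exactly min_genes−100 detected genes; max_genes+100
  detected genes; mitochondrial count fraction ≈ 0.30) and recorded.
* **Bulk expression**: log-normal marginals over a Gaussian copula; a
  planted Spearman rho is converted to the Gaussian correlation
  r = 2·sin(π·rho/6), so the rank correlation is exact in population under
  any monotone marginal transform.  Planted |rho| ≤ 0.99; genes sharing a
  correlation component must form a positive-definite system.  The default
  cohort is 300 samples — the scale at which a rho = 0.6 signal passes the
  filter with near-certainty and null pairs essentially never do.
* **Survival**: exponential proportional hazards, h₀·exp(Σβ_g z_g) with
  z_g the standardized bulk expression, baseline hazard 0.1 per year, and
  independent exponential censoring calibrated so a baseline subject is
  censored with probability `censor_rate` (default 0.2; `censor_rate=1`
  censors everyone at time 0).

Not emulated: batch effects, doublet transcriptome mixtures, ambient RNA,
molecular-subtype structure, non-proportional hazards, informative
censoring.  A green recovery test therefore establishes internal
correctness of the pipeline's statistics under its own assumptions, not
robustness to real-data artifacts.

One deliberate artifact of the stated world is worth noting: when planted
DE genes are a large fraction of the library, library-size normalization
induces small compensatory fold changes on null genes (composition effect).
Recovery tests therefore plant signals on a small fraction of a larger gene
panel, as real data would.

## Numerical choices and edge cases

* Gene symbols are canonicalized by upper-casing and stripping whitespace;
  duplicate rows collapse by sum (counts) or mean (continuous scales).
* BH adjustment and Spearman ranking delegate to statsmodels / scipy.
* Continuous-part RSS ratios are floored at 1e−12·RSS₀ to avoid infinities
  when detected values are nearly constant.
* The λ=0 solver is plain Newton-IRLS with backtracking; monotone
  likelihood (perfect separation) surfaces as a convergence error.
* `run_all` fans a single root seed into per-stage substreams; the run
  report contains no timestamps, so reruns are byte-identical.
* Validation applies the training-derived cutpoint by default; re-deriving
  the cutpoint on the validation cohort is available by flag.

## Known limitations

* The hurdle test pools cells across samples (no pseudobulk / random
  effects), so real-data inference would be anticonservative under strong
  sample-level correlation; the synthetic world has none.
* The Lausen–Schumacher adjustment is asymptotic and slightly conservative
  at small n; full recursive trees (more than one split) are out of scope.
* The published 11-gene coefficients are tied to an unknown expression
  scale; scores computed on other scales order patients sensibly only if
  the scale is a roughly linear transform of the original.
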
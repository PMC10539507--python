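# Methods

## Enrichment statistic

For one sample, genes are ordered by decreasing expression; ties are broken
by gene identifier so scores are identical across runs and platforms. The
gene at position *i* of *N* has rank magnitude *r* = *N* − *i* + 1. For a
set *S*, the hit ECDF at position *i* is the fraction of the set's total
weight `Σ_{j∈S} r_j^tau` accumulated by position *i*, and the miss ECDF is
the fraction of non-members passed. The enrichment score is the sum over
all *N* positions of (hit − miss) — the integrated ECDF difference, not the
maximum deviation, so the statistic rewards sets that sit coherently toward
one end of the ranking rather than a single early cluster. Internally the
sum collapses to a closed form (a hit at position *p* contributes to
exactly *r* = *N* − *p* + 1 positions), giving O(|S|) per set after one
ranking pass per sample; the tests check this against a brute-force oracle
that materializes both ECDFs position by position.

`tau` defaults to 0.25, the conventional single-sample choice; `tau = 0`
makes the score purely rank-based (invariant to any strictly increasing
transform of one sample's values, also property-tested). Scores are not
rescaled by their cross-sample range, because the pipeline quantile-
normalizes the activity matrix afterwards; callers wanting raw comparable
scores can skip normalization (`--no-qn`, `quantile_normalize_scores =
false`).

TF activity is the arithmetic mean of the TF's set scores. Quantile
normalization maps the value at within-column rank *k* to the mean of the
*k*-th order statistics across columns; ties within a column receive the
mean of the reference values their ranks span, which preserves
idempotence. Normalization is across sample columns (every sample ends
with the same score distribution), not across TF rows.

## Differential activity and selection

Group comparisons use the pooled-variance two-sample Student *t*
(Welch by flag), two-tailed, with BH step-up FDR; under the null the
per-feature p-values are uniform (KS-tested on 5,000 simulated features).
Promoting = mean activity higher in the high-invasion group. The
"highly expressed TF" filter keeps candidates whose own-gene mean
expression reaches a quantile (default the median) of the resolvable
candidates' means; it is a surrogate for an unstated qualitative rule, is
logged with its realized cutoff, and can be disabled with quantile 0. TFs
whose identifier matches no gene symbol skip the filter and are flagged
rather than dropped.

## Phenotyping

The 3D-assay and MRI indices are plain ratio formulas with domain guards.
The default dichotomization is the exhaustive optimal two-group split of
the sorted indices (minimum total within-group sum of squares) — the
smallest-assumption rule when no threshold is given; a threshold mode is
provided. Because ratio-scaled indices spread proportionally to their
level, the sum-of-squares criterion on the raw scale can trim samples off
the wider high-invasion cluster; the pipeline therefore splits on
log-indices whenever all indices are positive, and falls back to the raw
scale otherwise. `classify_invasion` itself always operates on the values
it is given.

Spearman correlation uses mid-ranks; for n ≤ 7 the two-sided p-value is
the exact permutation tail, for larger n the *t* approximation with n − 2
degrees of freedom.

## Clustering and differential expression

Samples are clustered on correlation distance (1 − Pearson *r*, computed
over all genes by default, optionally the top-variance subset) with
average (UPGMA) linkage; merge heights are verified against a brute-force
agglomerative oracle for small instances. Dendrograms serialize to Newick
with branch lengths equal to merge-height differences. Per-gene
differential expression reuses the pooled *t* / BH machinery.

## Survival

Kaplan–Meier estimation and the log-rank statistic are delegated to
lifelines; this package fixes the table conventions, validates inputs
(positive times, binary events, at least one event), applies the standard
events-before-censoring convention at tied times, and adds `min(1, p·m)`
Bonferroni adjustment for multi-group comparisons. Score stratification
takes the lowest and highest `floor(n·fraction)` samples by order
statistics (no percentile interpolation), so group sizes are unambiguous —
147 samples at 20% give groups of 29; boundary ties are broken by
sample-id order and logged.

## Synthetic cohorts

The generator emulates a post-normalization log-scale microarray: gene
baselines mu_g ~ Normal(7, 1), residuals Normal(0, noise_sd = 0.5), 20,000
genes × 23 samples (11 low / 12 high — the split is a stand-in choice, not
a reported value). Each of 50 TFs owns three 20-gene target sets with a
30% shared core, drawn disjointly across TFs when the universe allows;
planted TF pools are always kept disjoint so every planted shift is
attributable to one TF and direction. Promoting TFs add `effect_size`
(default 1.5, in gene-level SD units) to their targets and their own gene
in high-invasion samples; suppressing TFs do the same in low-invasion
samples. Shifting the own gene makes the activity-vs-expression
significance correlation reproducible in silico.

Invasion indices are log-normal around group geometric means (3D assay
0.6 low / 2.2 high; MRI 0.4 / 1.2) with a shared latent normal
(SD 0.25) plus idiosyncratic noise (SD 0.15), giving clearly separated
groups and a strong built-in 3D/MRI pairing; areas are back-computed so the
index formulas reproduce the drawn indices. Survival is exponential with
the low group at 18-month median, high-group hazard `hazard_ratio` (default
3) times larger, and independent exponential censoring whose rate is
matched per group to the target censored fraction (default 15%).

The generator does **not** emulate probe-level noise, batch effects,
stromal admixture, correlated co-regulation between different TFs, or
non-proportional hazards. Passing recovery tests therefore demonstrates
that the machinery is correct and calibrated under its own assumptions,
not that the selection would reach the same operating point on real
cohort data.

## Known limitation: quantile normalization of small activity matrices

With only 50 TF rows per sample and 10% of them strongly planted, forcing
every column to one shared distribution leaks signal: in high-invasion
samples the planted promoting TFs occupy the top ranks, so in low-invasion
samples whichever null TFs happen to rank highest are mapped to the same
reference tail, producing spurious low-group-elevated calls. The effect
shrinks as the regulon collection grows (measured false-discovery fraction
among selected TFs roughly halves from 50 to 200 TFs) and vanishes for
realistically sized collections. The planted-recovery benchmark and the
acceptance script therefore score selection on the raw activity matrix;
the pipeline default keeps normalization on, matching the intended
workflow on full-size collections.

The recovery benchmark also disables the own-gene expression filter
(quantile 0): planted cohorts contain no low-expression decoy TFs, so any
filtering would only remove true positives and make sensitivity reflect
the filter rather than the detection machinery.

## Problem sizes used in tests

Unit tests run on cohorts of 500–5,000 genes and 12–24 samples; the
statistical end-to-end checks use the full study conditions (20,000 genes,
23 samples, 50 TFs) over 8–50 seeds, 1,000 replicates for log-rank null
calibration and 400 per point for the power curve. The whole suite runs in
about a minute on one CPU.
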
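# Methods

This note documents the models, conventions, and numerical choices
behind `chemosig`, and what the synthetic-data experiments do and do
not demonstrate.

## Synthetic cohorts

`simulate_bulk_cohort` generates log-scale expression directly as
Gaussian noise: `x[g, s] ~ Normal(baseline_mean + delta * 1[g in
signal, s in NR], noise_sd)`. The pipeline consumes log-normalized
values (library-size normalization to a 10,000-count scale followed by
log2), so generating on the log scale skips the count model
deliberately; a negative-binomial count mode is out of scope. The
planted signal genes are the first `n_signal_genes` gene ids, recorded
in `truth`. Defaults emulate the kind of cohort the workflow targets: a
two-class bulk cohort of 50 responders and 38 nonresponders over 2,000
genes with a 43-gene planted signature at `delta = 1` (one noise-sd),
`baseline_mean = 2`, `noise_sd = 1`. Under this model a single signal
gene has closed-form discrimination AUC `Phi(delta / (sd * sqrt(2)))`
(≈ 0.76 at delta 1, ≈ 0.92 at delta 2) and an uncorrelated g-gene panel
approaches `Phi(delta * sqrt(g) / (sd * sqrt(2)))` — the calibration
targets the tests check.

All randomness flows from one seed through named `SeedSequence`
substreams (expression, labels, survival, censoring), so enlarging the
gene space cannot perturb sample labels, and identical configurations
serialize byte-identically.

`simulate_cell_clusters` plants `markers_per_cluster` genes per cluster
(up-shifted by `delta` only in that cluster's cells) and labels cells
R/NR by a per-cluster Bernoulli `nr_enrichment` probability.

Survival times are exponential with hazard `baseline_hazard * exp(beta
* score)`; the default 0.02/month puts the median near 35 months at
score 0, a realistic advanced-ovarian-cancer scale. Censoring follows
the classical random-censoring model: an independent exponential
censoring time whose hazard is `censor_rate / (1 - censor_rate)` times
the subject's event hazard, giving `P(censored) = censor_rate` exactly
for every covariate value while keeping the censoring time independent
of the event time given the covariate. An earlier design — censoring at
a uniform fraction of the subject's own drawn event time — was
abandoned because it is informative and biases the Cox estimate upward
by about +0.09 at a 30% censoring fraction; with the current scheme the
partial-likelihood estimate is unbiased (recovery within ±0.2 of
beta = 1 at n = 500, null type-I retention ≈ alpha over 2,000 genes).

What the generator does *not* emulate: gene–gene correlation, count
noise/dropout, library-size variation, batch effects, doublets.
Passing tests therefore demonstrate the correctness of the algorithms
under the stated model, not the clinical performance of any signature;
on real cohorts correlated genes make panels less informative than the
independent-gene analytics suggest.

## Differential expression and markers

R-vs-NR DE uses the two-sided Wilcoxon rank-sum test per gene with
Bonferroni correction within the comparison (BH is used elsewhere, e.g.
across gene sets). Fold changes follow the Seurat-style convention on
de-logged means with pseudocount 1: `avg_log2FC = log2((mean(2^x - 1 |
A) + 1) / (mean(2^x - 1 | B) + 1))`, antisymmetric under group swap.
Cluster markers are one-vs-rest with conjunctive pre-test gates
`pct_in >= 0.1` and `avg_log2FC >= 0.25`; relaxing a gate can only grow
the candidate set. Clusters with fewer than 3 cells are skipped with a
warning. A published ensemble-of-DE-callers step in this family of
workflows is deliberately replaced by this single documented Wilcoxon
procedure; ensemble consensus is out of scope.

The Wilcoxon test is exact (full enumeration) when the combined sample
size is at most 12 with no ties — enumeration cost is bounded and this
matches common practice — and otherwise uses the tie-corrected normal
approximation without continuity correction. At the switch point the
two paths agree only to the approximation's worst-case error (~0.07
absolute in the far tails at n1 = n2 = 6), which is a property of the
normal approximation, not of the implementation; the property test pins
that bound.

## Gene-set screening

Each DE gene list (sorted by |avg_log2FC| descending, or adjusted p
ascending) submits its top 500 genes. Enrichment against the collection
is the upper-tail hypergeometric overlap test on the collection's
universe (widened by the query); sets are BH-filtered at FDR < 0.05,
sets with fewer than 3 genes present in the evaluation cohort are
excluded (the classifier minimum), and the survivors are ranked by
(raw p, set name) — a deterministic tie-break — keeping the top 10.
Each surviving set is then fit and evaluated as an independent
classifier panel; the list is flagged predictive iff at least
⌈top/2⌉ of its top sets achieve AUC p < 0.05.

## GSVA-style scoring and preranked GSEA

GSVA: gene-wise kernel CDF across samples (Gaussian kernel, bandwidth
sd/4 — the conventional default; constant rows are excluded), per-sample
gene ranking of the CDF values, symmetric rank statistic |p/2 − rank|,
and a tau = 1 weighted Kolmogorov–Smirnov random walk whose score is
max deviation + min deviation ("mx.diff"). Sets with fewer than 2
scorable genes are skipped. An `ecdf` kernel is provided: it makes the
scores exactly invariant under *any* rank-preserving per-gene monotone
transformation, whereas the Gaussian kernel is exactly invariant only
under monotone affine maps (the kernel sees distances, not just ranks).
Both invariances are tested at their exact scope.

Preranked GSEA: weighted KS running sum with exponent `weight = 1` on
|rank score| (`n_perm = 1000` by default), signed ES at the extremum of
maximal magnitude, sign-stratified gene-label permutation p-values with
an add-one correction, NES = ES / mean(|permuted ES| of the same
sign), BH FDR across sets, and the leading edge as the member genes up
to the extremum. Preranked mode has no phenotype to permute, hence
gene-label permutation; the permutation seed is exposed. A signature's
response-associated refinement (`refine_by_leading_edge`, the
Sig → Sig2 step) is pinned as the leading-edge genes of a significant
enrichment in the stated direction — "all positively contributing
members" was the alternative reading; the leading edge is the
conventional, reproducible choice and is flagged here.

## Centroid classifier

Per-gene standardization uses training mean and population sd
(zero-variance genes dropped with a warning; fewer than 3 usable genes
is an error). The default score is the difference of Euclidean
distances to the class centroids in standardized space, oriented
higher ⇒ nonresponder. A difference-of-Pearson-correlations score is
available behind `distance="correlation"`, but it is **not** the
default: Pearson centering subtracts each sample's panel-mean, so a
shift shared by the whole panel — exactly the geometry of a response
signature whose genes move together — is invisible to it (held-out AUC
collapses to ~0.5 on planted-signature cohorts where the distance
score reaches ~1.0). The raw score is z-standardized by the
training-score mean/sd; prediction on new cohorts reuses training-time
gene scaling, score scaling, and calibration, never re-standardizing on
test data. Missing panel genes at prediction are dropped with a warning
(aborting below 3).

Calibration is a two-parameter logistic fit of class on score_z, by
near-unpenalized maximum likelihood (scikit-learn with C = 1e6): the
negligible ridge keeps perfectly separated training scores from
diverging while leaving the calibration monotone and the 0.5-probability
threshold well-defined. The dichotomous call is NR iff score_z exceeds
that calibrated threshold.

Evaluation reports the Mann–Whitney AUC (ties 1/2), a Welch t-test
p-value on the class-wise score lists (the convention of the
Cancerclass-style evaluation this mirrors, rather than DeLong or
permutation), and sensitivity/specificity at the Youden-optimal
threshold with Wilson 95% CIs; the threshold rule is recorded in the
result metadata because published reports rarely state their operating
point.

## Recursive elimination

From the assembled candidate panel (union of significant sets ∩ gated
per-subtype fold-change survivors ∩ cohort genes, lexicographically
ordered), each cycle evaluates all k size-(k−1) subsets by
resubstitution AUC on the training cohort and keeps the best; ties
resolve by removing the lexicographically last gene (recorded in the
trace). The loop stops at `min_size = 3`, giving p − 2 cycles and
p(p+1)/2 − 5 classifier evaluations, both audited from the trace.

Per-cycle evaluation uses an O(k·n) running-sum update of the centroid
distances/correlations rather than refitting: per-gene standardization
and centroid entries do not depend on the subset, and AUC is invariant
to the subset-specific monotone score rescaling, so the fast path is
score-equivalent to a classifier refit per subset — an equivalence the
test suite enforces by brute force (every subset, real fit/evaluate
path) for panels up to 8 genes. A degenerate subset scores AUC 0 and is
logged rather than aborting the search; zero-variance genes are dropped
before the search begins.

Selection: the highest best-AUC across cycles wins; among cycles tied
within 1e-9 the *median* panel size of the plateau is taken. A
smallest-panel tie rule was considered and rejected: with resubstitution
AUC the plateau at 1.0 routinely extends below the true signature size,
so the smallest tied panel has already shed real signature genes, while
the largest retains noise; the plateau's middle hedges both, mirrors
how a practitioner picks from a published AUC plateau, and restores
planted-gene recovery (≥ 60% required, ~100% observed at the study
conditions). `size_override` reproduces any manual choice from the
trace. Elimination is evaluated on the training cohort itself by
default (the protocol the workflow mirrors); for honest generalization
estimates, validate the frozen model on an independent cohort, as the
acceptance script does.

## Survival screening

The univariate Cox screen fits each gene by Newton maximization of the
single-covariate Breslow partial likelihood (vectorized cumulative
risk-set sums over descending times; ties share a risk set). Breslow
was chosen as the simplest adequate convention for continuous synthetic
times; on tie-free data it coincides with Efron, and the implementation
matches lifelines to ~1e-6 on the same data. Wald p-values and normal
CIs on the log scale; genes are retained at p < alpha with the hazard
ratio on the requested side of 1 (risk: HR > 1; protective: HR < 1).
Non-convergent or constant genes are skipped and logged. The
multivariate model is a thin wrapper over lifelines' `CoxPHFitter` and
carries no methodological weight here.

`km_median_split` dichotomizes a per-sample score at its median (ties
to the low group; all-equal scores are an error), estimates per-group
Kaplan–Meier curves, and tests with the two-group log-rank statistic
(lifelines); response labels play no role in the survival operations.

## Problem sizes and runtime

The test suite and acceptance script use scaled-down study conditions
chosen to exercise every code path with comfortable statistical margins:
signature development on 200-gene / 100-per-class cohorts with 20
planted genes (3 seeds), null controls on 5-gene panels at 200 per
class (20 seeds), analytic AUC calibration at 500 per class, Cox
calibration over 2,000 null genes at n = 500, and exhaustive-search
cross-checks on panels of 5–8 genes. The full suite runs in well under
a minute of CPU; `scripts/acceptance.py` in a few seconds.

## Known limitations

- Resubstitution AUC during elimination is optimistically biased; the
  selected panel's honest performance is the frozen-model AUC on an
  independent cohort.
- The generator's independence assumptions make recovery look easier
  than on real, correlated transcriptomes.
- GSVA here implements the Gaussian/ECDF continuous-data path only (no
  Poisson kernel for counts); GSEA FDR is BH across sets rather than
  the permutation-based FDR of the original tool.
- The Wilcoxon exact path is limited to combined n ≤ 12 without ties.
- Whether published per-cycle AUCs used resubstitution or internal
  cross-validation is generally unstated; both protocols are exposed
  (fit/evaluate are separable), with resubstitution as the default
  elimination criterion.
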
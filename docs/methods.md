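# Methods

This note documents the models, parameter choices and numerical policies
behind `endoscope`, and what the synthetic-cohort tests do and do not show
about behavior on real data.

## Synthetic cohort model

The generator draws a cohort of `n_patients` (default 500) across
`n_sites` (default 3, proportions 0.45/0.35/0.20). Each patient carries:

- an **endotype** label k ∈ {1..4} with proportions (0.20, 0.20, 0.20,
  0.40). The proportions are chosen so that, with the default per-endotype
  28-day mortalities (0.22, 0.22, 0.20, 0.11), the mixture mortality is
  ~17%, with one large low-mortality group and three smaller high-mortality
  groups — the regime the pipeline targets.
- a **severity** factor v ~ N(0, 1), the single latent axis linking
  expression to outcome.
- a death indicator from logit P(death) = β₀ₖ + 1.5·v, where each β₀ₖ is
  solved by root-finding (Brent) so the endotype's expected mortality over
  its realized severities equals the configured rate. This makes group
  mortalities controllable test targets rather than emergent quantities.

Genes (default 3400 = 3000 expressed + 300 low-expression + 100
sex-linked) have lognormal baseline means μ_g (log-mean 3.5, log-sd 1.2).
Low-expression means are drawn as a uniform fraction (0.02–0.45) of the
count level corresponding to 10 CPM, so they sit under the filtering line
regardless of library composition. Sex-linked genes are placed on X/Y;
Y-linked genes are knocked down ~64-fold in females.

Counts are negative binomial with mean s_j·μ_g·2^Δ and dispersion
α(μ) = a₀ + a₁/μ (defaults a₀ = 0.05, a₁ = 2). The log2 shift Δ sums:

- +1.0 (`module_log2_effect`) on that endotype's 50-gene module
  (disjoint modules named interferon / inflammation / heme /
  immunosuppression, echoing the biology of reported sepsis endotypes);
- ±0.8·v (`prognostic_log2_effect`) on 25 prognostic genes with random
  signs (60% positive), so mortality-associated expression flows through
  the same severity factor that drives death.

Library sizes s_j are lognormal (log-sd 0.25) with small per-site offsets
(±0.1 in log), normalized to geometric mean 1; sites have no expression
batch effect by default (an optional `batch_log2_shift` knob exists for
robustness experiments), matching a cohort whose preprocessing shows no
site bias. Age and sex are independent of mortality.

**Clinical score.** The qSOFA-like 0–3 score is a discretized noisy
severity reading: latent u = 2·(died) + 0.5·z(logit P(death)) + σ·ε, cut at
the 45/75/92% quantiles, with σ bisected until the empirical AUROC against
realized mortality hits `clinical_score_auroc_target` (default 0.72,
tolerance ~±0.03 at n = 500). Anchoring u partly on the realized outcome is
deliberate: the generating probability alone caps achievable AUROC at the
Bayes limit of the logistic model (~0.78 at defaults), so targets above it
would otherwise be unreachable. The score therefore carries information
about the outcome beyond the transcriptome — exactly the situation in which
comparing a gene panel to a clinical score is interesting.

**What the generator does not emulate:** gene–gene correlation beyond the
planted modules and severity axis, heavy-tailed count outliers, pathogen
etiology, missing clinical data (beyond what a user masks), or real
Hallmark pathway structure (`synthetic_hallmark_collection` plants the four
module sets among 46 random sets). Tests passing on this generator show
the machinery is correct and calibrated, not that real sepsis cohorts
decompose into four groups.

## Preprocessing

CPM is computed on pre-filter library totals; the low-expression rule is
*mean CPM across patients ≥ 10 retained* (inclusive boundary). Sex-linked
(X/Y) and unannotated genes are dropped to avoid sex bias in feature
selection. Median-of-ratios size factors use as reference the genes with
strictly positive counts in every patient (a pseudo-reference fallback over
positive counts is available for sparse data) and are rescaled to geometric
mean 1.

The dispersion trend is fitted to per-gene method-of-moments dispersions
α̂ = max((var − μ)/μ², 1e−8) on normalized counts by non-negative least
squares on [1, 1/μ], iteratively excluding genes beyond 2 MADs of the
residual (≤ 10 iterations). If every α̂ is at the floor the fit falls back
to (0.01, 1.0) with a warning; if a₀ ≤ 0 the VST falls back to
log2(x + 1). The closed-form VST is strictly increasing and approaches
log2(x) + const for large x, so downstream mean differences are log2 fold
changes.

## Mapper stage

Patient distance is 1 − Pearson r between VST profiles. The two lens
coordinates are the second and third eigenvectors of the symmetric
normalized Laplacian of the mutual k-NN graph (k = 15, unit edge weights),
**augmented with the global minimum spanning tree** of the distance
matrix. The augmentation is load-bearing: on separated patient groups the
mutual k-NN graph decomposes into group-sized components and the spectral
embedding is undefined; the MST restores connectivity while leaving local
geometry dominated by the k-NN edges. Eigenvector signs are fixed against
the lexicographically smallest patient id, and each coordinate is
rank-scaled (empirical CDF) to [0, 1] — Laplacian eigenvectors concentrate
mass, and rank scaling keeps cover bins populated. Without MST
augmentation (`connect_mst=False`) the largest component is embedded and
stragglers inherit their nearest embedded patient's coordinates, with an
error if the largest component covers under half the cohort.

The cover uses R intervals per axis with centers evenly spaced over the
data range, length range·(1+g)/R clipped to the range, half-open except
the last. Defaults: **R = 8, g = 0.35**. R was set from bin occupancy:
with ~n·(1+g)²/R² patients per 2-D bin, R = 8 keeps ~10–15 patients per
bin at cohort scale, which the per-bin clustering heuristic needs; finer
covers starve bins, fragment the graph, and halve endotype recovery.

Per-bin clustering is single linkage cut at the lower edge of the first
empty bar of a 10-bin histogram of merge heights; no gap (or all-equal
heights) keeps the bin whole. Nodes need ≥ 2 patients; edges join nodes
sharing patients, weighted by the shared count.

Groups are communities of the node graph under greedy modularity
maximization (nodes inserted by descending size, id tiebreak, for
determinism). Communities below 5% of assigned patients are dropped (their
patients stay unassigned and are logged). If more than `overlap_cap`
(default 10%) of assigned patients belong to multiple groups, the cover is
re-searched over R ∈ {10, 15, 20, 25} × g ∈ {0.20, 0.30, 0.35, 0.40},
keeping the setting with the most groups above the size floor subject to
the cap; failure raises with the best fraction found. Adjacent groups
(sharing patients or connected nodes) with fewer than 10 deaths each are
merged pairwise, and final groups are labeled t1..tK by descending
mortality.

## Differential expression and clinical comparisons

Welch t-tests with Welch–Satterthwaite degrees of freedom; constant genes
yield t = 0, p = 1 with a warning rather than an error. L2FC is the
died−survived difference of VST means (positive = higher in
non-survivors). BH adjustment is applied per contrast across all tested
genes. Between-group contrasts drop patients attributable to more than one
group; unions are written "t1+t2+t3". Clinical features are compared by
one-way ANOVA across exclusive groups plus pairwise Welch tests, restricted
to features with ≥ 2 observations per group; non-numeric features are
skipped with a log entry.

## Prognostic modeling

mRMR: relevance is the classification F statistic, z-scored over the
candidate pool once at the start; redundancy is the mean |Pearson r| with
already-selected genes; score = relevance_z − redundancy; the first pick
maximizes raw relevance; ties break by gene id. Note the redundancy term
is bounded by 1 while the z-scored relevance is not, so an exact duplicate
of a very strong gene can still precede a weak independent gene — the
penalty dominates only among candidates of comparable relevance.

Cross-validation is repeated stratified k-fold (default 10×10) of an
L2-penalized logistic model (C = 1, intercept, max_iter = 1000), features
standardized on the training fold only. Fold assignment orders each class
by a BLAKE2 hash of (patient id, seed, repeat) and deals round-robin, so
folds are invariant to row order and identical across models compared on
the same patients and seed — the clinical-score comparison (restricted to
patients with a score) uses exactly the same folds for both models. AUROC
is the Mann–Whitney statistic with half-credit for ties.

Panel size is the smallest n whose mean AUROC over the first n ranked
genes is within one standard error (sd at the best n over
√(repeats·folds)) of the best mean. With many informative correlated
genes the curve creeps upward and the rule picks large panels; its purpose
is to find the knee when informative genes are few. Per-group models
re-rank the shared top-50 candidates by mRMR within the group's exclusive
members before the step-up, and groups whose minority class is smaller
than the fold count are skipped with a logged reason.

## Enrichment

Genes are ranked by decreasing L2FC (significant-only filtering, adjusted
p ≤ 0.05 inclusive, for between-group contrasts; all genes within groups).
The enrichment score is the signed maximum deviation of the weighted
running sum (hit increments |stat|^p/Σ|stat|^p with p = 1, miss decrement
1/(N − N_hits)). The null is gene permutation — random same-size draws
from the ranked list (cached per set size) — because the ranking statistic
is a precomputed fold change, making phenotype permutation unavailable at
this stage. NES divides ES by the mean |null ES| of matching sign; the
p-value is the add-one estimator over sign-matched nulls (floor
1/(1 + n_same_sign), so adjusted significance needs enough permutations
relative to the collection size). Null scores are computed by a
closed-form over sorted hit positions that is tested to agree exactly with
the explicit walk.

## Pipeline and reproducibility

All randomness flows from the config seed; the manifest hash covers the
analytic configuration (not the output path), and repeated runs are
byte-identical. Heatmap row ordering uses Manhattan distance with
"mcquitty" (WPGMA) or "ward" linkage leaf order. The CLI (`endoscope
simulate|run|report`) is a thin wrapper over the library.

Default problem sizes used by the test suite: the full-size checks run on
500-patient × 3400-gene cohorts (single runs or 10–20 seeds, chosen to
keep the whole suite in a few minutes on one CPU); unit tests use reduced
cohorts (~150 patients, ~600 genes) that preserve the statistical
structure but not the power of the default configuration.

## Known limitations

- The lens surrogate is a documented stand-in for a proprietary
  construction; it preserves the intent (local-neighborhood geometry), not
  any specific published embedding.
- Greedy modularity tends to over-segment sparse mapper graphs: the
  pipeline typically reports 5–7 groups for 4 planted endotypes, with the
  extra groups being fragments of true groups. Endotype recovery (ARI
  against planted labels, exclusive patients) is ~0.65–0.7 median at
  defaults.
- Method-of-moments dispersion estimation is noisy per gene; only the
  trend coefficients are used, and their recovery is validated to ~25%
  relative error at cohort scale.
- The one-standard-error denominator √(repeats·folds) treats fold scores
  as independent, which they are not; the rule is a conventional
  heuristic, not an unbiased model-size estimator.
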
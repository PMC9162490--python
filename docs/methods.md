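# Methods

This note records the statistical model behind each module, the defaults
and why they were chosen, the numerical edge cases, and what the synthetic
benchmarks do and do not demonstrate.

## Quality control and normalization

Cells are filtered on two per-cell statistics: the number of genes with a
nonzero count (`n_features`) and the fraction of counts on mitochondrial
genes (`mito_fraction`). A cell is removed when `n_features` is below 200 or
above 4000, or when `mito_fraction` exceeds 0.10. All three comparisons are
strict inequalities, so cells sitting exactly on a threshold survive; the
tests pin this boundary behavior explicitly. Mitochondrial genes are
recognized by a case-insensitive `MT-` prefix, overridable with an explicit
gene list. Cells with zero total counts are flagged invalid and always
excluded. Thresholds are applied to the merged object, not per donor; a
`sample_id` column is carried through so per-sample diagnostics remain
possible. Duplicate gene symbols are rejected with an error rather than
silently aggregated, because aggregation changes fold changes downstream.

Normalization scales each cell to the cohort median depth and applies
log1p. This deliberately replaces heavier variance-stabilizing transforms:
clustering, batch correction and dimensionality reduction are out of scope
here (cluster labels are an input), and the marker statistics used
downstream — rank-sum tests and fold changes of means — need only a
monotone, depth-comparable scale. Zeros stay zeros and proportional cells
normalize identically; the scale-invariance property holds exactly whenever
the rescaled cell does not change the cohort median depth.

## Marker selection and the signature matrix

Differential expression between two clusters is a per-gene two-sided
Wilcoxon rank-sum test. The p-value uses the tie-corrected normal
approximation without continuity correction, so a gene with identical
values in both clusters gets exactly p = 1; for comparisons with at most 12
cells in total and no ties, the exact null distribution is used instead
(this is also the regime where the tests enumerate the permutation
distribution as an oracle). The fold change is
`log2((mean_t + eps) / (mean_b + eps))` with `eps = 1e-9`, computed on
normalized expression; the pseudocount and base are package choices, made
explicit because different toolkits disagree here. Benjamini–Hochberg
correction is applied within each pairwise comparison, matching a
per-comparison FDR reading of the selection rule.

A gene is a marker of cluster *c* only if it clears FDR < 0.05 **and**
log2FC > 0.4 against **every** other cluster. Because the fold-change
threshold is positive and antisymmetric between the two directions of a
pair, marker sets of different clusters are provably disjoint; this is
asserted at run time rather than assumed. Marker lists are ordered by each
gene's minimum pairwise log2FC (descending, ties by name), which makes the
output invariant to cell and cluster ordering. The signature matrix takes
the marker-gene union as rows and the mean normalized expression per
cluster as entries. Mean expression on the normalized (log) scale is used —
whether a signature should be built on raw, normalized, or corrected
expression is genuinely open, and this choice is flagged rather than
hidden. Both a whole-tissue signature and an epithelial-only signature are
producible: the type set is just whatever labels are supplied.

## Robust deconvolution

The mixing model is linear: a bulk profile over the shared genes is
`y = S β + noise` with `β ≥ 0`. Inputs are expected on a linear scale; a
heuristic warning fires when the bulk maximum is below 50 (a typical
signature of logged data). The inner solver is the Lawson–Hanson active-set
NNLS.

The robustness layer is a least-trimmed-squares loop with three exposed
hyperparameters:

| parameter  | default | meaning |
|------------|---------|---------|
| `trim_k`   | 3.0     | flag genes with residual beyond `trim_k` robust SDs |
| `trim_cap` | 0.25    | never trim more than this fraction of genes |
| `max_iter` | 20      | iteration bound on the reflag-refit loop |

The robust scale is `s = 1.4826 · median(|r − median(r)|)` over all genes'
residuals. Genes with `|r| > trim_k · s` are flagged (largest residuals
first when the cap binds), the fit is repeated on the retained genes, and
the loop stops when the flagged set stabilizes. A residual scale at or
below `1e-9 · max(1, median|y|)` is treated as an exact fit and stops the
loop — without this floor, machine-epsilon residuals on noiseless data
would be "trimmed". The published robust deconvolution tool this emulates
does not document its exact constants; these defaults are standard robust
statistics practice (a 3-sigma MAD fence) and all four knobs are config.

Proportions are `β / Σβ`. An all-zero `β` raises a degenerate-fit error for
a single sample and is recorded (NaN row) without aborting a cohort run.
No implicit renormalization over type subsets is performed; summing merged
lineages is an explicit downstream operation. Signatures with condition
number above 1e8 trigger a warning, not an error.

Verified properties: exact recovery (error < 1e-8) on noiseless full-rank
mixtures; scale equivariance in `y`; monotone refit (final residual norm on
retained genes never exceeds the all-gene fit restricted to them); and
dominance over plain NNLS under planted contamination.

## Subtyping, stage tests, survival

Lineage merging sums columns and preserves row sums exactly. The subtype
rule is strict: a tumor is labeled by its argmax lineage only when that
fraction exceeds 0.4; exact ties at the maximum go to the lexicographically
first lineage with a logged warning; everything else is "mixture".

Stage strings accept TNM with optional a/b/c suffixes and case variants.
T1–T2 map to `T_low`, T3–T4 to `T_high`; N0 stays `N0`, N1–N3 become
`N_plus`; Tis/Ta/TX/NX, unparseable strings and missing values map to
`missing` and are excluded from tests (a warning, never a crash — clinical
exports are messy). Group comparisons use the Mann–Whitney U with exact
enumeration when both groups have at most 8 samples and the tie-corrected
normal approximation otherwise.

Cohort filters drop low-grade and not-available records; the optional OS
cap (off by default; 100 months in the sensitivity analysis it mirrors)
drops records **strictly above** the cap. Median dichotomization happens
after all filters, within the current dataset, with ties at the median
assigned to "low" — so "high" always means strictly above the median. The
Kaplan–Meier estimator and the log-rank test are computed via lifelines
(events before censorings at tied times); the test suite checks them
against an independently coded product-limit formula and the direct
observed-minus-expected chi-square on small fixtures, so the library is
cross-validated rather than trusted blind. No multiple-testing correction
across lineages is applied by default (a Bonferroni column is opt-in), and
the subtype-versus-mixture comparisons use mixture as the reference group.

## CNV profiles and scores

Genes are ordered by chromosome (1–22, X, Y, MT; `chr` prefixes
normalized) and start coordinate. For each cell, expression is centered on
the per-gene mean of an explicit reference cell set (at least 20 cells
required — below that the per-gene SD estimates are too unstable to clip
against), clipped at ±3 reference SDs per gene, smoothed along each
chromosome with a 100-gene moving window ("surrounding" is implemented as
50 genes before and 49 after, truncated at chromosome ends), and finally
median-centered per cell. A gene whose reference SD is zero contributes
zero deviation by construction of the clip. The per-cell score is the mean
squared smoothed deviation: symmetric in gains and losses, zero iff the
profile is identically zero; a mean-absolute variant is selectable. The
score is a *burden* measure — the figure caption this summarizes was
ambiguous about the formula, and a burden definition is the one that
supports the intended use (certifying that a cluster is copy-number
neutral). Per-type summaries flag a type as CNV-elevated when a two-sided
rank-sum test against all other cells pooled gives p < 0.05 and its median
score exceeds theirs.

## Synthetic data: what it emulates, and what it does not

The generators exist so that every stage has ground truth. One global seed
expands into fixed-offset child seeds per component, logged at INFO, and
identical configs give bit-identical outputs.

* **Single-cell counts** are negative binomial, parameterized by mean and
  dispersion (`var = m + m²/θ`, default θ = 2, baseline mean 0.5 — a
  sparse, overdispersed regime typical of droplet data). Markers are
  planted per type by multiplying the NB mean by `2^marker_log2fc` in that
  type's cells only. The first `mito_gene_count` genes carry an `MT-`
  prefix and an elevated baseline so the mitochondrial QC predicate
  operates on realistic fractions. A stated fraction of cells is corrupted
  to fail each QC predicate (too few features, too many features, high
  mitochondrial load), recorded in the truth object; high-feature failures
  require more genes than the feature cap and are skipped (with a log
  message) otherwise.
* **Bulk samples** are `proportions @ signatureᵀ` with Dirichlet
  proportions, multiplicative log-normal noise, and outlier genes sampled
  once per cohort (the same genes across samples — mimicking platform
  artifacts, which is exactly the contamination model trimming is built
  for) and multiplied by `outlier_magnitude`.
* **Clinical tables** draw exponential survival times with hazard
  `baseline · exp(log_hr · proportions)`, uniform censoring applied with
  probability `censor_rate`, and administrative truncation at
  `max_followup_months`. The T_high indicator is Bernoulli with logit
  `stage_coefs · proportions`; the N+ indicator reuses the same linear
  predictor shifted by −1 (one shared axis of "aggressiveness" rather than
  an independent parameter, since nothing downstream estimates the N model).
  Exponential times keep closed-form sanity checks available.
* **CNV events** scale the counts of genes inside each planted segment by
  its copy ratio in a random fraction of cells, re-rounding to integers.

The two-arm survival benchmark (`emt_survival_scenario`) draws half the
cohort EMT-rich (Dirichlet α = (1,1,1,1,8)) and half EMT-poor
(α = (2,2,2,2,0.5)) and sets the per-unit-fraction log hazard ratio to
`log(HR) / gap`, where `gap` is the difference of the two design means of
the EMT fraction — so the planted hazard ratio between the designed arms,
which median dichotomization recovers, equals the nominal HR. A
per-unit-fraction reading of the same HR over a unimodal cohort would
produce a group contrast far too small to be a meaningful power benchmark.

None of this simulates real dropout structure, doublets, ambient RNA,
donor effects, or the correlation structure of real bulk cohorts. Passing
benchmarks therefore demonstrate the *machinery* — the estimators recover
planted truth under their own model assumptions with correct error
control — not that any particular biological cohort will behave as cleanly.

## Problem sizes used by the benchmarks

The acceptance script and the heavier tests use desk-scale sizes chosen to
make the target properties measurable with comfortable margins: 300 genes ×
5 types and 100 replicates for deconvolution recovery and robustness (15
planted outlier genes, 10×); 50 random 60-gene, 3-cluster fixtures for the
marker-rule enumeration; 200-cell-per-type atlases for marker recovery;
cohorts of n = 300 with 100 replicates for survival power and type-I error;
and 240-gene, 240-cell datasets with a 150-gene planted segment for CNV
discrimination.

## Known limitations

* The DE test is the rank-sum only; model-based DE (NB GLMs) is out of
  scope, so marker selection inherits the rank test's behavior on
  very small clusters (a hard minimum of 3 cells per cluster is enforced).
* Deconvolution assumes linear mixing on a shared linear scale and a
  reasonably conditioned signature; collinear lineages (e.g. basal vs
  intermediate) should be merged rather than estimated separately.
* Survival analysis is the unadjusted KM/log-rank workflow; no Cox
  regression or covariate adjustment.
* The CNV scorer detects large segmental events via moving averages; it is
  not an HMM state caller and does not attempt breakpoint or subclone
  inference.
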
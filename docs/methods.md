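# Methods

## Model and procedure

The pipeline treats each disease "database" as a set of independent
case/control studies measuring the same gene universe on a log2 intensity
scale. Per study, differential expression is summarized by the case-minus-
control mean difference (logFC) and a moderated t-statistic: the per-gene
residual variance s²_g with d = n₁+n₂−2 degrees of freedom is shrunk toward
a prior variance s₀² with d₀ prior df,

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),   t̃_g = logFC_g / (s̃_g·√(1/n₁+1/n₂)),

with two-sided p from t(d+d₀). The hyperparameters (d₀, s₀²) are estimated
by method of moments on log s²_g under the scaled-F hierarchical model
(digamma/trigamma matching, Newton inversion of the trigamma function);
when the observed log-variance spread is no larger than expected under a
common variance, d₀ → ∞ and all genes share s₀². With d₀ forced to 0 the
statistic reduces exactly to the ordinary pooled-variance t-test, which the
tests verify, and the full procedure reproduces a reference
empirical-Bayes implementation on a frozen fixture to ~1e-14.

Evidence is combined in two levels with the adaptively weighted Fisher
method. For p-values p₁…p_K the weighted Fisher statistic is T(w) =
Σ_k w_k(−2 ln p_k) for binary w ≠ 0, each scored by the χ²(2Σw_k) upper
tail; the observed statistic is the minimum candidate p over all 2^K−1
weights (ties prefer the most inclusive weight vector, then lexicographic
order — deterministic). Because the minimum is optimized, its distribution
is not uniform; the combined p-value is the probability, under K
independent Uniform(0,1) p-values, that the min-candidate-p is at most the
observed one. That null is estimated once per K from a shared, seeded
Monte-Carlo table of B draws (default B = 10,000), giving combined
p = (1 + #{null ≤ obs})/(B+1), floored at 1/(B+1). The Monte-Carlo route was
chosen over the closed-form importance-sampling approximation of the
original method because it is transparent, testable at desk scale, and
trivially correct for any K ≤ 20; its resolution limit (1/(B+1)) is the
documented price.

Truncated study tables (only genes with p ≤ t reported) are completed by
mean imputation before combination: an unreported gene is known only to
have p in the censored interval (t, 1], whose mean is (t+1)/2. The
alternative reading — grand mean of the observed p-values — is available
via `impute_missing_pvalues(..., method="grand_mean")` but is not the
default, since observed p-values are by construction below the threshold
and their mean badly understates the censored region. Studies reporting
p-values without effect sizes participate fully in the p-value combination
and are simply excluded from direction checks and logFC pooling.

Direction concordance within a database is categorical: C when all
effect-size-reporting studies agree in sign, S when the subset with
p < 0.05 agrees (at least one such study required; the threshold filters
marginal signals), D otherwise. Zero logFC carries no direction. Genes with
an effect size in at most one study are vacuously C and flagged as such.
Common DEGs require cross-database AW-Fisher p < α (default 0.05), weight
(1,1), and status C or S in both databases; their direction comes from the
sign of the inverse-p-weighted pooled logFC in each database, and genes
with conflicting pooled signs are excluded from the connectivity query.

## Synthetic data: what it emulates and what it does not

The generator plants a gene-level truth — shared DEGs (same sign in both
databases), database-private DEGs, nulls — and draws Gaussian log2-scale
expression: gene baselines at 8 with per-study offsets (sd 0.5) for
between-study mean heterogeneity, residual sd 1, case arms shifted by
±effect size. Reporting quirks are simulated downstream of a real DGE run:
truncation at a p threshold, blanked logFC columns. Defaults mirror the
reference scenario used throughout the tests: 5,000 genes, 3 studies per
database, 20 samples per arm, 200 shared and 50 private DEGs per database,
effect size 1.0 log2 units, one truncated study per database at p ≤ 0.05.
Gaussian intensities match the limma-style modeling assumption appropriate
for microarray-dominated source data; the generator does not emulate
probe-level structure, RNA-seq counts, correlated genes, confounded
batches, or platform-specific gene spaces. Passing tests therefore
demonstrate the statistical machinery (calibration, recovery, leakage
freedom), not robustness to those real-data pathologies. Stream-split
seeding (SHA-256-derived SeedSequence spawn keys per study/purpose) makes
every artifact independently reproducible and insensitive to adding
studies.

## Numerical and design choices

- p-values are clamped to [1e-300, 1] before logs; inverse-p logFC weights
  use the same floor.
- The log2 decision rule uses pooled-matrix quantiles (linear
  interpolation); "range" is max − min over all entries. Per-sample
  evaluation is a plausible alternative reading; pooled was chosen as the
  simpler one.
- The log2 offset shifts the matrix minimum to 1 when values ≤ 0 are
  present (offset = 1 − min, else 0): a fixed +1 leaves entries below −1
  undefined, which would poison quantile normalization for genes the
  negativity filter keeps.
- Quantile normalization maps each column onto the mean of the per-sample
  sorted vectors; ties within a column receive the mean of their assigned
  reference values, preserving within-column rank order up to ties.
- Duplicate gene rows keep the first-occurring maximum-variance record.
- Elastic net uses the glmnet parametrization (α mixing, λ strength) mapped
  to scikit-learn's saga solver via C = 1/(n·λ). Default grids: α ∈ {0,
  0.25, 0.5, 0.75, 1}, λ log-spaced over 50 values in [1e-4, 10]; random
  forest ntree ∈ {500, 1000}, mtry ∈ {√p, p/3, p/2}. Inner CV is stratified
  5-fold on the pooled training studies, tuned on accuracy (the reported
  metric), first-best tie-break. Tests and the orchestrated smoke run use
  trimmed grids (3 α × 3 λ, 3 inner folds) — the tuning surface on strongly
  separable fixtures is flat, so the smaller grid exercises the same code
  path at a fraction of the cost.
- Accuracy is the fraction correct at the 0.5 probability threshold. The
  feature ranking comes from one final fit on all studies pooled.
- The connectivity score is the Pearson correlation between a perturbagen's
  log-FCs (restricted to matched query genes) and the ±1 membership vector;
  a Spearman option exists. Magnitudes of the disease signature are not
  used — membership only. Perturbagens with fewer than 10 matched genes or
  zero variance are skipped, not scored.
- The enrichment stage is a plain one-sided hypergeometric ORA. It stands
  in for interactive annotation platforms; no redundancy clustering of
  pathways is attempted, and the BH-FDR column is informational (selection
  uses raw p < 0.05 with the overlap/ratio/size filters).

## Problem sizes and verification

The acceptance checks run the reference 5,000-gene scenario in full
(< 1 s per run at B = 10,000): 10-seed calibration gave sensitivity
0.985–1.000 and observed FDR 0.135–0.21 against a label-permuted null
sensitivity of 0.005–0.035, and the pinned pass bounds (sensitivity ≥ 0.9,
FDR ≤ 0.30, margin ≥ 0.5) sit far outside the observed seed-to-seed
variation. The AW-Fisher search is verified exactly against brute-force
enumeration for K ≤ 4 (1,000 random vectors per K), the all-ones special
case against the classical Fisher χ²(2K) closed form to 1e-12, and the
hypergeometric tail against exhaustive pmf summation for N ≤ 50.

## Known limitations

- Monte-Carlo combined p-values are bounded below by 1/(B+1); ranking below
  that floor relies on the observed min-candidate-p, which is emitted for
  diagnostics.
- The weight search is exponential in the number of studies (bounded at
  K = 20), which is ample for literature meta-analyses of this design.
- The imputed p-value for truncated tables is a single deterministic value
  per study; gene-specific censoring information beyond the threshold is
  not modeled.
- Concordance is direction-only; no heterogeneity magnitude statistics
  (Q, I²) are computed.
- The prediction stage assumes every feature gene is present in every
  study; gene-space mismatch must be resolved upstream.
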
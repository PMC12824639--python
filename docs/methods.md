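# Methods

`tmescope` re-creates, on synthetic cohorts with known ground truth, the
analysis chain used to characterize the breast-cancer tumor microenvironment
(TME) from bulk expression: immune-cell deconvolution, TME clustering,
signature-gene derivation, a PCA-based prognostic TMEscore, survival
stratification and immunotherapy-response scoring. This note records the
models, conventions and numerical choices, and what the synthetic test bed
does and does not establish.

## Synthetic cohorts

`simulate_cohort` draws, per sample *i* in latent TME group *g*:

* **Cell fractions** `f_i ~ Dirichlet(alpha_g)`. Archetypes put
  concentration 16 on the group's own block of cell types and 1 elsewhere.
  The separation is deliberate: for concentration *c* vs 1 the probability
  that an off-archetype coordinate exceeds the dominant one is
  `P(Gamma(1) > Gamma(c)) = 2^-c`; at `c = 8` that is ~0.4% per sample, so a
  few hundred samples always contain genuinely ambiguous points and perfect
  recovery (ARI = 1) becomes a coin flip over seeds, while at `c = 16`
  (2^-16 ≈ 1.5e-5) the planted partition is recoverable essentially without
  error. The default therefore models *cleanly separated* TME phenotypes,
  the regime in which exact-recovery tests are meaningful.
* **Marker expression** `(S f_i) * exp(N(0, noise_sd))` on the linear scale
  through the signature matrix `S` (multiplicative lognormal noise,
  default `noise_sd = 0.1`); expression never goes negative.
* **Prognostic modules**: module *m* has activity
  `a_im = shift_{m,g} + N(0, 0.5)` where the per-group shifts are a random
  permutation of equally spaced levels in ±1 log2 units; each module gene is
  `base + a_im + N(0, 0.4)` on log2. Defaults plant one hazardous and one
  protective module of 40 genes with log-hazards ±0.8 per SD (hazard ratios
  ≈ 2.2 and 0.45) — strong but realistic prognostic modules.
* **Survival**: `hazard_i = h0 * exp(sum_m beta_m * zbar_im)` with `zbar`
  the mean per-gene z-score of the module, event times Exponential,
  independent Exponential censoring (`h0 = 0.02`, `censor = 0.01` per month
  → ~1/3 censoring with null covariates, median survival ~3 years).
* **Batches**: additive `N(0, 0.5)` per gene × batch on the log2 scale,
  mirroring how location-scale batch correction models the nuisance.
* **TMB and response**: the latent prognostic score is the negated linear
  predictor (high = protected). TMB = `max(0, 10 + 5 z(latent) + N(0, 2))`
  mutations/Mb. Response adds standard-logistic noise to `z(latent)` and
  cuts at the 30/65/90% quantiles → PD/SD/PR/CR at roughly 30/35/25/10%,
  a plausible checkpoint-inhibitor response mix with CR rarest.

One integer seed drives a spawned family of numpy Generators; no global RNG
state is touched. The generator does **not** emulate read-count noise
(negative binomial), probe-level microarray artifacts, missing clinical
fields, or dependence between censoring and covariates. Tests passing here
show the *algorithms* behave as specified under their own model assumptions,
not that the pipeline is robust to real-data violations of them.

## Preprocessing

* TPM: per-sample rescale to a column sum of 1e6 (idempotent).
* Linear ↔ log2 conversions use `log2(x + 1)`; the +1 offset is fixed.
* Batch correction is the parametric empirical-Bayes location/scale model:
  standardize each gene by the pooled (batch-mean-removed) moments, estimate
  per-batch location γ and scale δ, shrink γ toward a normal cross-gene
  prior and δ toward an inverse-gamma prior (method-of-moments
  hyperparameters), iterate the joint update to relative change < 1e-6 or
  100 iterations, unstandardize. Degenerate guards: pooled variances and δ
  are floored at 1e-12; a cross-gene δ spread below 1e-12 collapses the
  prior onto its mean; γ shrinkage with cross-gene spread ~0 reduces to the
  common shift, so a pure location effect is removed exactly. Without
  shrinkage (`parametric=False`) the per-gene grand mean is preserved
  exactly; with shrinkage it is preserved only approximately, since the
  empirical-Bayes compromise deliberately does not force residual batch
  means to zero. Covariates are not supported.

## Deconvolution

Linear-kernel ν-SVR (C = 1) of the standardized mixture on the standardized
signature columns, per sample, over ν ∈ {0.25, 0.5, 0.75}; the ν minimizing
reconstruction RMSE wins; negative coefficients are clipped and the rest
normalized to the simplex. Standardization makes fractions invariant to
global rescaling of a sample. Significance: the sample's marker values are
permuted across markers `n_perm` times, the model is refit at the selected ν
only (a deliberate economy — the ν search is part of fitting signal, not of
the null), and `p = (r + 1)/(n_perm + 1)`. A degenerate fit with no positive
coefficient falls back to uniform fractions. Bit-parity with the hosted
CIBERSORT service is not promised; quantile normalization is off.

## TME clustering

Ward linkage on Euclidean distances (scipy's Lance–Williams `ward` update)
cut to exactly k; K-means is best-of-restarts k-means++ by within-cluster
sum of squares. Consensus clustering subsamples 80% of samples without
replacement `n_iter` times, clusters with the chosen base method, and
records co-assignment frequencies among co-samplings; pairs never co-sampled
get 0 and are logged. Final labels: average-linkage clustering of
1 − consensus. Stability is summarized by PAC — the fraction of off-diagonal
consensus entries strictly inside (0.1, 0.9).

**k selection.** k = argmin PAC. Ties at PAC > 0 go to the smaller k. Ties
at PAC = 0 go to the **larger** k: with three well-separated clouds, k = 2
is also perfectly stable (the same two clouds merge in every subsample), so
"smaller k wins" would systematically under-cluster separable data; a
coarse stable partition only merges clusters of a finer stable one, and
ambiguity appears exactly when k exceeds the recoverable structure. The
consensus-CDF delta-area per k is emitted for inspection alongside PAC.

## Signature derivation

Differential expression uses a two-sample t with the per-gene pooled
variance shrunk toward the cross-gene mean variance at a fixed prior df of 4
(the reference distribution gains those df). A fixed prior keeps the
moderation self-contained and testable; estimating the prior df adds little
at the cohort sizes in play. BH adjustment is applied within contrast.

Two gene lists are first-class outputs: the per-contrast significant-gene
**union** (the signature pool fed forward) and the all-contrast
**intersection** (the consistently dysregulated core, reported for
description). The analysis drivers additionally apply a 0.5-log2 effect
floor to the pool: once per-sample library normalization couples all genes
to the cell-composition differences between groups, large cohorts make
vanishingly small compositional shifts "significant", and a fold-change
floor keeps the pool at genes with meaningful differences.

Gene modules come from K-means over genes (samples as features) on z-scored
expression, module ids ordered by size. Optional reduction fits a random
forest of the TME labels on the module genes and ranks genes by **per-tree
out-of-bag permutation importance** (each tree's OOB accuracy drop when one
feature is shuffled, averaged over trees). Whole-ensemble permutation
importance is exactly zero for redundant informative genes — the rest of the
ensemble compensates — which defeats the pruning ranking; the per-tree
variant keeps redundant-but-informative genes above noise. Each module
always retains at least one gene, and pruning at nested keep-fractions is
nested.

## TMEscore

Within each gene module, PCA on the z-scored genes-by-samples block
(samples as observations); the per-sample component score is the projection
on PC1 plus PC2. Sign conventions, without which the score is not
reproducible across linear-algebra backends:

* each PC is oriented to correlate non-negatively with the module's mean
  expression profile; if that correlation is exactly 0 the positive
  loading-sum orientation applies (logged);
* a module whose mean profile is constant (e.g. an exactly anti-correlated
  gene pair, where no orientation against the mean exists) scores 0, logged;
* a degenerate PC2 (singular value ≤ 1e-10 × the first) contributes 0;
* a 1-gene module falls back to the z-scored gene itself.

Each module's component score is signed by the univariate Cox log-hazard
(Efron ties, Newton–Raphson, convergence 1e-9, ≤ 100 iterations); |beta| <
1e-8 is refused, and a Wald p > 0.5 logs an instability warning. Then

    TMEscore = Σ_{sign=+1} (PC1 + PC2) − Σ_{sign=−1} (PC1 + PC2).

As printed, the formula **adds** the positive-Cox (hazardous) modules, so on
the synthetic cohorts a high TMEscore marks the *high-hazard* group; the
package reports the estimated direction (the continuous-score hazard ratio
per SD) rather than asserting an orientation. The positive and negative
sub-scores (`tmescore_pos`/`tmescore_neg`) correspond to the two
signature-gene sub-scores of the quoted formulation; that mapping is an
inference and is flagged as such.

**Cutpoint.** Maximally selected rank statistics: candidates are observed
score values within the (0.1, 0.9) quantile window; each split (score >
cut) is scored by the standardized log-rank statistic with hypergeometric
variance at ties; the largest |statistic| wins, ties to the lower cut. The
adjusted p-value is the Ornstein–Uhlenbeck crossing (improved Bonferroni)
bound

    p ≈ φ(b)(b − 1/b) log[ ε₂(1−ε₁) / ((1−ε₂)ε₁) ] + 4φ(b)/b

for maximum |statistic| b over the window (ε₁, ε₂), clipped to [0, 1]; an
optional permutation p re-runs the full search on shuffled scores.

## Survival and response

Kaplan–Meier (Greenwood CIs), k-group log-rank and Cox fits go through
lifelines. ROC AUC is the Mann–Whitney concordance with half credit for
ties, computed as a single division of the exact half-integer pair count (so
it equals brute-force pair enumeration bitwise), with a DeLong placement
variance for the CI. The TMB + TMEscore combination fits a two-covariate
logistic model in-sample, uses its linear predictor as the combined score,
and compares nested models (TMB alone vs both) by a 1-df likelihood-ratio
test; quasi-separation falls back to a mild L2 ridge (logged, flagged in the
output). Response is dichotomized CR/PR vs SD/PD; four-level scores are
reported descriptively. The cell-type network pairs Spearman correlations
among fractions (constant columns yield missing values) with per-cell-type
univariate Cox flags (favorable iff HR < 1). The single-gene report applies
Wilcoxon rank-sum tests across receptor-status contrasts (exact at small n
without ties), Spearman correlations against all fractions, and a
median-split KM/log-rank, with BH within the report only. TMB enters as a
precomputed mutations/Mb column; for synthetic data it is generated
directly, and any TMB grouping uses a median split (flagged choice).

## Enrichment

ORA is the hypergeometric upper tail `P(X ≥ overlap)` with the universe
defaulting to the genes of the expression matrix under study — not the union
of the collection — because the choice changes p-values materially; BH runs
across the tested sets. Preranked GSEA uses the running sum with hit
increments ∝ |score|^w (default w = 1, configurable; w = 0 gives the
unweighted statistic) and uniform miss decrements; ES is the signed
extremum. The null permutes gene-set labels (the only permutation scheme
available to a preranked input). NES divides ES by the mean |null ES| of the
matching sign; the p-value is two-sided, comparing |ES| to the full
permutation null — the full null is exchangeable under H0, so the p-value is
calibrated, whereas conditioning on the observed sign at modest permutation
counts is conservative. Sets overlapping the ranking in fewer than 2 genes
are skipped with a warning.

## Problem sizes and limitations

The shipped tests and the acceptance script run cohorts of 120–600 samples,
50 noise-free mixtures of 3–8 cell types, 20–100 seeded replicates for
recovery/coverage checks, and 50–200 consensus iterations — sizes at which
every check completes in minutes on one core while keeping Monte-Carlo
margins comfortable. Known limitations: the batch model is purely additive
location/scale; deconvolution assumes the signature's cell types span the
mixture (no "unknown content" term); the consensus k-selection tie rule
presumes subsample-stable structure; the GSEA weight convention of the
original formulation is configurable but not auto-selected; and none of the
synthetic checks speak to probe-level microarray preprocessing, which the
package does not attempt.
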
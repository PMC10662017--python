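# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical decisions a maintainer would want written down.

## Inputs and containers

The pipeline starts from per-sample taxonomic classifier output (Kraken2
6-column reports or Bracken abundance TSVs) or a prebuilt taxon×sample
count table. The central container, `TaxonCountTable`, couples the
non-negative integer count matrix with (a) a lineage map (taxid → name,
rank, parent) reconstructed from the report's indentation structure, and
(b) each sample's human-aligned read count, which the load filter needs as
a denominator. Clade (not direct) reads are taken at the requested rank so
that per-rank tables are consistent with lineage aggregation, matching the
read-redistribution semantics of Bracken. Aggregation to a coarser rank
conserves per-sample totals exactly; taxa with no ancestor at the target
rank are collected in an explicit `unclassified-at-<rank>` row rather than
dropped.

**Minimum-read rule.** A classifier call supported by too few reads is
noise; entries with count ≤ 5 (strict "greater than five") are zeroed.
The rule is applied per (taxon, sample) entry by default — the
conservative reading, since classification happens per sample — with a
per-taxon cohort-total mode available.

## Decontamination

Four phases, applied in order; sample filters are pure projections (they
never alter retained counts), and every removal is logged with its
statistic.

1. **Microbial load** (default `max_load_ratio = 0.20`): a tumor sample
   whose microbial reads exceed 20% of its human reads is far outside the
   low-biomass regime and is treated as contaminated or mislabeled. The
   comparison is strict, so a ratio of exactly 0.20 is retained.
2. **Small batches** (default `min_batch_size = 10`): batch =
   (sequencing site, preservation method, flow cell). Batches with fewer
   than 10 samples cannot support within-batch contaminant statistics.
   Missing batch fields map to an explicit "missing" token (with a
   warning) rather than failing.
3. **Frequency test** (default threshold p < 0.10, 1,000 permutations): a
   reagent contaminant contributes ~fixed nucleic-acid mass, so its
   *relative* abundance scales as 1/concentration. On log(relative
   abundance) vs log(concentration) over samples where both are positive
   (≥ 5 required, else no call), the contaminant model M1 (slope fixed at
   −1, free intercept) and null model M0 (slope 0) are fitted by least
   squares and compared through λ = SS₁/(SS₁+SS₀). Because SS(y) and
   SS(x) are invariant under permutation of the concentration labels, λ is
   a monotone function of the centered cross-term Σ(y−ȳ)(x−x̄); the
   permutation p-value is computed through this closed form (equivalent to
   refitting both models per permutation, verified in tests, ~100× faster).
   The test runs pooled per cohort; no multiple-testing correction is
   applied inside the screen — 0.10 is a screening threshold, not an
   inference. A permutation reference was chosen over a parametric F
   distribution because it is assumption-free and exactly reproducible
   under a fixed seed.
4. **Deny/spare lists**: plain-text, one name per line, `#` comments.
   Matching is case-insensitive and, by default, at any rank of the
   taxon's lineage (so denying a genus denies its species). Sparing
   overrides denial: `final_contaminant = (statistical OR literature) AND
   NOT spared`. The shipped lists are small editable examples; real
   analyses should substitute curated lists.

## Normalization

**log-CPM with precision weights.** values = log₂((count + 0.5) /
(library + 1) × 10⁶). Per taxon, an OLS fit on the biological+technical
design yields residual standard deviations; √sd is smoothed against
average log₂ abundance by local linear regression (tricube weights, span
0.5, no robustifying iterations — plain local-linear matches the
brute-force oracle analytically and the difference from robustified
smoothing is negligible on clean data). Each observation's weight is the
trend's predicted √sd at its fitted log-CPM, raised to the −4 (i.e.
reciprocal predicted variance), with predictions clamped to the trend's
range at the extremes so weights are always finite and positive.

**Supervised covariate removal.** Per taxon, a weighted least-squares fit
of the values on [intercept | biological one-hots | technical one-hots]
(treatment coding) is computed and the fitted technical component
subtracted, iterating to a 10⁻⁶ max-norm tolerance on the technical
coefficients (≤ 50 iterations). The precision weights are held fixed
during removal by default: re-deriving the mean–variance trend between
iterations makes the estimator weighted in a way that leaves a small
*unweighted* residual group difference even for an exactly planted shift
(≈0.06 on an orthogonal 60-sample design), whereas fixed weights remove a
planted shift exactly on an orthogonal design; `refit_weights=True`
enables the alternating variant. A rank-deficient design (e.g. a
technical variable confounded 1:1 with a biological one) raises an error
naming the aliased columns — silently dropping them would silently change
the model. Flow cell is not a default adjustment variable (only center
and preservation are); it is configurable.

**Relative abundance, rarefaction, prevalence.** Relative abundances are
computed per sample (optionally with the human portion in the
denominator, in which case a "human" row is added and columns still sum
to 1). Presence/absence is derived only from rarefied, decontaminated
counts: each sample is subsampled once, without replacement (multivariate
hypergeometric draw), to the lowest common read depth under a recorded
seed — a single draw, not an average, because presence is a binary call
on one rarefied table. The draw iterates taxa in a canonical sorted
order, so the result is invariant to row ordering. Presence = count ≥ 1
("any read supports presence").

## Clinical association and concordance

**Survival.** Overall-survival days with a death indicator (censoring at
last follow-up, administrative in the simulations). Each taxon's
presence/absence is the single covariate of a Cox proportional-hazards
fit with Efron tie handling (day-resolution times tie often). The
one-parameter partial likelihood is concave, so the fit is a bounded
scalar maximization (|log HR| ≤ 15, xatol 10⁻⁸) of a fully vectorized
Efron log-likelihood; significance is the likelihood-ratio test against
the null model (χ², 1 df). Degenerate inputs — an empty presence group,
no events, or a monotone likelihood from complete separation (detected as
the optimum pinned near the bound) — return a flagged null result, never
an exception, so cohort-scale scans don't die on edge cases. The solver
is cross-checked in tests against both a brute-force grid search of the
partial likelihood (≤10⁻⁴) and lifelines. A multi-threshold variant
re-tests the association with presence replaced by dichotomized abundance
at each quantile of a grid (default 0.1–0.9 by 0.1).

**Continuous covariates.** Age, BMI, hypoxia score, and immune-cell
fractions (deconvolution output consumed as input) are tested by Spearman
rank correlation (average ranks for ties, two-sided t approximation,
pairwise deletion of missing values, ≥ 4 complete pairs required). The
hypoxia metagene score is the median-split form: +1 per signature gene
strictly above its cohort median, −1 otherwise, summed; the gene list is
a user-supplied text file (a synthetic stand-in ships for fixtures).

**FDR and concordance.** Benjamini–Hochberg step-up within each
(cohort, stratum, covariate, rank-level) family — the narrowest
defensible family; null results pass through. The concordance
intersection keeps keys with q < α in *both* cohorts and matching effect
direction (q by default; raw-p mode available). Strata are each cancer
type plus a pooled "all" stratum with no stratification term. Under a
global two-cohort null the intersection multiplies two small
post-correction pass rates, so concordant false positives are rare — the
acceptance suite verifies ≤ 2 hits in ≥ 95% of 100 null replicates at
α = 0.05, and recall ≥ 0.7 with correct signs for 10 planted log-HR-1.0
taxa at n = 300/cohort.

## Microbe–gene networks

Normalized microbe abundances (cancer type preserved as a biological
variable) are correlated with gene expression in both cohorts via a
rank-transform + matrix-product implementation of all-pairs Spearman
(identical to the pairwise call, verified in tests). Pairs whose
correlation sign agrees in both cohorts are retained; edges are the top
and bottom 2.5% of the *validation-cohort* rho among concordant pairs
(signed value, not |rho|; ties at the cutoff are all included). Ranking
on the validation cohort follows from filtering the validation results
against discovery signs before taking extremes; a mean-of-cohorts mode is
configurable. Centralities are computed on the unweighted bipartite
graph: degree (edge count), normalized shortest-path betweenness, and
per-component closeness (harmonic variant available). Σ microbe degrees =
Σ gene degrees = edge count, always.

**Random-matrix null.** Two cohorts of iid standard-normal microbe
(100×100) and gene (1000×100) matrices run through the identical
correlate → concordance → extreme-5% → degree pipeline. Independence
makes sign agreement a fair coin (concordant fraction ≈ 0.5) and edge
count ≈ 5% of concordant pairs; the per-microbe degree histogram is
binomial-like and symmetric (|skewness| < 0.5), in contrast with the
hub-dominated degree distributions of structured data.

**Degree-shape diagnostic.** The discrete power-law tail exponent is the
exact zeta MLE (minimizing n·ln ζ(α, dmin) + α·Σ ln d) with dmin chosen
by Kolmogorov–Smirnov minimization; candidate cutoffs are restricted to
tails holding ≥ 10% of nonzero-degree nodes (floor 10) because the KS
statistic is too noisy on tiny tails to anchor the estimate. The KS
distance uses the Hurwitz-zeta survival function at observed values, so
arbitrarily large hub degrees cost nothing. `heavy_tail_flag` = excess
kurtosis > 1 AND exponent ∈ (1.5, 4), the regime of hub-dominated
empirical networks; applied to the network's full edges-per-node
distribution it is true for planted-hub fixtures (α ≈ 2.1–2.4) and false
for the binomial per-microbe degrees of the random null.

**Enrichment.** Preranked running-sum enrichment: genes sorted by the
ranking statistic, weighted Kolmogorov–Smirnov running sum with weight
exponent 1 on |statistic|, ES = the extreme of the running sum. The null
draws the same number of member positions uniformly from the ranking
(gene-label permutation, default 1,000, seeded); p is one-sided on the
observed ES sign; BH across sets. Sets with fewer than 3 members in the
ranking are skipped. The ranking statistic for a microbe's neighbourhood
is its validation-cohort rho against each gene.

## Synthetic cohorts

The generator emulates the statistical structure the filters and tests
assume, at the study's scale by default: 100 samples, 200 taxa, 1,000
genes, 30 contaminants per cohort.

- **Counts**: negative binomial (dispersion 0.5 — overdispersion typical
  of classifier count tables) with per-taxon occupancy ~ U(0.3, 0.8), so
  presence/absence varies independently of abundance. Baseline means are
  lognormal (median 50).
- **Contaminants**: expected counts ∝ 1/concentration (input RNA
  concentration ~ lognormal(1, 0.6)) with 10% lognormal multiplicative
  noise, present in every sample (reagents hit everything). The
  compositional denominator couples null taxa *positively* with
  concentration — as in real data — which the frequency test tolerates.
- **Batch effects**: a 2⁰·⁵ᵗᵒ²-fold multiplicative shift (default log₂
  effect 2.0) on a random half of taxa for FFPE-preserved samples.
- **Survival**: exponential times with per-sample hazard
  h₀·exp(Σ log HR × presence) (h₀ = 1/1500 days), administrative
  censoring at the horizon giving ~40% events under the null; planted
  taxa get occupancy 0.5 for balanced groups.
- **Hub**: one microbe's log abundance linearly coupled to a gene block
  (Pearson ρ = 0.5 ⇒ Spearman ≈ 0.48).
- **Pairs**: identical planted truths, independent noise, distinct
  sequencing centers — so the cohort label can serve as the technical
  variable when cohorts are normalized together.
- A **truth ledger** records every planted parameter, sufficient to score
  recovery without touching generator internals.

What the fixtures do *not* emulate: real taxonomies and name
distributions, read-level errors, library-preparation artifacts beyond a
multiplicative batch shift, correlated microbe–microbe structure, and
informative (non-administrative) censoring. Passing tests therefore
demonstrate that the machinery recovers planted effects under the stated
noise model — not that any particular real dataset is contamination-free.

## Pipeline and reproducibility

`run_pipeline` executes min-reads → load filter → batch filter →
statistical filter → literature filter → normalization → relative
abundance/rarefaction/prevalence → associations → concordance → network,
per the stage toggles in the config (all on by default, in that order).
Every output table's header embeds the config hash and seed; the
per-phase removal ledger records items and reads removed at each step, so
the read-loss accounting of a run is reproducible from its directory.
Identical config + seed reproduces the run directory byte-for-byte; to
keep that guarantee, timestamps go to stderr only and the in-directory
run log is timestamp-free. All stochastic steps (permutations,
rarefaction, simulation) derive from the single config seed.

Problem sizes in the test and acceptance suites (e.g. 100 null-concordance
replicates at n = 100×200, 20 network-null replicates at the 100×100 /
100×1,000 scale, 1,000 permutations × 200 taxa for the contaminant
screen) were chosen to give stable Monte-Carlo bands; the full acceptance
script completes in about two minutes on one CPU.

## Known limitations

- The statistical contaminant screen needs genuine variation in input
  concentration; with constant concentration it abstains (null p) rather
  than guessing.
- Supervised normalization with categorical covariates cannot separate a
  technical variable perfectly confounded with a biological one; it
  refuses (aliased-column error) instead.
- The Cox model here is single-covariate by design (presence only);
  treatment-conditional or multivariable survival modeling is out of
  scope.
- Deny/spare matching is name-based; taxonomic synonymy is the caller's
  responsibility.
- The power-law exponent of a hub-plus-bulk degree distribution is a
  tail summary, not evidence of a generative scale-free mechanism.
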
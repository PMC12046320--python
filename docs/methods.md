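# Methods

This note documents the models, estimators, defaults, and design choices
behind `carsx`, and what the synthetic validation does and does not
establish about real data.

## Moderated differential expression

For a two-group comparison on a genes × samples matrix (log2CPM or activity
scale), each gene g gets

- log2FC_g = mean(case) − mean(control),
- pooled equal-variance residual variance s²_g on d_g = n₁ + n₂ − 2 df,
- an empirical-Bayes squeeze s̃²_g = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g),
- t_g = log2FC_g / (s̃_g·√(1/n₁ + 1/n₂)) on d₀ + d_g df,
- a two-sided p and the signed normal-scale z = sign(log2FC)·Φ⁻¹(1 − p/2).

The prior (d₀, s₀²) is estimated by method of moments on log s²_g: under a
scaled-F model the residuals e_g = log s²_g − ψ(d_g/2) + ln(d_g/2) have
excess variance ψ′(d₀/2) beyond ψ′(d_g/2); d₀ solves the trigamma equation
by Newton iteration and s₀² follows from the mean of e_g. When the observed
spread of log-variances is no larger than sampling noise predicts, d₀ = ∞
(complete shrinkage to s₀²). This is the standard variance-moderation
estimator for small-replicate designs, and the test suite verifies the full
chain against R/limma's `lmFit`/`eBayes` to ~1e-8 as an independent oracle.
`d0` and `s0_sq` are overridable: `d0=0` reduces exactly to the ordinary
pooled-variance t (verified against an independent computation at 1e-10).

Numerical choices: |z| is capped at 8.21, the magnitude where a
double-precision two-sided p underflows; this keeps downstream Stouffer
sums finite. A gene constant across all samples has no defined t and is
reported with p = 1, z = 0, and a `constant` flag. The pseudocount for
log2CPM defaults to 1 (keeps zeros finite); no expression pre-filter is
applied by default, with `min_mean` exposed for callers who want one.

## Cross-species integration

Ortholog mapping defaults to case-insensitive symbol identity restricted to
1:1 matches (ambiguous case-folded symbols are dropped and logged); an
explicit two-column map overrides it. Anchor selection is three steps:
per-species |z| > 1.96, fold-change sign agreement between species, then
size equalization to min(|human|, |mouse|) keeping the largest |log2FC|
within each species (ties at the cutoff break to the smaller symbol). The
shared anchor set is the intersection of the two equalized lists — the only
definition under which every anchor is a member of both species'
signatures. Overlap significance is the two-tailed Fisher exact test with
the merged gene list as the universe: only merged genes were eligible for
either signature.

The response score z-scales anchor expression gene-wise within each species
(removing location, scale, and species batch offsets), concatenates the
samples, and takes PC1 of the combined matrix (SVD). The PC1 sign is fixed
so the anchor with the largest |loading| has a positive loading — PCA signs
are otherwise arbitrary and tests require determinism. ROC AUC is the
Mann–Whitney statistic (ties 0.5) with a stratified-bootstrap percentile CI
(2,000 resamples, seeded) and an accuracy at the Youden-optimal threshold
reported alongside, since threshold-free and thresholded summaries answer
different questions. For AUC evaluation the score is oriented so the case
group scores higher; this uses the labels once, globally, and is the usual
convention for reporting a separation that PCA returns with arbitrary sign.

The combined ranking is Stouffer's method, (z_h + z_m)/√2, sorted
descending with lexicographic tie-breaks.

## Regulon inference and activity

Mutual information uses the plug-in estimator on equal-frequency (quantile)
bins, natural log, with n_bins = max(2, ⌊√n/2⌋) per axis by default. Ties
are split by stable sort order, so marginals are uniform by construction;
MI is invariant under monotone transforms of either variable, and
MI(x, x) = ln(n_bins) exactly when n is divisible by the bin count.

Network inference, per bootstrap resample of the samples:

1. Driver–gene MI is computed for all pairs on the resampled data.
2. The null threshold comes from permutations of the driver *on the
   original sample axis*, re-indexed by the same bootstrap draw. This
   preserves the duplicate-sample structure of the resample — duplicated
   samples inflate plug-in MI for every pair, and a null that broke their
   alignment would sit far below the observed null pairs, passing
   essentially every edge.
3. α = 0.05 is family-wise per bootstrap: the threshold is the (1 − α)
   quantile of the per-permutation *maximum* MI over genes (100
   permutations). A per-gene 5% threshold is not usable here: chance edges
   are persistent across bootstraps (the resamples share the data), so a
   per-gene null feeds the consensus stage a correlated 5% error it cannot
   remove; the family-wise null keeps the per-bootstrap false-edge rate at
   ~α in total.
4. Surviving edges are pruned by the data-processing inequality: in every
   MI triangle the weakest edge is marked if weaker than both others minus
   a tolerance (default 0, the classic strict rule), and marks are applied
   after scanning all triangles.
5. Consensus over 100 bootstraps keeps edges whose support count k has a
   binomial tail P(Bin(B, α) ≥ k) below `consensus_p` (default 0.01) after
   Bonferroni correction across candidate edges. With one bootstrap and
   `consensus_p=None` the procedure reduces to a single-pass threshold +
   DPI, which the tests exploit.

Edge weight is the mean MI over supporting bootstraps; the sign is the sign
of the Spearman correlation on the full (non-resampled) data, which is more
stable than per-bootstrap signs. Activity is the signed weighted mean:
genes are z-scaled across samples and activity(driver, sample) =
Σ_t sign_t·w_t·z_t / Σ_t w_t. Normalizing by the weight sum (a mean, not a
sum) keeps activities on the z scale regardless of regulon size, and makes
activity invariant to rescaling all weights in a regulon. Whether z-scaling
precedes weighting is a genuine ambiguity in weighted-mean activity
scoring; scaling first is this package's documented choice, since otherwise
highly expressed targets dominate regardless of information content.

Differential activity reuses the moderated two-group machinery on the
activity matrix. Hidden drivers satisfy z_DA > 1.96 and z_DE < 0: the
regulon moves although the driver's own transcript does not. The table is
ranked by z_DA (primary) with a mean-activity ordering emitted alongside,
as both orderings are in use.

## Enrichment

GSEA is the classic running sum over a ranking sorted descending: hits
advance by |statistic|^w (w = 1 by default; w = 0 gives the unweighted,
KS-equivalent form), misses retreat by 1/(N − N_h); the enrichment score is
the largest excursion, clipped to [−1, 1]. Significance is reported two
ways: a gene-label permutation p (random same-size sets; one-sided among
permutations matching the observed ES sign; NES = ES / mean |ES| of
same-sign permutations) and the analytic two-sample KS p on in-set vs
out-of-set rank positions. Gene-label permutation (rather than phenotype
permutation) is the right null here because callers pass a single
precomputed ranking, not the sample-level data. Signed-regulon enrichment
runs the positive and negative target sets separately; when a driver's
activity is higher in the cases, positive targets enrich at the top and
negative targets at the bottom. Gene-set activity is the unweighted mean of
z-scaled member expression and feeds the same differential-activity
machinery (e.g. inflammatory M1 vs anti-inflammatory M2 macrophage
signature scoring).

## Synthetic cohorts

The generators simulate directly on the log2 scale (normal noise around
per-gene baselines drawn from N(7, 2), the typical log2CPM range) because
every pipeline stage consumes log2CPM; a Poisson-thinning export produces
integer counts for testing the normalization path (recovery is exact up to
the per-sample CPM composition constant). Defaults for the paired cohort:
1,000 genes, 20 signature genes, 20 samples per group per species,
driver effect 3 (log2), other signature effects U(0.25, 0.35)×3 with random
sign, species batch offset 1, noise SD 0.5. Heterogeneous signature effects
with a single full-effect driver are deliberate: they are the realistic
condition, and they create a unique strongest shared signal. With a uniform
effect of 3 at these sample sizes every signature gene saturates the z cap
in both species and the combined ranking degenerates into an all-way tie;
the U(0.25, 0.35) range keeps the chance that a non-driver saturates the
cap in both species negligible, so rank-1 recovery of the driver measures
the statistics rather than the tie-break rule. Human symbols are uppercase
and mouse symbols capitalized to exercise the ortholog-matching path.

The regulon population defaults to 200 genes, 2 drivers × 20 targets (40%
negative), 500 cells, noise SD 0.3, and a latent-activity shift of 2 for
the first driver between groups. The driver's own mRNA tracks its latent
activity by default (so the regulon is learnable from expression); setting
`driver_mrna_coupled=False` with a small negative `driver_mrna_shift`
phenocopies a hidden driver. Because such a driver's regulon cannot be
inferred from the cohort in which its mRNA is decoupled, the intended
workflow — mirrored by the pipeline and the validation — infers the
interactome from a separate reference population (coupled, no group effect)
and computes activity on the comparison cohort; `structure_seed` lets the
two populations share the planted regulon layout with independent noise.

A single root seed expands into fixed per-artifact substreams, so each
matrix is individually reproducible.

## What the validation shows — and does not

The test suite and `scripts/acceptance.py` establish: exact equivalence to
independent oracles (pooled t, limma, Fisher-table enumeration,
concordant-pair AUC, brute-force running sums, triangle enumeration for
DPI); calibration under the null (DE type-I error ≈ 5% on 10,000 null
genes; KS enrichment rejection ≈ 5% on random sets); and parameter recovery
at the default conditions (planted driver ranks 1; regulon recall and
precision 1.0 at n = 500; DPI removes the indirect chain edge; the hidden
driver tops the filter). Problem sizes — 1,000-gene cohorts, 200-gene
populations, 25–50 replicate seeds — are the package's chosen validation
scale; rates at that scale carry Monte-Carlo error of a few percent.

The generators do not model count overdispersion beyond Poisson thinning,
single-cell dropout, correlated gene programs outside the planted regulons,
copy-number structure, or cell–cell communication. Passing tests therefore
demonstrate that the estimators are correct and well calibrated under the
stated model, not that real cohorts of a given size will yield the same
recovery rates; on real data the anchor thresholds, bootstrap counts, and
consensus stringency are the knobs to revisit.

## Known limitations

- The ortholog default is symbol identity; paralog-aware mapping requires
  an explicit table.
- The equal-frequency MI estimator is biased upward by ~(B² − 1)/(2n) nats
  for B bins; thresholds are permutation-based precisely so the bias
  cancels between observed and null values.
- The Fisher-overlap universe must be the merged gene list; passing a
  larger universe inflates significance.
- Bootstrap support values are correlated across resamples; the binomial
  consensus is an approximation and is deliberately paired with the
  family-wise per-bootstrap threshold (see above).
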
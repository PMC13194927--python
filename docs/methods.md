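# Methods

This note documents the statistical models, the synthetic-data generator,
numerical choices, and known limitations of `ratioscreen`.

## Data model

The central object is a proteins × samples matrix of log2 label-free
quantification (LFQ) intensities with explicit missingness.  Log2 is the
canonical internal scale; raw-intensity input must be declared with an
explicit flag (`--input-scale raw`) and is never auto-detected, because
silently double-logging a matrix is the classic failure mode of proteomics
pipelines.  Missing tokens on disk are the empty string, `NA`, and `NaN`
(case-insensitive) — nothing else; any other non-numeric cell is a parse
error naming the offending row and column.  Metadata carries a closed
three-level severity label (mild/moderate/severe), a binary POTS flag and
free covariates; sample order is taken from the matrix on load and carries
no meaning afterwards.

## Detection filtering

Proteins are retained when observed in at least ⌈f·n⌉ samples (default
f = 1/3, so 11 of 31).  The ceiling convention matches the "at least a
third of samples" reading for cohorts whose size is not divisible by three.
The filter is idempotent and order-preserving.

## Normalization

Three methods, chainable left to right:

* `median_center` — subtract each sample's median of observed values.
* `quantile` — observed values are mapped onto the mean order-statistic
  profile across samples, with midranks for ties and per-sample
  interpolation when missingness makes column depths unequal.  For complete
  samples this is classical quantile normalization (sorted columns become
  identical — asserted by a test).
* `vsn_lite` (default) — a deliberately simplified variance-stabilizing
  transform: for each sample a two-parameter affine calibration
  (a_s, b_s) is estimated by Huber-robust regression of the sample's
  observed raw-intensity quantiles against a reference (column-median)
  quantile profile, followed by h(x) = arsinh((x − a_s)/b_s)/ln 2.  This
  keeps the defining property of published VSN — the arsinh compresses
  multiplicative noise so per-protein SD decouples from the mean (a test
  asserts the SD-vs-mean rank trend strictly decreases) — while replacing
  the maximum-likelihood fit with an explicit, fully specified robust
  regression.  It is a surrogate, not a reimplementation, of the
  Huber-2002 estimator, and is documented as such.

The normalization report records per-sample affine parameters and the
SD-vs-mean rank correlation before/after, so the variance-stabilization
claim is checkable on any dataset.

## PCA

Samples are projected by SVD of the protein-centered matrix.  Missing
values default to `half_min` imputation (half the protein's observed
minimum, i.e. −1 log2 unit), the standard surrogate for left-censored LFQ
values; `complete_proteins` restricts to fully observed proteins and errors
when fewer than two remain.  Scores are reproducible up to component sign.

## Differential expression

Per protein, OLS on its complete-case samples with design
`intercept + POTS + severity(moderate) + severity(severe)` (treatment
coding, baseline mild).  Severity is an unordered factor because the
contrasts of interest are pairwise level comparisons, not a linear trend.
The POTS contrast from this joint model is by construction adjusted for
severity; no interaction terms are fitted.  Covariate columns constant
across the cohort are dropped; per-protein designs that become rank
deficient (e.g. a severity level entirely missing for that protein) or have
residual df < 3 cause the protein to be skipped with a logged reason.

Variance moderation uses the method-of-moments estimator on log s²: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess variance of e over the
trigamma sampling noise determines d₀ via the inverse trigamma (Newton
iteration), and s₀² follows from the mean of e.  When the observed spread
does not exceed sampling noise, d₀ = ∞ and every posterior variance equals
s₀².  The d₀ = 0 override gives the ordinary t.  A test verifies exact
agreement (d₀, s₀², t, p) with limma's `eBayes` on a complete fixture, and
simulation from the conjugate prior (d₀ = 4, s₀² = 2) verifies parameter
recovery.

Nominal DEP gate: raw p < 0.05 **and** |FC| > 1.5 on the linear scale
(|log2FC| > log2 1.5 ≈ 0.585), both strict.  The linear-scale reading
matches volcano-plot convention; a switch reads the threshold on the log2
scale instead.  BH adjustment is applied within each contrast separately
(the per-contrast convention of limma-style reporting).  The ratio screen
is fed by default with the de-duplicated union of the three severity
contrasts' nominal DEPs.

## Ratio screen

All unordered pairs of the candidate set, canonically ordered
(alphabetical within pair).  Ratios are log2 differences internally; every
statistic used is rank-based, so results are identical to raw-scale ratios
(asserted as a property test).  Per pair:

* complete-case n (both proteins observed); pairs with n < 8 or fewer than
  2 severity groups represented are excluded with a reason code.  The
  min-n default of 8 reflects that with MNAR missingness per-pair n well
  below the cohort size is expected and must be surfaced, not hidden.
* Spearman ρ against severity scored 1/2/3 (fixed encoding), as Pearson on
  midranks; constant inputs are flagged undefined rather than coerced.
* 95% percentile bootstrap CI over 1000 participant-level resamples
  (x and y resampled jointly).  Degenerate resamples (constant series or
  < 3 distinct pairs) are redrawn up to 10 passes then dropped with a
  count; the CI is flagged unreliable when more than half are degenerate.
  Per-pair bootstrap seeds are derived from the pipeline seed and the
  canonical pair name (CRC32), so results are independent of evaluation
  order; the screen also canonicalizes sample order internally, making
  output exactly invariant to input column order.
* Kruskal–Wallis with tie correction, df = non-empty groups − 1 (the mild
  group has few members and can vanish under missingness).

Multiplicity: Storey q-values over all pairs with a defined test p-value,
computed jointly (computing within subsets would change q — callers
restricting the pair universe should be aware the gate shifts with it).
π0 is estimated by the λ-smoother: π0(λ) = #{p > λ}/(m(1−λ)) on
λ = 0.05…0.95, smoothed by a cubic least-squares fit in λ and evaluated at
λ = 0.95, clipped to (0, 1], with fallback π0 = 1 (q ≡ BH) when m < 10 or
the fit is unstable.  The cubic least-squares smoother plays the role of
the natural smoothing spline in the classical q-value implementation with
the same three effective degrees of freedom, without smoothing-parameter
machinery.

Whether the q-gate should act on Kruskal–Wallis or Spearman p-values is
genuinely ambiguous in practice; the default is KW-based q (`q_on="kw"`),
and the audit table always carries both variants.

Report: pairs with q < 0.05 and |ρ| ≥ 0.75, ranked by |ρ| descending, ties
broken by smaller KW p then pair name.  The full audit table (every
enumerated pair with reason codes) is always emitted.

## Enrichment

Right-tailed Fisher per set — hypergeometric upper tail P(X ≥ overlap)
after intersecting each set with the background — and BH across sets.  The
recommended background is the detection-filtered protein universe, since
detection defines what could have been a hit.  The activation z-score is
the simplified direction-consistency form (n_up − n_down)/√(n_up + n_down)
over a set's differential members, sign = predicted activation/inhibition.
Commercial pathway tools implement an edge-weighted causal variant over a
proprietary knowledge base; their result tables are **not** comparable in
content and are not reproduction targets of this module.

## Synthetic-data generator

Defaults emulate the cohort structure the pipeline targets: 31 samples in
severity groups 3/21/7, 9 POTS-positive (independent of severity by
default, configurable dependence), 900 proteins with per-protein log2 means
N(20, 2.5²) and SDs uniform on (0.25, 0.9).  Missingness is left-censoring
at a global intensity threshold — the pooled `censor_quantile` (default
0.13, chosen so ~87% of entries are observed, i.e. roughly 780 of 900
proteins quantifiable per sample) — which makes missingness
abundance-dependent (MNAR): low-abundance proteins fail the detection
filter while per-pair complete-case n varies realistically.  A
`per_protein` censor mode (each protein censored at its own quantile,
homogeneous detection) is available for controlled experiments.

Planted signal, on disjoint protein sets drawn from the above-median
abundance half (reported biomarkers are well-quantified by construction;
planting in the censored tail would silently delete the truth):

* DEP proteins: a fixed log2 shift (default 0.7) applied to the numerator
  group of one contrast.
* Ratio pairs: both proteins share a participant-level random effect and
  split a planted log-ratio ±r/2, where r = step·severity + ε.  The noise
  SD is calibrated by Monte Carlo bisection (400 replicates per evaluation,
  seed derived from the config seed) so the expected Spearman of the ratio
  against severity equals the target; target 1.0 forces ε = 0 and yields
  ρ = 1 exactly.  Sharing the participant effect keeps the pair signal in
  the ratio rather than in the marginals alone.

What the generator does **not** emulate: batch effects, peptide-level
structure, correlated protein modules, non-Gaussian heavy tails, and an
inverse-χ² dispersion hierarchy.  The last point matters for
interpretation: because protein SDs are uniform rather than
scaled-inv-χ², the empirical-Bayes prior is (mildly, deliberately)
misspecified on synthetic data, so moderated p-values are nearly but not
exactly uniform under the null.  Null-uniformity is therefore asserted
exactly on the ordinary-t (d₀ = 0) route, while the moderated route is
asserted through its type-I rate (fraction of p < 0.05 within
[0.03, 0.07]).  Passing tests demonstrate correctness of the machinery
under these conditions, not robustness to everything real CSF data can do.

## Problem sizes used in tests and the acceptance script

Null calibration uses 20 seeds × 2000 proteins with the screen run on
40-protein subsets without bootstrap (the retention gate uses only q and
ρ); recovery uses 20 seeds × 900 proteins with 5 planted pairs and 30
decoys per seed; bootstrap CI coverage uses 200 replicates × 500 resamples
at n = 31; the end-to-end acceptance run uses the full default cohort with
1000 bootstrap iterations.  These sizes were chosen to make the statistical
assertions stable while keeping a full run in minutes on one core.

## Known limitations

* `vsn_lite` is a calibration surrogate; datasets needing the full VSN
  likelihood (strong intensity-dependent variance at the low end) should be
  normalized externally and fed in as log2.
* No imputation is used in the DEP stage (complete-case per protein); with
  heavy MNAR missingness this loses power for low-abundance proteins and
  can bias contrasts toward the observed (higher) intensities.
* Bootstrap percentile CIs undercover slightly at n ≈ 31 and high |ρ|
  (the coverage test budgets ≥ 88% for nominal 95%).
* With only three mild participants, the Kruskal–Wallis test frequently
  degrades to two effective groups under missingness; df follows the
  non-empty group count.
* q-values are computed over whichever pair universe was screened;
  restricting the input set changes q.
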
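# Methods

## Model and hypotheses

For feature *i*, let **s**ᵢ = (s₁(i), …, s_K(i)) be its sample-averaged
expression across the K subtypes (arithmetic mean, linear scale,
non-negative). An ideal marker of subtype *k* satisfies s_k ≫ 0 and
s_l ≈ 0 for l ≠ k, i.e. **s**ᵢ ∝ **ê**ₖ. The test is one-sample: the null
is "**s**ᵢ is not proportional to any unit vector", the alternative is
exact proportionality. The statistic

    t(i) = max_k s_k(i) / ‖sᵢ‖₂

is the cosine to the nearest unit vector. On the non-negative orthant
1/√K ≤ t ≤ 1: the infimum is attained by the constant vector and the
maximum exactly by scaled unit vectors. (A looser bound 1/K < t < 1 is
sometimes quoted for this statistic; the tight lower bound is 1/√K, which
is what the implementation asserts — anything satisfying it also
satisfies the looser bound.) The statistic is invariant to positive
rescaling of **s**ᵢ, so expression magnitude does not influence ranking
and no variance stabilization is required. Argmax ties break to the
lowest subtype index for determinism.

Variants:

* per-subtype statistic t_k(i) = s_k(i)/‖sᵢ‖₂ (no argmax), used for
  subtype-signature ranking and for per-subtype nulls;
* subtype-downregulated statistic
  t(i) = max_k Σ_{j≠k} s_j(i) / (√(K−1) ‖sᵢ‖₂), the cosine against the
  complement-of-k indicator, equal to 1 iff the feature is constant off
  one subtype and zero there. Its printed range in some sources is
  typographically ambiguous, so only the derivable bounds (maximum 1)
  are asserted.

## Workflow

1. **Cleaning.** Features whose mean expression is below `low_cut` in
   every subtype are removed as noise (default `low_cut` = 5th percentile
   of per-feature max subtype mean — data-adaptive and conservative);
   features whose subtype-mean L2 norm exceeds `norm_cut` are removed as
   outliers (default off). All-zero rows are always removed. The norm
   filter applies to the subtype-mean vector because that is the object
   all downstream mathematics uses.
2. **Scoring.** Cosine scores on the cleaned subtype-mean profiles.
3. **Null approximation.** The empirical distribution of scores is
   approximated by a finite normal mixture (FNM) fitted by EM directly on
   the raw scores in (0, 1] — no logit transform, matching how the score
   histogram is read. Initialization is deterministic (means at evenly
   spaced quantiles, equal weights, pooled variance), convergence is
   per-observation mean log-likelihood change < 1e−7, and components that
   collapse below variance 1e−10 are pruned. Default 5 components,
   overridable; a BIC-based selector is available (`select_components_bic`)
   since no principled component count is prescribed. Scores exactly 0
   or exactly 1 are excluded from the *fit* (not from testing): they are
   boundary atoms that a continuous mixture cannot represent — exact 1 is
   the ideal-marker value itself, a measure-zero event under any
   continuous null — and they otherwise degenerate the EM.
4. **Marker calling.** One-sided p-values p = 1 − F_null(t); BH q-values
   (Storey's π₀ variant behind a flag); acceptance at p ≤ threshold and
   optionally q ≤ threshold. A concordance table reports, over a grid of
   p-thresholds, the implied q, the implied minimal accepted cosine (the
   mixture's upper quantile) and the accepted count.

### FDR-guided null fitting

True markers contaminate the score sample, and under the
most-features-are-null assumption they must be excluded from the fit.
Two naive rules fail, and both failures were measured during development:
removing raw p < cut removes its nominal fraction on *every* pass, so on
marker-free data the refitted tail lightens and the loop cascades
(≈19% of null features end below p = 0.01); removing BH-significant
scores only removes nothing, because a 5-component EM *absorbs*
right-tail contamination into a dedicated component, after which no
score is significant. The implemented loop therefore works structurally:

1. fit the FNM on currently retained scores;
2. flag contamination-like components — rightmost, cumulative weight
   ≤ 25%, mean beyond the 1e−3 upper tail of the remaining sub-mixture;
3. compute p-values for all scores from the null-only sub-mixture;
4. exclude scores significant at FDR `p_cut` (BH-adjusted p < 0.01 by
   default) and repeat until the excluded set is identical between
   consecutive passes.

The returned null is the full mixture refitted on retained scores. On
marker-free data nothing is flagged and nothing is BH-significant, so the
result equals the plain fit after one pass, and the p-values are
calibrated (fraction of features with p ≤ α within binomial tolerance of
α for α ∈ {0.01, 0.05}). Contamination well separated from the null
support is excised essentially completely; contamination that overlaps
the null's own upper shoulder is information-theoretically inseparable
from it and stays absorbed — p-values are then conservative near the
tail, and the per-subtype mode (below) is the practical mitigation. An
error is raised if more than half the scores would be excluded.

### Per-subtype nulls

When marker counts are strongly imbalanced across subtypes, one null per
subtype is fitted over t_k of all features and each feature is tested
against the null of its argmax subtype. Markers of other subtypes score
near zero for subtype k, so they stop contaminating its null; measured on
simulated data, recall of minority-subtype markers is unchanged when
another subtype's marker count is inflated tenfold (the inflated subtype
itself pays with conservative calls, as expected when its own markers
swell its null's tail). Pooled mode remains the default.

## Synthetic data generator

The generator emulates subtype-labelled expression profiles:

* **Null (non-marker) features** draw their cross-subtype pattern from a
  mixture of Dirichlet distributions. The default
  (`null_mixture`) combines a broad symmetric Dirichlet(2, …, 2)
  (housekeeping-like genes, 70%) with pair-shared components —
  concentration 2 on a pair of subtypes, 0.3 elsewhere (lineage-shared
  genes, 30% split over all pairs). Two properties motivated this choice
  and are deliberate: the null density vanishes at the simplex vertices
  (a null law that routinely emits ideal-marker patterns would contradict
  its own non-marker labels and put a ceiling on every method's
  measurable power), and a substantial minority of null genes are
  expressed in a strict subset of subtypes, which is both a well-known
  feature of real subtype profiles and the failure mode that separates
  rest-averaging statistics from the cosine. A "complex-null" variant
  adds a component rotated 15° about the simplex center (within the
  sum-one hyperplane, clipped and renormalized) and an asymmetric
  Dirichlet(3, 2, 1.5).
* **Marker features** (default 5%) pick a subtype uniformly and tilt its
  unit vector by an angle uniform in [0°, `mg_deviation` = 15°] along a
  random orthogonal direction, clipping at zero and renormalizing. The
  clipping concentrates part of the deviation budget in a single other
  subtype for about half the markers and leaves about a quarter exactly
  ideal; this is a consequence of the prescribed clip-at-zero mechanism
  and is discussed under limitations.
* **Magnitudes and noise.** Each pattern is scaled by a log-normal
  magnitude (median 100, sdlog 1 — irrelevant to the scale-invariant
  cosine, relevant to ANOVA) and expanded into replicates (default 3 per
  subtype) with multiplicative log-normal noise of coefficient of
  variation `noise_cv` = 0.2. Multiplicative noise preserves exact
  zeros, so fold-change statistics meet exactly-zero denominators; these
  are floored at a machine-epsilon-scaled pseudocount.

Everything derives from a single integer seed; identical configurations
produce byte-identical datasets. What the generator does *not* emulate:
additive background (exact zeros survive), feature-feature correlation,
library-size or batch effects, count noise. Passing tests therefore
demonstrate correctness of the machinery under a clean multiplicative
model, not performance on raw sequencing counts.

## Evaluation harness

Peer statistics implemented for comparison (all scored so that higher is
more marker-like): one-way ANOVA F; max over subtypes of the Welch
t-statistic (subtype vs pooled rest); max one-versus-rest fold change of
subtype means; one-versus-everyone fold change (top vs second subtype
mean); and OVE-sFC, read as the statistically calibrated variant — the
OVE fold change referred to its subtype-label permutation null (200
permutations, seeded; permutation exceedance counts ties toward the
observed statistic so capped values are not outranked, with raw-FC rank
as tie-break). External differential-expression toolchains are not
re-implemented; the comparison is restricted to these self-implemented
statistics.

Accuracy is measured by ROC against the generator's truth, emphasized on
the stringent window FPR ∈ (0.01, 0.05): partial AUC by trapezoid on the
staircase ROC restricted to the window (maximum 0.04), and power as the
interpolated TPR at FPR = 0.05. The benchmark runs the four settings —
standard (K=3, 3×3), more-subtype (K=5, 3×5), more-sample (K=3, 4×3),
complex-null — over seeded replicates and reports means. The default
problem sizes in the test suite and acceptance script are 10,000 features
× 10 replicates for power and ordering runs, 4,000–6,000 features for
unit-level checks; these sizes make the stochastic assertions stable
while keeping runs desk-scale.

Measured outcome: the cosine statistic dominates ANOVA-F, OVR-t, OVE-FC
and OVE-sFC in all four settings and OVR-FC in the K=5 setting; OVR-FC
leads by ~2–3% relative pAUC in the K=3 settings. The discordant features
are exactly the generator's single-subtype-leakage markers (patterns like
(0.97, 0.23, 0)) — genes expressed in *two* subtypes that the truth
labels positive; the cosine down-ranks them by design, rest-averaging
cannot see them. See limitations.

## Marker quality and deconvolution

P1 = 1/(M(K−1)) Σᵢ (Σⱼ sⱼ(i)/max_k s_k(i) − 1) over an M-row candidate
set; 0 exactly for scaled row-permutation-pattern matrices, 1 for
constant rows, invariant to row scaling and permutation. Improvements are
reported as percent relative reductions 100·(P1_ref − P1_new)/P1_ref.

Bulk mixtures B = S·A (pure profiles S, column-stochastic proportions A,
optional multiplicative noise) are deconvolved by non-negative least
squares per bulk column restricted to a candidate marker row set, then
renormalized to the simplex. NNLS was chosen as the minimal,
parameter-free, deterministic estimator. With at least one exact marker
per subtype and zero noise, recovery is exact to solver tolerance —
the operational content of marker-based identifiability. Accuracy is
summarized by entrywise RMSE and mean per-sample Pearson correlation
(Spearman behind a flag); correlation of a constant vector is defined
as 0.

## Numerical choices

* Cosines are computed after dividing each pattern by its maximum, so
  norms neither overflow nor underflow (the statistic is scale-invariant).
* Mixture quantiles invert the CDF by Brent's method on a ±10σ bracket.
* p-value monotonicity, EM log-likelihood monotonicity and
  BH monotonicity are property-tested.
* Fold-change denominators are floored at eps·max(numerator, 1).
* Result tables default to 12 significant digits in the library (exact
  round-trip at that precision) and 6 in the CLI (`--precision`).

## Limitations

* The generator's marker-deviation mechanism (clip at zero after an
  arbitrary-direction tilt) produces borderline positives whose leakage
  sits in a single other subtype; under that labelling, rest-averaging
  fold change can score marginally higher pAUC than the cosine at K=3
  even though it cannot distinguish even from uneven rests. Deciding
  whether such genes *are* markers is a labelling convention, not a
  property of the statistics.
* The FNM null is a smooth approximation to a bounded score
  distribution; p-values beyond the fitted support's edge rely on
  Gaussian tails.
* Contamination overlapping the null's upper shoulder cannot be excised
  by any fitting rule; per-subtype mode mitigates, and reported
  p-values err conservative there.
* No real-data preprocessing is provided: inputs must already be
  sample-normalized and batch-adjusted.
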
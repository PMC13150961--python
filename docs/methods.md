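# Methods

## The measurement and the model

Cortical thickness (CT) is the distance in millimetres between the pial
surface and the gray/white boundary, summarised per region of the
Desikan-Killiany (DK) parcellation (34 gyral regions per hemisphere, 68 in
total).  A *structural covariance network* (SCN) is the 68 x 68 matrix of
inter-subject Pearson correlations of regional CT.  Group-level SCNs carry
no individual information; the *network-template perturbation* approach
recovers it by measuring how much a single subject displaces the covariance
structure of a fixed reference population:

1. reference SCN `r_n` from the n control subjects;
2. perturbed SCN `r_{n+1}` after adding subject k to the controls;
3. differential network `ΔSCN = r_{n+1} − r_n`;
4. edge weight

   `Z = ΔSCN / [ (1 − r_n²) / (n − 1) ]`.

This exact normalisation is implemented as published for the method being
emulated.  It is *not* a standard-error transform (the sampling SD of
`ΔSCN` scales as 1/n, so `Z` retains an O(1) spread); we deliberately do
not substitute a "corrected" variant, because parity with the published
edge weights is the point.  Edges whose reference correlation is exactly
±1 have a vanishing denominator and are masked explicitly rather than
propagated as NaN; downstream tests exclude masked edges and report them.

**Who gets which reference.**  Subjects outside the control group perturb
the full control reference (add-in; reference size n = 37 at the emulated
cohort's scale).  For control subjects themselves, the only construction
that does not degenerate (re-adding a member leaves the correlation matrix
unchanged) is leave-one-out: control k is referenced to the other n − 1
controls.  Published descriptions of the method define individual networks
only for the non-reference groups yet analyse all three groups edgewise;
leave-one-out is this package's documented reading, not an established
convention.

**Edge enumeration.**  A full 68 x 68 grid has 4624 entries, the count
conventionally quoted for this parcellation.  All statistics run on the
2278 unordered off-diagonal pairs: diagonal entries are identically 1
(zero denominator in `Z`), and symmetric duplicates would double the
multiple-testing burden with identical tests.  Both conventions are
exposed (`full_grid`, `unique_pairs`) with bijective flat indexing.

## Edgewise statistics

Per unique pair, a one-way fixed-effects ANOVA across the three groups
(df = 2, N − 3; at the emulated scale 2, 113), Benjamini-Hochberg step-up
FDR over the 2278 tested edges with significance at adjusted p < .001, then
for significant edges pairwise pooled-variance t tests with a Bonferroni
factor of 3 (the pairwise family; .05/3 ≈ .02) and adjusted p capped in
reports at ">.99".  Effect sizes use the identities

    eta² = F·df1 / (F·df1 + df2)
    d    = t·sqrt(1/n1 + 1/n2)
    d CI = d ± 1.96·sqrt((n1+n2)/(n1·n2) + d²/(2(n1+n2−2)))

which reproduce the published three-group table values from printed F/t to
within one unit of the printed precision (the printed inputs are themselves
rounded to 2 dp).  Published post hoc tables print df = n1 + n2 − 3, which
matches no standard two-sample test we can identify; we use the pooled
df = n1 + n2 − 2 throughout, which is also the df under which the printed
d and CI values are internally consistent.  The eta² CI has no printed-form
identity; it is estimated by a bias-corrected percentile bootstrap (2000
resamples within groups).  CI agreement with any published eta² interval is
not asserted.

## Network-based statistic (NBS)

Familywise inference on connected components of suprathreshold edges.
Component statistic is *extent* (edge count), the NBS default.  The null
distribution permutes whole-subject group labels (preserving inter-edge
dependence), recomputes every edge's F, and records the maximum component
size; component p-values use the add-one convention
`p = (1 + #{null ≥ obs}) / (K + 1)`.  The edge threshold mirrors "the
minimum significant F": the smallest F among FDR-significant edges, falling
back to the parametric F quantile at p = .001 when nothing is significant
(the fallback keeps the null graph sparse; measured familywise type-I rate
0.02–0.09 at alpha = .05).  The permutation engine computes per-permutation
F for all 2278 edges via batched group-sum matrix products, so K = 1000
costs ~0.3 s and the study-scale K = 10 000 stays interactive.

## Prediction of weekly gaming hours

Connectome-based prediction in the suprathreshold-selection style: per
outer fold (10-fold, 10 repeats by default; both unpublished for the
emulated study and therefore config), features are min-max scaled to [0, 1]
by training ranges, each edge is tested by Pearson correlation with the
training target, edges with p < .01 are restricted to the largest connected
component on the region graph, and a linear model predicts the held-out
fold.  The estimator is ridge regression with the penalty chosen by inner
5-fold grid search over 5 values including lambda = 0 (plain least
squares); the published description names a linear model with 5 grid-search
optimisation steps but no penalty.  Model quality is the Pearson r between
pooled out-of-fold predictions and observed hours, summarised across
repeats (mean, percentile CI); significance comes from re-running the whole
cross-validation on permuted targets.  Edges accumulate signed
selection-frequency weights (sign = majority training-correlation sign,
ties to positive); thresholding |w| > 0.8 / 0.9 yields consensus
positive/negative networks and per-region nodal degrees.

Folds with an empty selection predict the training mean.  Under the null
this induces a small *negative* bias in cross-validated r (the training
mean anti-correlates with held-out values); at the emulated cohort scale
the bias is negligible (measured mean null r ≈ −0.01), but it is visible
at small n.  Positive null bias would indicate leakage; a dedicated test
verifies each subject's out-of-fold prediction is invariant to their own
target value.

## SVM classification

Pairwise group classification from the differential-edge features: the
full-sample significant-edge set, exactly as in the emulated design — note
this feature selection sees all subjects and is therefore optimistically
biased; we reproduce it faithfully rather than nesting it, and fall back to
the top 30 edges by F (30 = the emulated study's significant-edge count)
when nothing passes FDR.  Leave-one-out cross-validation with per-fold
z-scoring, per-fold mutual-information feature ranking (equal-frequency
8-bin plug-in estimate with Miller-Madow correction, clipped at 0, in
nats; the published estimator is unspecified), optional top-k cutoff
(default: all features), and a linear SVM (C = 1).  AUC comes from pooled
out-of-fold decision values with proper tie handling (equals the
normalised Mann-Whitney U); accuracy/sensitivity/specificity use the
zero-margin threshold with the first-named group as positive class.

Pooled LOOCV decision scores are mutually correlated (any two folds share
all but two training subjects), which inflates the null AUC spread to
SD ≈ 10% at n = 76 versus ~6.6% for independent scores.  Permutation-based
significance of an observed AUC should therefore use the LOOCV-consistent
null, not the U-statistic variance.

## Synthetic cohorts and what they do (not) emulate

The generator produces the *shape* of the emulated cross-sectional cohort:
groups of 39/40/37 (FPS-like, MOBA-like, control), per-region CT as a
multivariate normal `x = 2.5 mm + 0.15 mm · L·eps` with a block base
correlation (8 hemisphere-lobe blocks, within-block rho = 0.45, between
0.10), group effects planted as correlation increments (default: a
connected 12-edge auditory-temporal-to-fronto-parietal-occipital module at
+0.35 for the FPS-like group, giving planted entries ≈ 0.45), and weekly
hours `max(0, 21 + 12·latent + N(0, 12²))` for the FPS-like group, where
`latent` is the subject's mean co-deviation over the planted edges (so
hours are tied to exactly the covariance structure that distinguishes the
group; median ≈ 21 h, consistent with the 11–34 h interquartile band of
committed players).  The MOBA-like group gets hours `max(0, 18 + N(0, 11²))`
with no edge linkage, emulating the null prediction result for that group.
Planted node degree is capped at 3: concentrating many +0.35 increments on
one hub makes the implied matrix strongly non-positive-definite and the
repair (eigenvalue clipping at 1e-6, diagonal renormalisation, repair
distance reported, entries moved > 0.05 warned) would wash the planted
values out.  Everything is reproducible from (config, seed) and a truth
record carries planted edges, increments, repair distances, and latent
scores.

**Limitation — the effect-size ceiling of correlation increments.**  A
subject from a population whose correlation on an edge is rho + delta
shifts the perturbed correlation by only ~delta/n, so group mean `Z`
differences are ≈ delta/(1 − rho²) with within-group SD ≈ 1: at
delta = 0.35 the per-edge standardised group difference is ~0.35.  The
published cohort's per-edge effects (d ≈ 1.1–1.3, eta² ≈ 0.2) are three to
four times larger and would require delta ≈ 0.9 on a 0.1 background —
outside the admissible correlation range.  Effects of the published
magnitude arise instead from *coordinated mean shifts* (a group whose
module regions all sit ~1 SD above the reference has mean co-deviation
≈ 1), a channel this generator intentionally does not include.
Consequently, passing pipeline tests demonstrate correctness and
calibration of the machinery (null rates, oracle agreement, determinism,
no leakage), while planted-effect *recovery* at FDR-corrected thresholds is
weak by construction at delta = 0.35: recovery checks at published-style
thresholds are expected to fail under these conditions and are retained as
honest measurements rather than tuned into passing.

## Numerical and procedural choices

- Pearson correlations: two-pass mean-centred computation; constant regions
  raise with the region named; values clipped to [−1, 1]; perturbed
  networks recomputed from scratch (agreement with an independent
  recomputation at 1e-12 is a test invariant).
- BH adjustment via the standard step-up with enforced monotonicity
  (statsmodels), cross-checked against a hand implementation.
- Components via sparse connected-components, cross-checked against a
  union-find oracle; component ordering: size descending, ties by smallest
  region index.
- Permutation p-values use the add-one convention, never 0.
- Stage seeds derive from SHA-256 of (master seed, stage name), all below
  2³¹; same config + seed reproduces every numeric output byte-for-byte.
- Degenerate cases: constant training targets skip the fold (logged);
  constant decision scores flag AUC = 50% as degenerate; zero-variance
  features scale to 0 under min-max.
- BrainNet-style `.node`/`.edge` exports use approximate MNI display
  centroids packaged with the atlas; they affect rendering only.

## Problem sizes used by the shipped checks

The test suite and acceptance script run at the emulated cohort scale
(116 subjects, 2278 edges) with K = 1000 NBS permutations, 200 prediction
permutations, 60–200 replicates for null calibration and 20–50 replicates
for recovery measurements; the `paper` preset (K = 10 000 everywhere) is
the configuration a full-scale reanalysis would use.
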
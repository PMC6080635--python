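# Methods

## Model and procedure

The package estimates *when* (and through *which* maltreatment type)
childhood adversity is associated with a continuous regional brain signal,
using random-forest regression with conditional inference trees.

**Response scaling.** The signal (a gray-matter eigenvariate β score, or
any continuous response) is centered and scaled to sample mean 100 and
sample SD 10 (`ddof = 1`).  The scale is arbitrary; it fixes the units of
all importance values (squared scaled-signal units of MSE increase) and
makes runs comparable.  The transform is idempotent and commutes with the
analysis entry points.

**Base learner.** At each tree node, `mtry` candidate predictors are drawn
without replacement.  Each candidate `x` is scored against the node
response `y` with the linear permutation statistic `T = Σ xᵢ(yᵢ − ȳ)`;
conditional on the data, permuting `y` gives `E[T] = 0` and
`Var[T] = n/(n−1) · m₂(y) · Σ(x − x̄)²` with `m₂(y) = mean((y − ȳ)²)`, and
the two-sided p-value comes from the standard normal applied to
`z = |T|/√Var`.  Degenerate candidates (zero variance in `x` or `y`)
score `(z, p) = (0, 1)` and are never selected.  The winning variable
(smallest p, ties to the smallest column index) is split at the cutpoint
maximizing the same statistic with the left-child indicator in place of
`x`, over all midpoints between consecutive distinct values whose children
both hold ≥ `min_bucket` cases; ties go to the smallest threshold, and
cases equal to the threshold route left.

**Stopping.** Defaults are `alpha = 1.0` (no test-based stopping — trees
are unpruned and the ensemble controls variance), `min_split = 8`,
`min_bucket = 3`; these suit cohorts of a few dozen subjects and are
configurable and recorded in every report.  When `alpha < 1`, the minimum
candidate p-value is Bonferroni-adjusted (×`mtry`, capped at 1) before the
comparison.  Candidate draws are keyed to the node's position in the tree
(root = 1, children 2k/2k+1) from one per-tree base seed, so stopping one
branch early never changes the candidates any other node sees; a direct
consequence is that lowering `alpha` can only prune, never deepen, a tree.

**Forest.** 200 trees by default, each on a without-replacement subsample
of fraction 0.632, `mtry = 4`.  Aggregation is the unweighted mean of tree
predictions (the classical conditional-forest implementation aggregates
per-case weights; the unweighted mean is simpler, testable, and the
difference is immaterial for the statistics computed here).  Out-of-bag
(OOB) predictions for case *i* average only trees whose subsample excluded
*i*; with 200 trees the probability of a case never being OOB is
0.632²⁰⁰ ≈ 10⁻⁴⁰.

**Importance.** For each tree and predictor, the tree's OOB MSE is
recomputed after permuting that predictor's column among the tree's OOB
cases; the importance is the mean MSE increase over all trees (trees not
using the predictor contribute exactly 0; negative values are reported
untruncated, though bar-chart displays conventionally floor at 0).
`n_perm = 1` permutation per tree by default — the 200-tree average
absorbs permutation noise.  Within one tree and replicate, the *same*
permutation of OOB positions is applied to whichever column is scored:
common random numbers make the profile exactly invariant to predictor
column order and shrink between-predictor Monte-Carlo variance.  This is
*marginal* permutation importance; the conditional variant (permuting
within a partition of correlated covariates) is out of scope, with
consequences discussed under limitations.

**Significance.** The re-randomization null refits the entire pipeline
(forest + importance) `B` times (default 10,000; simulations use 59–500)
on response vectors permuted across subjects.  Permuting the response
breaks every response–predictor association simultaneously while
preserving the strong correlation structure among exposure predictors,
which is exactly the null of interest.  From the `B × p` null matrix:

- `p_max = (1 + #{maxₚ null_b ≥ maxₚ observed}) / (B + 1)` over a declared
  predictor set — the age bins in the timing design ("importance at any
  age"), all five predictors in the type design;
- marginal per-predictor p-values by the same add-one rule, BH-FDR
  adjusted within the tested family (age bins per analysis; within each
  subscale in the symptom analysis);
- the combined-window statistic sums observed importance over a contiguous
  block of age bins and compares it with the null *maximum over all
  same-length windows* within the age-bin block, so the p-value pays for
  the window having been selected at the observed peak.

Add-one estimators are valid (conservative) at any `B`; the attainable
floor is `1/(B+1)`.

**Eigenvariate extraction.** For users starting from a cluster voxel
matrix (subjects × voxels), the signal is the first left singular vector
of the column-centered matrix scaled by its singular value, sign-fixed to
correlate positively with the subject-wise mean.  This is exact for a
rank-1 cluster and stable whenever one component dominates, which is the
regime of a coherent significant cluster.

## Synthetic cohort generator

The generator emulates the exposure structure such analyses face, so the
whole pipeline is testable without clinical data:

- one contiguous exposure episode per subject: onset uniform over the 16
  annual bins (configurable distribution), each following year exposed
  with probability `episode_persistence = 0.98`, truncated at age 16.
  With a uniform onset this geometric episode gives a mean duration of
  ≈ 7.7 years, matching the long exposures reported for such cohorts
  (generator calibration is checked by simulation, mean within 7.7 ± 3);
- type indicators drawn independently at prevalences 7/21, 11/21, 2/21,
  16/21 (physical, emotional, sexual, neglect — multiple types allowed);
  a subject with no type comes up unexposed and their annual record is
  cleared, keeping the marginal prevalences exact without rejection;
- prenatal domestic-violence flag at prevalence 0.25 (no published figure;
  chosen as a plausible minority exposure and configurable);
- response `y = baseline − effect_size · (exposed years in effect_window)
  + type_effect · n_types + N(0, noise_sd)`, default window ages 5–7
  (bins 5 and 6), `effect_size = 1` and `noise_sd = 1` (a 1-SD-per-year
  effect), `type_effect = 0`.  Optional six symptom subscales use the same
  model with the effect sign flipped (symptoms rise with exposure) and
  independent noise streams.

What it does **not** emulate: multiple exposure episodes per subject,
cross-type correlation (config option exists for neither; both default
off), age-dependent type profiles, measurement error in retrospective
exposure reports, or any imaging noise structure — the response is the
already-extracted eigenvariate analogue.  Passing recovery tests therefore
show the machinery detects windows under the stated generative model, not
that any clinical finding is correct.

## Simulation sizes and numerical choices

- Recovery checks: 50 seeded cohorts at n = 200, 200-tree forests; the
  top-importance age bin must fall in ages 4–8 (injected window 5–7) in
  ≥ 90% of runs; likewise `n_types` must rank first under a pure type
  effect.  Both pass at 100% here.
- Test-size checks: 60 outer replicates of a null cohort at n = 60 with
  30-tree forests and B = 59; empirical size at α = 0.05 must not exceed
  0.05 + 2·√(0.05·0.95/60) ≈ 0.106 for the max-importance and
  combined-window tests.
- Tree-oracle checks: 250 random instances with n ≤ 8, p ≤ 3 against
  exhaustive permutation enumeration and brute-force cutpoint search.
  Split choice matches exactly.  The asymptotic normal p-value is compared
  with the exact permutation p-value under an n-dependent tolerance
  (0.55 for n < 6, 0.25 for n ≥ 6): the permutation distribution at n = 4
  has as few as 6 distinct values, so the normal approximation is
  qualitative there; the forest's behaviour depends only on the *ranking*
  of candidate p-values, which the checks confirm on clear-cut instances.
- All randomness descends from integer seeds through
  `SeedSequence(entropy=seed, spawn_key=...)` streams (per tree, per node,
  per re-randomization replicate), making every report and CLI output
  byte-identical across reruns with the same seed.
- Variance guards use an absolute tolerance of 1e-12; constant columns and
  constant responses are treated as degenerate, never split on, and raise
  only where a contract requires it (scaling a constant vector).
- Missing values are rejected everywhere, never imputed.

## Known limitations

- **Null bias of marginal importance under correlated predictors.**
  Exposure duration is by construction the sum of the annual bins, and
  adjacent bins are strongly correlated.  Permuting one such column
  creates off-manifold predictor combinations, which inflates permuted-MSE
  slightly even when the response is pure noise: under the null generator
  a few percent of importances fall outside ±3·SE of zero with a
  systematic positive mean (an independent forest implementation shows the
  same behaviour on identical cohorts; this is the classical argument for
  conditional permutation importance).  Per-tree importances are also
  positively correlated across trees, so SE = per-tree spread/√T slightly
  understates the sampling SD.  Consequently, raw importance z-scores must
  not be used for inference here; the re-randomization p-values are the
  supported inference route, and they are valid because the reshuffled
  null carries the identical bias — confirmed by the empirical size
  checks.
- Asymptotic (not exact) selection p-values in the hot path; exact
  enumeration exists only as a test oracle.
- Small-n caveat: at study scale (n ≈ 21) OOB node sizes are tiny;
  prediction correlations are noisy and importance profiles should be read
  through their permutation p-values, not their point values.
- Regression only; no classification mode, no surrogate splits, no
  multi-level categorical split search.
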
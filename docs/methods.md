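# Methods

This note records the models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic studies do and do not
establish about real data.

## Data model and detection semantics

A feature table is a dense non-negative matrix (features × samples)
with sample metadata (diet, age in days, replicate).  An intensity of
exactly 0 means the feature was not detected in that sample —
left-censoring at the instrument's detection limit — and is
deliberately distinct from "missing": input files with empty cells are
rejected.  This convention drives the whole split of the analysis:
features with any zero within a diet carry information about
*detection* (diversity analysis), features detected everywhere carry
information about *levels* (screen, trajectories, clusters).

Normalization divides each sample by the mean of its spiked internal
standards (when present) and then by the sample's remaining total
signal, in that order; the order is a convention (the two operations
commute only in their effect on shared per-sample factors) and is
recorded in the run config.  Zeros stay zeros.  With the total-signal
step every shared multiplicative per-sample factor — extraction
efficiency, injection volume, biomass — cancels exactly, which is the
point of the procedure.  The `log_display_transform` (zeros → 1e-5,
log10) exists only for heatmaps and is never used in statistics, since
substituting an arbitrary floor for censored values would fabricate
signal.

## Repeated-measures ANOVA screen

Per feature and diet, intensities are log10-transformed (detected
features only, so the transform is well-defined; the generator's noise
model is log-normal, making the transformed errors Gaussian) and
decomposed as SS_total = SS_age + SS_subject + SS_residual on a
balanced ages × replicates matrix, with the replicate batch as the
subject followed across ages.  F = MS_age/MS_residual with
df = (a−1, (a−1)(s−1)); no sphericity correction is applied.
Degenerate inputs are resolved by convention: zero age variation gives
(F, p) = (0, 1); a perfectly additive matrix (zero residual, nonzero
age effect) gives an infinite-F sentinel with p = 0.  Exact-zero sums
of squares are detected with a tolerance relative to SS_total.  The
implementation is vectorized over features and cross-checked in the
tests against a loop-written sums-of-squares oracle and against
pingouin's `rm_anova`.

The default threshold is p < 0.0014 for metabolite tables (an expected
false-positive fraction of 0.14% < 0.2% among null features) and
0.0013 for transcript matrices, which run through the identical code
path.  The optional auto-calibration operationalizes "the transition
between the linear and the exponential rise of the error rate": on a
100-point log-spaced α grid from 1/m to a 0.05 cap it computes
FDR̂(α) = α·m / max(R(α), 1) and returns the grid point of maximum
perpendicular distance to the chord joining the curve's endpoints in
(log10 α, log10 FDR̂) space.  A curve whose median exceeds 0.5 is
treated as signal-free (the cap is returned with a flag); the median is
used because the left edge of the grid is noisy when R is 0–3.  The
reported FDR is the π₀ = 1 plug-in α·m/R — conservative, undefined
(NaN, not 0) when R = 0.

## Concordance permutation test

The concordance statistic is the median Pearson r over matched feature
pairs (the same feature's trajectory in the two diets).  The null
re-pairs feature identities in the second diet uniformly at random;
p = (1 + #{null median ≥ observed})/(n_perm + 1), which is exact-level
for any n_perm.  All pairwise correlations are precomputed once
(row-normalized matrices, one matrix product), so each permutation
costs one gather and a median.  Exhaustive enumeration over all
pairings is available for small feature sets.  Constant trajectories
have undefined r and are excluded with a flag rather than silently
scored.

## Clustering and diet dependence

Replicate-averaged log10 trajectories of the overlapping
age-associated features are z-scored (sample sd, ddof = 1) either
within each diet (shape only) or across the concatenated diets (shape
plus level).  The across-diet matrix is clustered by complete-linkage
agglomeration on Euclidean distance and the tree is cut into exactly
k = 12 groups; cutting a complete-linkage tree is the implemented
semantics, with k-means (fixed seed) as an optional alternative mode.
k is config-exposed and fixed rather than selected by a gap statistic.

Each cluster is classified from its member features' log10 intensities
averaged per sample: at each age, a Student t test (equal variances,
3 vs 3 replicates by default) compares the diets, and an age counts as
"different" only when p < 0.05 **and** the cluster-mean difference
exceeds log10(2).  Progressive = different at all ages, intermittent =
at some but not all, independent = at none.  The twofold effect-size
floor is a deliberate part of the definition, for the same reason
volcano plots pair p-values with fold changes: cluster means over many
features make the replicate standard error arbitrarily small, so a
bare t test eventually flags *any* systematic difference — including
the few-percent level shifts that delayed remodeling produces at
matched ages in clusters whose trajectories are otherwise shared.
Tying "diet-dependent" to a minimal fold change keeps the three
classes about biologically meaningful level differences and makes the
classification stable as cluster size grows.  Both the α and the floor
are config-exposed (`dependence_alpha`, `min_fold`), and a per-feature
granularity is available (`level="feature"`) since the choice between
cluster- and feature-level testing is a genuine design fork; cluster
level is the default because the dependence summary is reported per
cluster.

Dual-scaling PCA treats samples as observations of the feature-scaled
matrix (scaled across diets: samples separate by diet, then age;
scaled within diet: samples order by age regardless of diet).  Score
signs follow the convention that each component's first nonzero
loading is positive.

## Diversity trends, plateau, survival

Diversity (detected count) and total signal are fitted with cubic
polynomials through all replicate points (never through means — the
replicate scatter is part of the fit).  The plateau age is the
smallest root of the fitted derivative inside the observed range with
negative curvature; using the fitted derivative rather than the raw
argmax makes the estimate robust to replicate noise.  The diversity
ANOVA reuses the screen's RM-ANOVA on counts.

Survival utilities work on fully observed cohorts (no censoring):
interval death counts are cohort size times the survivorship
decrement; mean lifespan is the arithmetic mean of death times; the
log-rank test is the standard per-day risk-set chi-square with 1 df
(delegated to lifelines, with a hand-computed hypergeometric oracle in
the tests).  The Gompertz model S(t) = exp(−(a/b)(e^{bt}−1)) is
calibrated by 1-D root finding of the quadrature mean over log a with
b fixed at 0.1/d — mean lifespan is one constraint, so only one
parameter is identifiable — and sampled by inverting the CDF.

## Remodeling-delay curves

Clusters are labeled increasing or decreasing by the sign of the net
change (last minus first age) of their within-diet-scaled mean
trajectories.  For each direction and diet, member features are
z-scored per feature within the diet at replicate level, averaged, and
summarized by a quadratic polynomial fit through all replicate points.
The delay statistic compares the diets' half-change ages.  Because the
curves are z-scored per diet, their absolute levels are not comparable
across diets; the half-change age is therefore defined against each
diet's *own* fitted total change (min-to-max over the observed range,
restricted to the segment before the fitted peak), which is invariant
to any per-diet affine transform and hence to the scaling.  On
noiseless ramp templates the quadratic approximation biases the
half-change-age ratio about 8% low of the planted time-warp factor —
a known, documented distortion of the quadratic summary, not of the
underlying trajectories.

## Synthetic cohort: what is planted and what it shows

The generator emulates the study design the analysis assumes: 2 diets
× 7 ages (days 3, 10, 25, 40, 50, 60, 63 — day 3 is the transfer to
experimental diets, the last group "60–63 d") × 3 replicates, with
mean lifespans 50.8 d (standard) and 64.4 d (defined).  The default
table has 2,000 features per diet, a desk-scale stand-in for the
>15,000 analytes of a real untargeted run; scaling up is a config
change.  Study conditions planted by default:

* **14% age-associated features**, split 50% monotone-up, 42%
  early-monotone-down, 8% mid-life reversal — rises dominate, declines
  start early (lipid-like), reversals are rare.  Templates are linear
  in log10 from day 3 to the plateau age (50 d standard), constant
  after; amplitudes uniform on 0.55–0.9 log10 (3.5–8-fold), the upper
  end matching the observed ceiling of intra-diet changes and the
  lower end keeping the screen near-saturated (noncentral-F power at
  p < 0.0014 is ≥0.98 at the smallest amplitude with σ = 0.1), so that
  the planted *fraction* — not screen power — is what end-to-end
  recovery measures.
* **The delay**: the long-lived diet's template is the short-lived
  template evaluated at t × (50.8/64.4) — the same program traversed
  proportionally later.
* **Diet dependence** among age-associated features: 62% independent
  (no offset), 24% progressive (constant ±0.5–0.8 log10 offset at
  every age; these are exactly the above-twofold features, since
  1 − 0.76 below-twofold = 0.24), 14% intermittent (±0.6–0.75 log10 at
  a single mid age, sized so the lifespan-averaged inter-diet ratio
  stays below twofold).  The three printed rates — 62% independent,
  76% below twofold, 24% above — are therefore mutually consistent by
  construction.  The planted inter-diet ratio of every feature is
  computed from the noiseless templates and stored in the truth table.
* **300 damage-onset features** that sit below the detection limit
  early in life and cross it at an onset age τ ~ U(3 d, plateau),
  rising 0.08 log10/d to a cap 0.6 log10 above the limit (low-
  abundance by design, so they never distort the total signal), with
  no new onsets after the plateau and a slow post-plateau decline
  (0.03 log10/d) that lets the most recent arrivals drop back out —
  detected counts rise, level off, and slightly decrease in late life.
  Onsets in the long-lived diet are delayed by the inverse warp and
  capped at its plateau (60 d).
* **Noise and nuisance structure**: i.i.d. log10-normal replicate
  noise (σ = 0.1); a biomass factor 1 − 0.003·t multiplying all
  endogenous features (total signal declines with age); two spiked
  internal standards (flat, high, not biomass-scaled).  No sample-level
  batch effects are modeled: normalization would cancel them exactly,
  so they would add nothing testable.
* **Lifespans**: Gompertz with b = 0.1/d and a calibrated per diet;
  200 flies per cohort by default (a typical assay size; the source
  design is not fully specified, so this is a documented assumption,
  as is the exact sampling schedule).

Flat features draw baselines over a wide log10 range with a lower tail
near the detection limit, giving realistic sample-to-sample detection
flicker; age-associated baselines are bounded so declining features
never censor.  A global-null configuration (no age-associated
features, no damage features, zero biomass slope) is the reference
null: under it the screen's p-values are exactly uniform and detected
counts are flat in age.

What passing recovery tests shows: the pipeline correctly recovers the
structure it is designed to detect, at the stated design size, under
log-normal noise and left-censoring.  What it does not show: detector
drift or batch structure that normalization cannot remove, unbalanced
or missing samples, correlated features (adducts, isotopes — upstream
deconvolution is out of scope), retention-time artifacts, or
annotation-level chemistry.  Real-data conclusions inherit those
caveats.

## Problem sizes and determinism

Default analyses (2,000 features × 42 samples) fit and report in under
a second; the null-calibration study pools 20,000 features over 5
seeds, and recovery properties average 20 independent studies —
problem sizes chosen so the full suite and the acceptance script each
run in well under a minute on one CPU.  All randomness flows from a
single integer seed through `numpy.random.default_rng`; a fixed seed
reproduces every number in the bundle, and each output table is
stamped with the seed and a hash of the resolved configuration.
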
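# remodelome

Analysis of age- and diet-associated metabolome remodeling in untargeted
LC-MS feature tables, for studies that profile an aging cohort (e.g.
*Drosophila* males on a standard versus a lifespan-extending defined
diet) at several ages with a few replicates per age.

The package asks two linked questions about such data:

1. **How does the *breadth* of the metabolome change with age?**
   A feature with intensity 0 is *not detected* (left-censored at the
   instrument's limit).  The number of detected features per sample —
   metabolite diversity — rises with age as low-abundance species
   (candidate damage products) cross the detection limit, and levels
   off in late life together with the survivorship curve.
2. **How do the *levels* of consistently detected features remodel with
   age, and how does a lifespan-extending diet change that program?**

## Methods at a glance

* **Diversity and mortality.** Per-sample detected counts and total
  signal, cubic polynomial trends, and the plateau age — the smallest
  root of the fitted derivative with negative curvature.  Survival
  utilities: interval deaths, mean lifespan, log-rank test, and a
  Gompertz simulator (hazard a·e^{bt}) calibrated so the integrated
  mean of S(t) = exp(−(a/b)(e^{bt}−1)) matches a target mean lifespan.
* **Age-association screen.** Per feature and diet, a one-way
  repeated-measures ANOVA with age as the within factor and the
  replicate batch as subject, F = MS_age/MS_residual with
  df = (a−1, (a−1)(s−1)).  Features with any zero in a diet are routed
  to the diversity analysis instead of the screen.  Significance at
  p < 0.0014 (≈0.2% false positives among nulls; 0.0013 for transcript
  matrices), optionally calibrated from the knee of the error-rate
  curve FDR̂(α) = α·m / #{p ≤ α}, with the π₀ = 1 plug-in FDR reported.
* **Cross-diet concordance.** Pearson r between the two diets' agewise
  trajectories per overlapping feature; the median r is tested against
  a null that randomly re-pairs feature identities between the diets
  (permutation p = (1 + #{null ≥ observed}) / (n_perm + 1)).
* **Clusters and diet dependence.** Replicate-averaged trajectories are
  z-scored within or across diets, grouped by complete-linkage
  hierarchical clustering cut into k = 12 clusters, and each cluster is
  classified as diet-independent / progressive / intermittent from
  per-age Student t tests with a twofold effect-size floor.
  Fold-change analytics (intra-diet max/min, inter-diet ratio of
  lifespan-averaged means) and dual-scaling PCA accompany the clusters.
* **Remodeling delay.** Mean scaled up- and down-trajectories per diet
  with quadratic fits; the delay statistic is the difference between
  the diets' half-change ages (age at which each fitted curve attains
  half of its own total change).
* **Synthetic cohort.** A generator plants all of the above structure —
  trajectory classes, detection-onset ages, diet-dependence offsets,
  the time-warp delay, Gompertz lifespans — with per-feature truth
  labels, so every stage is testable as a recovery problem without any
  external download.

## Worked example

```python
import remodelome as rm

results = rm.RemodelingModel.from_synthetic(rm.RunConfig(seed=1)).fit()
print(results.summary())
```

```
Metabolome remodeling analysis
==============================================
config bf3307f904de  seed 1  kind metabolite
diets: standard (short-lived) vs defined (long-lived)

Lifespan
  mean lifespan  standard:   51.5 d
  mean lifespan   defined:   65.2 d
  log-rank chi2 153.26, p = 3.36e-35

Metabolite diversity (detected features per sample)
   standard: RM-ANOVA F = 4296.6, p = 2.8e-19; plateau ~ 51.8 d; total-signal slope -1.11e-05/d
    defined: RM-ANOVA F = 19558.8, p = 3.2e-23; plateau ~ none; total-signal slope -2.1e-05/d

Age-association screen (alpha = 0.0014)
   standard: 281/2000 significant (14.1% of all, 1700 eligible), plug-in FDR 0.008
    defined: 260/2000 significant (13.0% of all, 1684 eligible), plug-in FDR 0.009
  overlap: 257 in both diets (24 / 3 diet-specific)

Cross-diet trajectory concordance
  median matched-pair r = 0.949; re-pairing permutation p = 0.0005 (1999 permutations)
  inter-diet fold change below twofold: 79.0% of overlap features

Trajectory clusters (k = 12, hierarchical, complete linkage)
  diet-independent 63.4%  progressive 20.2%  intermittent 16.3%
  increasing signals: half-change at 23.6 d (standard) vs 32.6 d (defined), delay +9.0 d, ratio 0.724
  decreasing signals: half-change at 31.1 d (standard) vs 43.8 d (defined), delay +12.8 d, ratio 0.708
```

Reading the output: the two simulated cohorts differ in survival
(log-rank p ≪ 0.001) with mean lifespans near their 50.8 d / 64.4 d
targets.  Metabolite diversity rises strongly with age in both diets
(RM-ANOVA p ≪ 1e-5) and, in the short-lived diet, levels off near the
planted plateau of 50 d.  The screen declares ~14% of features
age-associated per diet — the planted fraction — and nearly all of them
overlap between diets.  Overlapping features follow concordant
trajectories (median r = 0.95, permutation p = 5e-4), mostly with
below-twofold inter-diet differences (79%, planted 76%).  Clustering
classifies 63% of the overlapping signal as diet-independent (planted
62%), and the delay curves show the long-lived diet reaching
half-change ~9–13 d later, a half-change-age ratio near the planted
lifespan ratio 50.8/64.4 ≈ 0.79.

The same pipeline runs on real data from TSV files (feature matrix,
sample metadata, survivorship) via `RemodelingModel.from_files`, or
from the shell:

```sh
remodelome generate --seed 1 --outdir study/       # synthetic study TSVs
remodelome run --seed 1 --outdir out/ --plots      # full report bundle
remodelome age-assoc --alpha 0.0014 --outdir out/  # screen only
```

All tabular outputs are TSV stamped with the config hash and seed;
`config.yaml` beside them reproduces the run exactly.

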
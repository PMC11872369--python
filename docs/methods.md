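# Methods

This note documents the models and procedures implemented in `suitsurv`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical choices that matter for
reproducing results.

## The question and the measurement scales

The package relates three measurements of the same species in a novel
region, each on a three-level ordinal scale (unsuitable < marginal <
optimal):

- **HS** — ensemble-mean habitat suitability from presence–background
  models trained on the species' native occurrences and projected onto the
  target region, averaged per district. Classes: HS < 0.3 unsuitable,
  0.3 ≤ HS < 0.6 marginal, HS ≥ 0.6 optimal. Boundary values go to the
  upper class (the intervals are stated without boundary rules anywhere
  authoritative; one convention is fixed and tested).
- **SR** — the fraction of cultivated individuals surviving a fixed period,
  SR = 1 − MR, where MR counts only deaths attributed to climate or
  unknown causes. Individuals dying of excluded causes (pest, mechanical,
  horticultural) stay in the denominator — they existed — but not the
  numerator.
- **SSR** — SR standardised against locally native congeners:
  SSR = (SR − SRμ)/σ with SRμ and σ the mean and *sample* (n−1) standard
  deviation of the native species' SRs in the same region (the estimator
  is not specified in the source material; n−1 is the conventional
  choice and makes native SSRs sum to exactly zero). SR classes:
  SR < 0.1 → unsuitable regardless of SSR; SSR ≥ −2 → optimal; otherwise
  marginal. SSR above +2 is still optimal: surviving *better* than natives
  is not penalised.

Comparing HS class to SR class ordinally yields the verdict: **agree**,
**over** (HS above SR — the model promised more than the plants deliver)
or **under** (HS below SR — the species persists where the model said it
could not).

## Synthetic data

The generators produce inputs with exactly the statistical structure the
downstream stages assume, with known ground truth:

- **Environmental layers.** Gaussian random fields with *exponential*
  covariance, synthesized spectrally (FFT on the grid torus), standardized
  to zero mean and unit variance, then mixed by the Cholesky factor of a
  target correlation matrix. `autocorr_range` (km) is the effective range
  (correlation ≈ 0.05); because the block-size estimator in the modelling
  stage fits an exponential variogram, its recovered range is directly
  comparable to the generating parameter (recovered 17–27 km for a true
  20 km on a 200×200 grid). A Gaussian-kernel smoothing construction was
  considered and rejected: its Gaussian-shaped correlogram biases
  exponential-variogram fits upward by a factor of 3–6, making the
  generator's nominal range meaningless to the estimator that consumes it.
  Fields are periodic (spectral synthesis); at desk scales this is
  invisible to every consumer.
- **Virtual species.** Suitability is a product of per-layer Gaussians,
  exp(−(x−μ)²/2b²); occurrences are cells drawn without replacement
  (Gumbel top-k) with probability ∝ suitability × bias^strength, where the
  bias surface is itself a smooth random field squashed through a
  logistic — emulating clustered collection effort. One record per cell,
  at the cell centre, so 1-km thinning has work to do only when bias
  clusters records.
- **Inventories.** Each individual survives with probability
  logistic(baseline + section effect + garden effect); deaths draw a cause
  from a fixed mix (climate 0.45, unknown 0.25, pest 0.15, mechanical
  0.10, horticultural 0.05 by default — weighted towards the causes the SR
  filter keeps so the filter is exercised). The period is metadata only;
  SR is a single period aggregate and no within-period event times are
  simulated.

What the generators do **not** emulate: realistic climate geometry,
dispersal limitation, demography or reproduction, temporal climate trends
(e.g. late-period heatwaves), spatially varying inventory effort, or
taxonomic error. Passing tests therefore demonstrate that the *methods*
are implemented correctly and behave as designed under their own
assumptions — not that the real-data conclusions would reproduce.

## Occurrence prep

- Cleaning drops, in order: non-finite coordinates; out-of-bounds lon/lat
  (geographic data only); the exact (0,0) artefact; exact duplicates
  within species; and optionally points in non-terrestrial cells. Per-rule
  counts are reported and logged.
- Thinning removes the record with the most neighbours within the
  thinning distance, breaking ties uniformly at random, until no pair is
  closer than the distance; 10 replicates by default, keeping the one
  retaining the most records. The heuristic is greedy, not optimal; on
  instances of ≤ 12 points it stays within one record of the brute-force
  optimum (tested). Distances are great-circle for geographic data,
  Euclidean for planar.
- Variable selection computes Pearson correlations on ≤ 10,000 random
  valid cells (seeded) and greedily drops, from the worst-correlated pair
  at or above the 0.70 cutoff, the variable with the larger mean absolute
  correlation to everything still in play (the caret convention).

## Niche overlap

The environmental space is the first two principal components of the
standardized, pooled background cells; the occupancy grid is 100×100 over
the min–max of the background scores. Occurrence and background scores are
kernel-smoothed with Gaussian kernels (Scott's rule per axis, computed per
sample) via binning + Gaussian filtering — numerically a grid-evaluated
KDE, fast enough for permutation testing. The occupancy density is
availability-corrected, z ∝ o/e where e > 0 (and 0 elsewhere), then
normalized; an uncorrected variant is available (`corrected=False`) since
the exact correction used by any given toolchain is rarely verifiable.

Schoener's D and Warren's I compare two such densities; both are 1 for
identical densities, 0 for disjoint support. The background similarity
test redraws each species' occurrence count uniformly from its own
background (99–100 replicates), one-sided for "more similar than chance",
with the add-one convention p = (1 + #{null ≥ observed})/(n + 1).

Both one-sided directions are computed. The *directional* tests are the
calibrated objects — with species 2 truly random, the direction that
randomizes species 2 rejects at ≈ 3–5% at α = 0.05 (measured over 200
null datasets). The headline p reported per metric is the **less extreme**
(larger) of the two directions; it is conservative by construction and its
type-I rate under a fully null pairing is ≈ 1%. Consumers wanting a
calibrated single test should read `p_D_directional` /
`p_I_directional`.

## Habitat-suitability models

- **Training region**: cells within 200 km of any occurrence (exact
  Euclidean distance transform on planar grids; haversine otherwise),
  intersected with valid data.
- **Pseudo-absences**: 5 replicate sets. *G.E.* draws uniformly from the
  training region outside exclusion disks around occurrences. *E.S.* fits
  a robust Mahalanobis envelope to presence environments (minimum
  covariance determinant location/scatter, χ² cutoff at the 0.95 quantile)
  and draws uniformly from in-region cells outside it. The envelope is a
  deterministic, dependency-light one-class boundary with a coverage
  guarantee (0.95 ± 0.03 on multivariate-normal data at n = 5000, tested);
  a one-class SVM could sit behind the same contract.
- **Model**: L1-penalized logistic regression of presence vs
  pseudo-absence on standardized linear + quadratic + pairwise-product
  features. This is the feature set under which penalized logistic and the
  MaxEnt family's logistic output coincide (maxnet equivalence);
  replicating any specific MaxEnt release bit-for-bit is a non-goal — the
  accuracy surface here is parameter recovery on virtual species
  (Spearman ≈ 0.98 between predicted and true suitability at 300
  occurrences on a 200×200 grid) and the block-vs-random contrast below.
  Pseudo-absences are down-weighted so total class weights are equal. The
  penalty is chosen from {0.01 … 3} (inverse strength C) by deviance on an
  internal 80/20 split, then the model is refit on all training data. The
  bounded grid doubles as the guard against complete separation.
- **Cross-validation**: the *random* strategy holds out 25% of presences
  and pseudo-absences per run. The *block* strategy tiles square blocks —
  sized by the median, across layers, of exponential-variogram effective
  ranges fitted to ≤ 2000 sampled in-region cells — and assigns them to
  k = 4 folds greedily (largest presence count first, into the currently
  smallest fold, random ties). Ten runs per strategy: block cycles its 4
  folds and re-randomizes the block-to-fold assignment each full cycle;
  random draws 10 independent splits. With 5 pseudo-absence replicate
  sets this yields the canonical 10 × 5 = 50 models per strategy
  combination. Oversized blocks fall back to k vertical strips with a
  warning; white-noise layers collapse the block size to the cell size.
- **Evaluation**: AUC as the Mann–Whitney rank statistic (ties count ½) —
  invariant to monotone transforms of the predictions; TSS maximized over
  the fixed threshold grid {0.00, 0.01, …, 1.00} with the maximizing
  threshold reported. Constant predictions give AUC 0.5, TSS 0.

**Transferability contrast.** On spatially autocorrelated worlds
(exponential range 30 km on a 100-km grid, 300 biased occurrences, 8 CV
runs × 2 PA replicates per strategy), mean validation TSS under block
partitioning is below the random-split value in 17 of 20 replicate worlds
(mean deficit ≈ 0.01–0.02; one-sided sign test p ≈ 0.001): random splits
flatter the model's transfer performance. The effect is small and
consistent rather than large — with fewer CV runs per world (4) the
within-world noise dominates and the sign test loses power, which is why
the replicate design uses 8.

## Projection and alignment

Ensemble projection is the cellwise arithmetic mean of member predictions
(NaN propagates); district aggregation averages HS over cells whose
*centres* fall inside the polygon (cell-centre membership, no area
weighting — deterministic and resolution-honest at 1-km cells). Verdict
counts are conserved by construction: agree + over + under equals the
number of (configuration, region) comparisons.

## Phylogenetic section tests

Per garden, each section's SRs are compared against all other species by
Mann–Whitney U. For combined n ≤ 20 the test is exact by full enumeration
of C(n, m) group assignments over the actual value multiset (ties handled
by counting wins + ½ ties); the two-sided p doubles the smaller tail,
capped at 1. Larger samples use the tie-corrected normal approximation.
With n = 4 vs 6 the smallest achievable exact two-sided p is
2/210 ≈ 0.0095 — stars beyond p < 0.01 are unattainable at these sample
sizes, so claims are made at the 0.05 level. Species missing at a garden
are excluded pairwise, not listwise. No multiple-comparison correction is
applied across the 3 sections × 3 gardens; the output notes this.

## Configuration, seeding, determinism

One YAML config drives everything; all defaults are pre-filled so
`run-all` works out of the box on the synthetic world. A single
`master_seed` fans out to stages and replicates via
`numpy.random.SeedSequence(master, spawn_key=(stage, …))` counters; no
stage consumes global randomness, and the solver seeds of the underlying
library fits are pinned. A run directory's `manifest.json` records the
parameters actually used and a SHA-256 of every output; re-running a
config reproduces all hashes byte for byte (tested, including through the
GeoTIFF writer).

### Desk-scale defaults

Analysis constants keep their canonical values (correlation cutoff 0.70,
200-km training buffer, 5 PA replicates, k = 4, 25% hold-out, 10 CV runs,
100-ish permutations, HS thresholds 0.3/0.6, SSR window ±2, minimal SR
0.1). Scale-*dependent* sampling sizes are set to the synthetic world's
100-km extent rather than a continental one: 100×100 1-km cells,
200 occurrences per species, 800 pseudo-absences with a 5-km exclusion
radius (continental analyses would use 5,000–10,000 PAs and 10–30-km
exclusions; those values scale with extent, not with the method). The
acceptance experiments state their own sizes: a 200×200 world for
suitability recovery, 200 null datasets × 99 permutations for test
calibration, 20 replicate worlds for the block-vs-random contrast.

## Known limitations

- The presence–background model implements linear/quadratic/product
  features only (no hinge/threshold classes, no cloglog output, no
  multi-algorithm ensembles).
- Reprojection and raster resampling beyond nearest-neighbour lookup are
  out of scope; all layers must already share one grid (checked).
- The niche space is strictly two principal components; niche equivalency
  (identity) testing is not implemented.
- SR is a period aggregate; no time-to-event modelling.
- The synthetic world's realism limits are listed above; in particular,
  real-data AUC/TSS levels and real niche-overlap values depend on data
  this package deliberately does not fetch.
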
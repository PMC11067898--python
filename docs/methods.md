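# Methods

This note documents the models and procedures `nichekit` implements, the
defaults and why they were chosen, the numerical choices that matter, and
what the synthetic-data tests do and do not demonstrate about real data.

## Occurrence preparation

Records pass through a canonical sequence: coordinate-uncertainty filter,
locality dedupe, breeding-window date filter, accessible-area (M) clip,
spatial thinning. Choices:

- **Uncertainty filter** removes records with stated uncertainty
  *strictly greater than* 10 km (the boundary is kept); records without a
  stated uncertainty are retained by default, since dropping them would
  discard most community-science data. Both behaviors are configurable.
- **Dedupe** keys on (taxon, lon, lat) rounded to 1e-4° (≈ 11 m) and
  keeps the earliest-dated record per site.
- **Breeding windows** default to April–July north of the equator and
  October–January (wrapping the year boundary) south of it; residents are
  exempt. Dateless records are dropped for migrants and kept for
  residents. Per-taxon month lists override the defaults.
- **Thinning** is greedy over a seed-shuffled visit order: a record is
  accepted iff it lies ≥ the threshold (great-circle, haversine, Earth
  radius 6371 km) from every accepted record. This guarantees the
  pairwise separation constraint, is maximal (every rejected record is
  within the threshold of an accepted one), and is reproducible given the
  seed. The step order (thin last) is a package decision; thinning is
  order-sensitive in principle, so the prep log records every step count.

## Environmental space

Layers are co-registered grids (cell-center addressed, row 0
northernmost) with NA propagated by union across layers, so every non-NA
cell carries a complete environmental vector. Rasters are read and
written as ESRI ASCII grids; grids must share a lattice and are cropped
to their common overlap (no resampling or reprojection). Values at
occurrence points use nearest-cell-center lookup; points on NA cells are
dropped and counted.

PCA variable importance uses correlation-matrix PCA by default
(environmental variables carry incommensurate units; covariance-mode is
available) and reports the percent contribution of variable v to
component c as 100·loading²(v,c)/Σᵥ loading²(v,c). PCA here is a
reporting tool; niche models are fit on the raw retained variables
(fitting on leading PCs is possible by transforming inputs upstream).

## Ecopopulation clustering

LDA assignment accuracy is reported as a resubstitution confusion matrix
in row percentages — the same rows used for fitting are predicted back,
matching how such accuracies are conventionally quoted; priors default to
group proportions. Groups smaller than the dimension trigger automatic
covariance shrinkage. The gap statistic follows Tibshirani's original
form: B = 100 reference sets drawn uniformly over each feature's observed
range, Gap(k) = E*[log Wₖ] − log Wₖ, se(k) = sd_b(log Wₖ⁽ᵇ⁾)·√(1+1/B),
and the one-standard-error rule (smallest k with Gap(k) ≥ Gap(k+1) −
se(k+1)). k-means uses 25 restarts, all seeded.

## Ellipsoid niche model

`fit_mve` implements the classic resampling estimator of the minimum
volume ellipsoid: draw (d+1)-point subsets (all of them when there are no
more than `n_subsets`, otherwise a seeded random sample), and for each
subset scale its covariance C by the h-th smallest squared Mahalanobis
distance s of all n points (h = ⌈inclusion·n⌉); the candidate minimizing
det(s·C) wins, giving center = subset mean and shape = s·C. By
construction at least h calibration points satisfy
(x−c)ᵀ(s·C)⁻¹(x−c) ≤ 1. Numerical choices:

- Subsets whose covariance determinant is below 1e-12 × the product of
  the data variances are discarded as degenerate; an all-degenerate set
  (collinear data) is an error, as are n ≤ d and identical points.
- No chi-square consistency rescaling is applied: the ellipsoid is used
  geometrically (a coverage region), not as a covariance estimate.
- The fit is exactly reproducible given the seed, and distances are
  invariant under affine reparameterization of the environmental axes.

**Suitability** is exp(−d²/2) — monotone decreasing in distance, 1 at
the center, bounded in (0,1], and proportional to a multivariate normal
density. A linear 1−d/d_max alternative exists behind a flag. Because
Schoener's D is computed on sum-normalized surfaces, the choice of
monotone transform does affect D's numeric value; it is therefore fixed,
documented, and configurable.

**Thresholds.** Occurrence distances are right-skewed, so a Gamma is fit
by maximum likelihood (location fixed at 0) and binary maps use its
inverse CDF at 75/85/90/95/99% inclusion. Zero distances are jittered up
by machine epsilon (logged); constant distances and n < 5 are errors.

## Equivalency testing

- Observed D compares the two taxa's suitability surfaces normalized
  over the **union of their Ms' non-NA cells** — symmetric, and covering
  all environments accessible to either taxon.
- Each null replicate draws n points uniformly *without* replacement
  from the other taxon's M cells, refits the ellipsoid, and recomputes D
  on the same extent; n defaults to the occurrence count of the M's own
  species (equal sampling effort). Null fits use a reduced resampling
  budget (500 subsets versus 5000 for observed models) to keep 100-rep
  nulls tractable; singular replicate fits are retried up to 10 times.
- p = (1 + #{null ≤ D_obs})/(N+1): the add-one correction avoids p = 0
  and makes both tails reachable at N = 100; ties count fully into the
  lower tail, which is conservative for divergence claims.
- Scores: −2 if both p < α/2; +2 if both p > 1−α/2; ±1 if exactly one
  tail is reached and the other p is central; 0 otherwise. The
  contradictory case (one p in each tail) scores 0 and raises a conflict
  flag.

## Ancestral niche reconstruction

Bin tables use equal-width bins (default 20) spanning the union of all
taxa's M value ranges per variable. A taxon's occupied interval is the
[trim/2, 1−trim/2] quantile range of its occurrence values (5% total trim
by default, mirroring the ellipsoid's outlier tolerance; 0 disables). A
bin overlapping the occupied interval is *present*; a bin wholly outside
the taxon's M range is *uncertain* (inaccessible environments carry no
evidence); remaining bins are *absent*. Absent bins strictly between
present bins are recoded present, so each taxon's niche is one contiguous
run — niches are assumed interval-shaped per variable.

Missing taxa are grafted onto the tree as sister to a designated tip,
with a new node at the midpoint of that tip's terminal branch (the
alternative reading — midpoint of the path to the root — is not
implemented).

Reconstruction is parsimony: Hartigan's generalization of Fitch (exact on
polytomies), uncertain tips treated as missing (compatible with both
states), two passes (postorder state-set construction, preorder
resolution), nodes with non-unique sets labelled ambiguous. The summed
per-node deficits equal the minimum change count (verified against
exhaustive enumeration in the tests). Branch gains/losses count only
resolved parent→child flips; a terminal branch with more losses than
gains is flagged contraction-dominated — the signature of a descendant
occupying a subset of the ancestral niche. A maximum-likelihood Mk-model
option is a recognized non-goal for this version.

## Synthetic worlds

The simulator defines virtual species directly in environmental space
(a true ellipsoid), so the ground truth coincides with the estimand of
`fit_mve` and recovery tests are well-posed. Defaults — chosen once as
the study conditions for all calibration experiments:

| parameter | default | meaning |
|---|---|---|
| taxa | 2 | one pair per world |
| occurrences / taxon | 100 | sample size per species |
| raster | 100×100 cells | landscape size |
| layers | 3 | environmental dimensionality |
| smoothness | 5 cells | Gaussian kernel radius of the random fields |
| niche width | 0.5 SD | ellipsoid axis scale in standardized env units |
| divergence offset | 4 Mahalanobis units | > 2× the scaled radius, so true ellipsoids are disjoint |
| Brownian step | 0 | optional center jitter per unit branch length |

Layers are smoothed white noise standardized to mean 0, SD 1.
Accessible areas are disjoint vertical strips (allopatric ranges).
Occurrences are drawn uniformly from the cells of a taxon's M whose true
distance falls within a cutoff radius (the 0.95 chi-square quantile
scaled against the model's 0.90 inclusion level, ≈ 1.1× the boundary),
with sub-cell jitter. Scenario geometry: *conservatism* copies the root
niche to every tip; *partitioning* recursively splits the parent
ellipsoid into two disjoint half-radius sub-ellipsoids along a random
direction (all descendants contained in the ancestor); *divergence*
displaces one tip's center along a random direction. Worlds in which a
taxon's true niche has almost no suitable accessible cells (fewer than
3(d+1)) cannot host that species; the niche-direction draw is then
retried, deterministically and at most 20 times.

What the simulator does **not** emulate: real covariance structure among
climate variables, spatial sampling bias, coordinate error, taxonomic
misidentification, or realistically shaped Ms. Passing calibration tests
therefore show that the machinery is correct and well-calibrated under
idealized allopatric conditions, not that any real pair of species has or
lacks divergent niches.

## Calibration experiments and problem sizes

Two canned experiments (module `nichekit.experiments`) back the
statistical claims, at sizes chosen to give stable Monte-Carlo estimates
on a single CPU:

- **Error calibration / power**: 50 independent two-taxon worlds per
  scenario, 50 null replicates per direction, 100 occurrences per taxon.
  Under conservatism the −2 rate estimates the false-divergence rate
  (observed ≈ 0 at the default cut points, against a nominal 0.025²-level
  compound test); under divergence it estimates power (observed ≈ 0.9).
- **Center recovery**: mean MVE center error at n = 25/100/400
  occurrences, 30 paired worlds per n, on a 160×160 landscape so the
  pool of distinct suitable cells does not floor the error, with the
  resampling budget scaled as 50·n (robust-covariance implementations
  conventionally scale subset counts with n). Errors decrease with n,
  as consistency predicts.

## Known limitations

- The MVE is approximate (resampling), so very small `n_subsets` can
  miss the optimum; all-subset enumeration kicks in automatically for
  small problems.
- D is computed over grids; two models compared on different extents are
  not comparable, and the union-of-Ms extent is a documented choice, not
  the only defensible one.
- The published score-matrix data object supports bookkeeping tests
  only; reproducing the underlying real-data analysis would require the
  original occurrence and climate downloads, which are out of scope.
- Reconstruction treats bins independently; no rate model or
  branch-length information is used beyond tree topology.
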
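# Methods

This note records the models, estimators, defaults and numerical choices
behind `lgclust`, and what the synthetic fixtures do and do not establish
about real data.

## Point patterns and validity domains

A pattern is an n × 2 array of planar metric coordinates. Geographic
lon/lat input is rejected (all distances are Euclidean; users must project
first). A validity domain is a polygon with holes; membership uses the
closed-set convention (boundary points are inside) because gridded cell
centres can fall exactly on borders. CSR reference patterns are simulated
by rejection sampling from the domain's bounding box, which is exact for
arbitrary hole geometry; the acceptance probability equals the
domain-to-bbox area ratio, so heavily perforated domains cost proportionally
more draws but no accuracy. No edge corrections are applied anywhere:
boundary effects are handled by *comparing* the observed pattern to CSR
simulated in the same domain, so both carry the same bias.

## Fractal dimensions

**Box counting.** Grids of cell edge `l` anchored at the bbox minimum
corner; `N(l)` = occupied cells; the dimension is minus the OLS slope of
`ln N` on `ln l`. Default scales are 12 dyadic subdivisions of the longer
bbox side. The fit excludes:

* saturated scales with `N(l) ≤ 1` (whole pattern in one cell), and
* undersampled scales where the mean occupancy `n / N(l)` falls below 10
  points per occupied cell. Below that occupancy the grid resolves
  individual points and `N(l)` flattens toward `n`, biasing the slope low:
  for a chaos-game Sierpinski sample with n = 10⁵ the unguarded fit reads
  ≈ 1.44 instead of log3/log2 ≈ 1.585. The threshold of 10 is the usual
  order-of-magnitude sampling guard; if the guards leave fewer than two
  scales they are relaxed (undersampling first), and a single isolated
  point reports dimension 0 by convention.

**Sandbox counting.** For every point, the number of *other* points within
a closed ball of radius R (the paper-standard "count the others" convention;
closed vs open is immaterial for continuous coordinates). The mean over all
centres versus R on log-log axes gives the sandbox dimension. Counts use a
KD-tree pair count, so the n = 10⁵ calibration runs in seconds. Radii must
be small relative to the domain (the fit range is the user's scaling
window); for CSR in the unit square the boundary deficit is `O(R)` and
contributes ≈ −0.01 to the slope at R ≤ 0.05.

**Log-log fits.** Plain OLS on natural logs restricted to positive values,
with the retained scales recorded in a mask; exact on perfect power laws.
`r²` is reported only when ≥ 3 points enter the fit.

## Local growth curves (LGC)

The LGC matrix holds per-point closed-ball neighbour counts on a strictly
increasing radius grid (default: 25 geometric radii from 300 to 10 000
length units — the scale window of settlement-pattern analysis at 100 m
cell resolution; both endpoints included). Rows are non-decreasing by
construction, and column means equal the sandbox mean counts exactly (the
global estimator is the row-average of the local ones).

**Local fractal dimension.** Per-row OLS slope of `log N` vs `log R` over
radii with `N ≥ 1`; zero counts are dropped rather than offset by +1, which
would bias small-radius slopes. Rows with fewer than three usable radii are
flagged invalid (NaN), never silently zeroed; invalid rows are excluded
from dimension histograms but keep their (well-defined) count features for
clustering. Local slopes can legitimately exceed the embedding dimension 2.
The masking policy is shared with the global sandbox fit so local and
global dimensions are comparable. Note the local fit is only meaningful
when the smallest radii see O(1) or more neighbours; far below that the
`N ≥ 1` conditioning biases slopes low.

**Preprocessing.** Default `log1p` then per-column z-score for clustering
(raw counts span orders of magnitude and would let the largest radius
dominate Euclidean distances); raw counts are kept for profiling.
Zero-variance columns are dropped under z-scoring with a warning. The
transform is recorded in the feature matrix for reproducibility.

**PCA summary.** Explained-variance fractions from the covariance
eigendecomposition (negative eigenvalues clipped at 0); rank-deficient
inputs simply show trailing zero components, which is itself the
redundancy signal.

## Morisita index, intrinsic dimension, redundancy

The m-point index on a grid of cell edge δ over the min-max-scaled unit
hypercube:

    I_{m,δ} = Q^{m−1} · Σ_i n_i(n_i−1)⋯(n_i−m+1) / [N(N−1)⋯(N−m+1)]

Cells are half-open with the last cell closed (upper-boundary points belong
to the top cell). Only occupied cells are enumerated (row-wise unique of
integer cell indices), so fine grids in high dimension are cheap; the
falling factorials are evaluated in log space because `Q^{m−1}` overflows
double precision long before the ratio leaves O(1).

**Intrinsic dimension.** `log I` is linear in `log δ` with slope
`S_m = (m−1)(D_m − E)` for data of Rényi dimension `D_m` in E features,
giving `ID = E + S_m/(m−1)`. The sign convention is fixed by the CSR
calibration: uniform data in E dimensions has a flat index (I → 1) and must
recover ID = E, which the estimator does to within ±0.02 at n = 10⁴ for
E ≤ 5. Default order m = 2 and dyadic δ grid 1/2 … 1/32 (L = 5). Deltas
with I = 0 are dropped; among the two finest scales, deltas whose mean
occupied-cell count falls below m are dropped too (the m-tuple counts there
are Poisson noise); at least three usable deltas are required.

**Redundancy reduction.** Greedy forward selection: repeatedly add the
feature maximising the ID of the selected subset (ties to the lowest
index), stopping the *selected* set once the best gain drops below a
threshold (default 0.05 ID units) while still reporting the full ranking.
Exact duplicates and monotone copies contribute no ID and are discarded.

## Clustering suite

* **Hopkins statistic** `H = Σu/(Σu+Σw)` with uniform reference points in
  the per-feature bounding box and a default probe sample of
  min(200, n/2). H ≈ 0.5 signals spatial randomness in feature space,
  H → 1 clustering; verdicts: clusterable above 0.7, uniform at or below
  0.6, ambiguous between.
* **Number of clusters.** One clustering method is fixed (k-means default)
  and five validity indices vote over the k range: silhouette (subsampled
  beyond 3000 points), Calinski–Harabasz, Davies–Bouldin, the gap statistic
  (uniform bbox reference, B = 10, one-standard-error rule) and the
  within-SS elbow (maximum second difference). Majority vote, ties to the
  smallest k. An index — or a k that cannot be fitted at all, e.g. fewer
  distinct feature rows than clusters — is skipped with a warning rather
  than poisoning the vote.
* **k-means**: scikit-learn, k-means++ with 10 restarts.
* **PAM**: BUILD (most central point, then greedy additions) followed by
  steepest-descent SWAP on the full distance matrix; the objective never
  increases and the search stops at a local optimum. Deterministic; capped
  at n = 10⁴ (quadratic memory).
* **CLARA**: 5 subsamples of size 40 + 2k (the classical defaults),
  PAM on each, subsequent subsamples seeded with the incumbent medoids, and
  the winner judged by total dissimilarity over *all* points. Medoids are
  actual data rows.
* **Hierarchical**: SciPy linkage (Euclidean, average linkage by default —
  robust for elongated growth-curve families), leaf order for heatmaps,
  cutting by cluster count. Inputs above 10⁴ are refused with a pointer to
  subsampling, the standard practice for dendrogram inspection.
* **SOM**: classical online Kohonen training — random uniform init in the
  data ranges, Gaussian neighbourhood with radius decaying linearly from
  max(rows, cols)/2 to 1, learning rate 0.5 → 0.01, default 20 × 15
  hexagonal grid. The per-epoch quantisation error is logged and must
  settle (non-increasing averaged over the last fifth of training).
  Clustering the codebook (k-means or hierarchical) and mapping samples
  through their best-matching units yields the data clustering.

Cluster labels are arbitrary; all cross-method comparisons use the
adjusted Rand index.

## Pipeline and profiling

Stages run in a fixed order, each writing a CSV artifact and a structured
log line; the echoed YAML config plus the seed regenerate every artifact
byte-identically. Cluster interpretation uses two per-cluster
distributions: local density (the LGC column at the grid radius nearest the
profiling radius, default 4000 length units, snapped with a warning when
out of range) and local fDim. Histogram bins are Freedman–Diaconis on the
pooled values and shared across clusters; per-cluster counts sum exactly to
cluster sizes (minus reported invalid-dimension exclusions). An optional
full-vs-reduced comparison clusters once on all features and once on the
redundancy-selected subset and reports the ARI and size shifts.

## Synthetic fixtures: what they do and do not show

* `csr` (in any domain) calibrates the homogeneous reference: dimension 2,
  Morisita ≈ 1, Hopkins ≈ 0.5 in coordinate space.
* `sierpinski` (chaos game) fixes a known fractal dimension log3/log2.
* `line` and `grid` pin the 1-D scaling and the regular (I < 1) regimes.
* `thomas` produces realistic soft clustering (Poisson parents, Gaussian
  offspring) for variability comparisons against CSR.
* `blobs` is the labelled ground-truth fixture: three compact Gaussian
  clusters (spreads 10/20/40) at unequal pairwise separations
  (≈ 3350/5190/6900) so that each cluster has a unique staircase signature
  in its growth curve and, on the default radius grid, every radius lies on
  a plateau. This makes the clustering ground truth unambiguous — by
  design, it is an *easy* instance. Passing it shows the pipeline machinery
  (embedding → vote → five algorithms → profiles) is correct and mutually
  consistent; it does not show that real settlement data, where the
  feature-space clusters are overlapping density continua rather than
  separated clumps, admits a unique partition. The fixtures likewise do not
  emulate marks (inhabitants per cell), anisotropy, or measurement noise in
  coordinates.

## Problem sizes and defaults

Calibration checks use n = 10⁵ points for global dimensions (seconds via
KD-tree pair counting), n = 10⁴ for intrinsic-dimension recovery and
n = 3000 for pipeline-level checks — sizes at which every stochastic
assertion above holds with wide margin under fixed seeds. PAM and
hierarchical clustering are the deliberate small-n tools; CLARA and SOM are
the large-n path (CLARA is O(n·k) per candidate evaluation, SOM linear per
epoch).

## Known limitations

* No multifractal spectrum, functional-data clustering of curves,
  DBSCAN/spectral/kernel methods, or geographically constrained SOM.
* No edge-corrected estimators; everything is comparison-to-CSR.
* Local dimension estimates degrade when the smallest radii see ≪ 1
  neighbour (zeros dropped from fits; invalid rows flagged).
* The Morisita δ-window and m for a given dataset are defaults, not fitted;
  strongly non-uniform feature marginals can shift the ID by more than the
  CSR calibration suggests.
* CLARA's quality depends on subsample size relative to cluster granularity;
  for k approaching the subsample size increase `sample_size`.
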
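# lgclust

Unsupervised characterisation of spatial point patterns through **local
growth curves**: multi-scale neighbour counts, fractal dimensions, the
multipoint Morisita index, and a validated clustering pipeline.

The package targets analyses of gridded settlement/population data treated
as a planar point process — e.g. inhabited 100 m × 100 m cell centres in a
projected metric CRS — but works for any point pattern with Euclidean
coordinates: epidemiological case locations, monitoring networks, species
occurrences. It answers three questions about a pattern:

1. **How clustered / space-filling is it?** Global box-counting and sandbox
   dimensions, `N(l) ~ l^(-f_b)` and `<N(R)> ~ R^(f_sb)`, and the
   multipoint Morisita index `I_{m,δ}` (≈1 random, >1 clustered, <1
   regular).
2. **What does the neighbourhood of each point look like across scales?**
   The local growth curve of point *j* is the vector
   `N(x_j, y_j, R_1) … N(x_j, y_j, R_d)` of other-point counts within
   increasing radii; its log-log slope is a *local* fractal dimension.
   Stacking all curves embeds the pattern into an n × d feature space.
3. **What groups of environments exist?** The feature space is checked for
   clusterability (Hopkins statistic), the number of clusters is chosen by
   a majority vote of validity indices, and the points are clustered with
   k-means, PAM/CLARA k-medoids, hierarchical clustering and Kohonen
   self-organising maps; clusters are interpreted through per-cluster
   distributions of local density and local dimension. The Morisita-slope
   intrinsic dimension `ID = E + S_m/(m−1)` and its greedy feature-selection
   variant quantify and remove redundancy among the d radii.

Every estimator is conditioned on a **validity domain** (polygon with
holes, e.g. a national border minus lakes): complete-spatial-randomness
(CSR) reference patterns are simulated inside the domain so that comparisons
are free of the "natural clustering" imposed by the domain shape.

## Worked example

```python
from lgclust import (RunConfig, run_pipeline)

config = RunConfig(
    synthetic={"kind": "blobs", "n": 3000, "seed": 3},  # 3 labelled settlements
    k="vote", k_range=[2, 3, 4, 5], method="clara", seed=0,
    outdir="demo_run",
)
report = run_pipeline(config)
```

which prints per-stage logs and leaves `demo_run/` with one CSV per stage;
running `python examples/04_clustering_pipeline.py` prints:

```
n=3000  global fDim: box=0.83 sandbox=0.32
Hopkins = 1.000 (clusterable)
votes: {'silhouette': 3, 'calinski_harabasz': 3, 'davies_bouldin': 3, 'gap': 3} -> k = 3
cluster sizes: [1000, 1000, 1000]
  cluster 0: size 1000, density 1999 at R=4162
  cluster 1: size 1000, density 999 at R=4162
  cluster 2: size 1000, density 1999 at R=4162
adjusted Rand index vs ground truth: 1.000
```

Reading: the three compact clusters make the pattern strongly clusterable
(Hopkins ≈ 1), every validity index votes for k = 3, CLARA recovers the
ground-truth labels exactly (ARI 1.0), and the profile shows which clusters
see one vs two settlements within the ~4 km profiling radius. The global
fractal dimensions are far below 2 because the pattern is three point
masses, not a space-filling cloud.

The other examples demonstrate individual capabilities: fractal-dimension
calibration on CSR and the Sierpinski triangle (`examples/01…`), local
growth curves and border effects in a domain with a hole (`examples/02…`),
Morisita intrinsic dimension and redundancy reduction (`examples/03…`).

A thin CLI mirrors the library: `lgclust simulate | lgc | fractal |
morisita | cluster | profile | run`, all accepting `--seed` and
config/output paths.

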
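# Methods

## Model and procedure

`spotpie` treats cluster-count selection as something to be examined rather
than decided. The spot × gene matrix is clustered independently at each
requested resolution (a target cluster count k, a backend, a seed); no
hierarchy is imposed between resolutions. Relationships are recovered
afterwards from the data:

**Cluster graph.** For each pair of consecutive resolutions (in the order
the user listed them) an edge connects coarse cluster P to fine cluster C
with weight |C ∩ P| / |C| — the fraction of the finer cluster's spots that
sit in the coarser one. Because each spot has exactly one coarse label, the
incoming weights of every fine cluster sum to 1; this conservation is
checked pre-thresholding in the tests. A display threshold (default 0.05)
hides sub-noise edges; it never affects computed quantities, and a child
node losing all parents under an aggressive threshold is permitted and
logged.

**Similarity scores.** Spot s is scored against centroid k (the arithmetic
mean expression of cluster k's spots, on the same normalized values that
were clustered) as `exp(−λ·RMSD)`, with RMSD the root-mean-square deviation
over genes. Scores lie in (0, 1], equal 1 exactly at zero distance, and
decrease strictly in both distance and λ. A spot's pie slices are its
scores normalized to sum to one — the only convention under which one pie
closes into a full disc; raw scores are retained in the exports for users
who want absolute similarity.

**Color embedding.** Centroids of *all* resolutions are pooled,
mean-centered (not variance-scaled) and projected onto their first up-to-3
principal axes; each used component is min-max scaled to [0, 1] and read as
(r, g, b), with missing components (rank < 3) filled at 0.5. Pooling gives
one shared embedding, so a fine cluster and the coarse cluster it descends
from get comparable colors across the graph and every array plot. PCA's
sign ambiguity is removed by orienting every axis to correlate nonnegatively
with the centroid totals (falling back to a largest-loading sign convention
when that correlation is exactly zero), which keeps rendered output stable
across runs and platforms.

**Sub-clustering.** Iteration is the zoom mechanism: restrict the matrix to
the spots of selected clusters (dropping genes that become all-zero) and
feed the subset back through the identical pipeline. Re-selecting the full
spot set with the same specs reproduces the original assignments exactly.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| λ (`lambda`) | `auto` | score decay per unit RMSD; `auto` = ln 2 / median nearest-centroid RMSD, so the median spot scores 0.5 against its closest centroid. A fixed default would be meaningless across normalization scales. |
| edge threshold | 0.05 | minimum overlap proportion an edge needs to be displayed; 5% hides noise-level overlaps without touching the conservation property. |
| resolutions | 2, 3, 4 | cluster counts to compare; the method's point is to look at several. |
| backend | `kmeans` | k-means++ init, 10 restarts, best inertia kept. `hierarchical-ward` is built in; any `(values, k, seed) -> labels` callable can be registered. |
| top-gene count | 5 | genes summarized per node, ranked by centroid mean expression (most *expressed*, not most enriched), ties lexicographic. |
| normalization scale | 10⁴ | per-spot total before log1p; plumbing, not a contribution — any standard normalization can be applied upstream and passed with `--no-normalize`. |

Cluster labels within a resolution are canonicalized by descending size
(ties by smallest member spot index), making outputs stable under backend
label permutations. Empty k-means clusters are compacted rather than
erroring, and the effective k is reported.

## Synthetic tissues

The generator emulates the geometry these visualizations are built for: a
W × H spot array partitioned into axis-aligned rectangular domains, grouped
into superdomains (vertical strips split horizontally into subdomains),
optionally wrapped by a thin peripheral rim domain. Counts are negative
binomial with variance μ + αμ² (dispersion α shared across genes,
default 0.1; α = 0 degrades to Poisson), baseline mean 5. Each domain owns
a block of marker genes whose mean is multiplied by the effect size
(default ×8); when more than one superdomain exists, each rectangular
superdomain additionally owns a shared marker block raised in all of its
subdomains, so siblings are closer in expression space than non-siblings —
the nested signal the cluster graph is meant to reveal. The
mixed-boundary variant replaces the mean profile of spots within a
Chebyshev distance of a domain border with the 50/50 average of the two
adjacent domains' profiles, producing visibly split pies there.

Defaults (20×20 grid, 4 domains in 2 superdomains, 100 genes, 10 markers
per block) keep simulations comfortably small while leaving unambiguous
structure. What passing tests on these tissues shows: the pipeline recovers
planted contiguous domains, their ancestry, and boundary gradients. What
they do not show: robustness to library-size gradients, batch effects,
zero-inflation, irregular domain shapes, or Visium hexagonal geometry —
none of which the generator models.

## Numerical and design choices

- Matrix orientation on disk is auto-detected by attempting spot-ID parsing
  on both header axes; an explicit layout flag overrides. Coordinates parsed
  from `<x>x<y>` IDs are 1-based, x = column, y = row; rendering puts row 1
  at the top (microscopy convention).
- Matrices are stored dense: the intended inputs are hundreds to a few
  thousand spots. MatrixMarket triplets are densified on read; genes with
  zero total count are dropped with a warning.
- Median over an even count is the mean of the two central order statistics.
- Rank deficiency in the color PCA is detected with an SVD tolerance of
  `max(m, n) · ε · σ_max`; degenerate axes use the 0.5 fill.
- SVG output is generated directly as text with fixed 4-decimal coordinate
  formatting and no timestamps or generated IDs, so identical inputs yield
  byte-identical files; PNG output rasterizes the same primitives through
  matplotlib and is not guaranteed byte-stable across library versions.
- Edges are only drawn between *consecutive* resolutions in the user's spec
  order; a non-monotone order is allowed but logged.
- `auto` λ with every spot exactly on a centroid yields λ = 0 (uniform
  pies) with a warning rather than an error.

Problem sizes in the test-suite and acceptance checks (20×20 grids, ≤ 100
genes, 10 simulation seeds) were chosen as the smallest configurations at
which the spatial structure is unambiguous; all checks complete in seconds.

## Known limitations

- No graph-based (Louvain/Leiden) built-in backends; register your own.
- No H&E image overlay, interactive interface, or hexagonal (Visium)
  geometry; the static SVG reports with embedded tooltips replace
  interactivity.
- The exponential-RMSD kernel is the only similarity implemented;
  alternatives (cosine, Gaussian-on-squared-distance) would be extensions.
- The color embedding is plain RGB; no perceptual-uniformity correction is
  applied.
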
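# Methods

## The problem and the approach

Routine cell-culture monitoring produces label-free brightfield images in
which cells are low-contrast, dark-rimmed objects on a bright background.
`brightcount` estimates the number of cells in a single such image and
characterizes their spatial arrangement, without training data. The method
rests on one geometric observation: if each cell contributes roughly one
"seed" point, the Voronoi tessellation of those seeds tiles the image into
polygons whose areas encode local cell density — tiles in confluent regions
approach the size of a single cell, while tiles over empty background are
large.

The pipeline has four stages:

1. **Seed extraction.** Gaussian blur (σ = `blur_sigma`), adaptive
   threshold (foreground = pixels strictly below `(1 − thr_offset)` × the
   local box mean over a `(2·thr_radius+1)²` window; ties are background),
   despeckling by opening (`clean_px`), binary gradient-magnitude edge
   detection, optional dilation (`grow_px`) and a final erosion
   (`shrink_px` ≥ 1). Connected components (8-connectivity) of the final
   mask become seeds at their unweighted centroids.
2. **Voronoi tessellation** of the seeds, clipped exactly to the image
   rectangle by mirroring every seed across the four edges before
   triangulating (the seed–mirror bisector *is* the image edge). Tiles
   partition the rectangle, so areas sum to W·H.
3. **Mixture classification.** A univariate 3-component Gaussian mixture
   (unequal variances) is fitted to the tile areas by EM: class 1 =
   smallest-mean component (cluster interiors), class 2 = cell-sized
   tiles, class 3 = cell-free background.
4. **Grid optimization.** All combinations of the six stage-1 parameters
   are evaluated; each is scored by |mean cell-class tile area − target
   cell area|, where the target is the mean shoelace area of manually
   traced cell polygons (supplied as a CSV; a mean over ~20 cells is
   conventional). Valid combinations are ranked ascending by that
   distance (ties: fewer seeds, then enumeration order) and the seed
   counts of the best k = 20 are averaged into the cell-count estimate.
   The rank-1 combination supplies the seeds and tiles for the spatial
   layer.

Accuracy is reported as the magnitude-based relative error
`(ln est − ln truth)/ln truth` (natural logs; positive = overestimate),
and rank agreement with ground truth as Spearman correlation
(average ranks on ties).

### Spatial layer

From the selected combination: DBSCAN on seed coordinates (defaults
eps = 40 px, minPts = 5, a scale appropriate for ~1017×749 px frames at
1.68 μm/px); per-cluster density = seeds in cluster / total tile area of
the cluster; a quadrat test of complete spatial randomness on a 10×8 grid
(χ² = Σ(obs − e)²/e, e = n/80, df = 79, asymptotic upper-tail p);
confluency = area fraction of class-1+2 tiles; and mean/sd/cv (sample sd,
n−1) of class-1+2 tile areas. Tiles of noise seeds and class-3 tiles are
left unlabeled in cluster maps.

### Nuclei ground truth

Fluorescence nuclei images are counted by: disc-21 mean-convolution
background, threshold strictly above background (offset exposed, default
0; a small offset such as 0.02 is advisable for noisy sensors), opening
with disc-3, Euclidean distance map, watershed on the negated distance map
seeded at its regional maxima (one marker per plateau, minimum peak
separation 3 px), and connected labeling. The count is invariant to global
intensity scaling.

## Design choices where the design was open

- **Threshold polarity and ties.** Foreground is strictly below the local
  mean (brightfield cells are darker than background); equality is
  background. A 1e-9 guard keeps summed-area rounding from flipping exact
  ties.
- **Structuring element.** Discrete disc {(dx,dy): dx²+dy² ≤ n²}; n = 1 is
  the 5-pixel cross. Border pixels of the threshold window use the
  truncated in-image mean.
- **Edge operator.** Central differences on a replicate-padded mask, so a
  uniform mask yields no artificial frame ring.
- **Cell class.** The optimizer's `cell_class` defaults to 2 (the
  cell-sized middle component, the same classes from which confluency is
  defined); setting `cell_class=1` reproduces the convention of scoring
  against the smallest-mean component instead. Both are exposed.
- **EM details.** k-means initialization (10 restarts, deterministic per
  seed — a single start occasionally lands in a merged-component local
  optimum), convergence at relative log-likelihood change < 1e-8 or 500
  iterations, variance floor 1e-6 × sample variance, responsibility ties
  toward the lower class, components relabeled ascending by mean. An
  all-identical-areas sample short-circuits to a flagged degenerate model
  with every tile in class 2.
- **Fit scale.** The mixture is fitted on raw areas (the natural density
  view of tile areas); `log_transform` is available but off by default.
- **Ranking robustness.** When fewer than k combinations are valid, all
  valid ones are averaged rather than failing — sparse images routinely
  invalidate part of the grid. Per-combination seeds derive from
  `hash(global_seed, combo_index)` so parallel and serial evaluation
  agree.
- **Quadrat binning.** 10 along x, 8 along y; points on interior grid
  lines bin to the higher-index quadrat; the asymptotic χ² distribution is
  used without small-count correction (expected counts in the intended
  regime are ≥ ~6).
- **DBSCAN border points** go to the first cluster that reaches them in
  deterministic seed order; noise is labeled 0.
- **Nuclei brush sizes** are read as disc diameters (21 and 3 px).

## The synthetic generator and what it does (not) show

`render_scene` emulates the features the algorithm actually keys on: a
bright background (0.85) with a linear illumination gradient and Gaussian
sensor noise, and cells as dark-rimmed ellipses (rim depth above interior
depth) at either hard-core uniform or parent–offspring clustered
positions. Ground truth (count, positions, per-cell rendered area) is
exact by construction. It does **not** simulate defocus stacks, debris,
vignetting, mitotic figures or cell-shape heterogeneity beyond ellipses —
so passing the synthetic validation demonstrates the correctness and
calibration of the pipeline's machinery, not its accuracy on any
particular instrument or cell line, which always depends on tracing a
sensible target cell area.

### Frozen validation fixture

The validation scenes are 512×512 px, uniform layout, semi-major axis
U(1.8, 2.6) px, axis ratio U(0.75, 1.0), rim contrast 0.45, interior
contrast 0.25, noise sd 0.008, gradient amplitude 0.04, minimum center
separation 9 px (`synthetic.FIXTURE_CONFIG`). These values were chosen
once so that the scene family is feasible up to 2000 cells per frame
(hard-core packing fraction ≈ 0.49) and the rendered rims are resolvable
by the reduced grid below across that whole density range; they are
frozen and used unchanged by the tests and by `scripts/acceptance.py`.

With ~2 px cells, erosion radii above 1 px obliterate the edge rings, so
the **reduced grid** (`ParameterGrid.reduced()`, 72 combinations) fixes
`shrink_px = 1` and spans blur σ ∈ {1, 2}, threshold radius ∈ {15, 21, 27},
offset ∈ {0.05, 0.08}, clean ∈ {0, 1}, grow ∈ {0, 1, 2}. The full default
grid (`ParameterGrid.default()`, 864 combinations; hard cap 20 000)
remains the recommendation for real 4×-objective frames.

Problem sizes used in validation: 5 scenes of 500–2000 cells for count
accuracy, a 12-scene series of 100–2000 cells for rank fidelity, 500
replicates of n = 800 CSR patterns for χ² calibration, point sets ≤ 200
for the DBSCAN oracle.

## Numerical notes and known limitations

- Voronoi vertices are snapped onto the rectangle edges after mirroring;
  tile areas equal the shoelace area of their vertices to 1e-9 relative.
- Duplicate seed coordinates are merged before tessellation (a zero-area
  tile is meaningless); coincident component centroids are perturbed by
  1e-6 px at extraction so seed sets stay duplicate-free.
- At low density (< ~250 cells on a 512×512 fixture; the same effect is
  expected on real images) there are no dense regions, every tile is far
  larger than a cell, and the distance ranking degenerates toward the
  most-oversegmenting combinations — counts are then biased upward. This
  is an inherent property of the target-matching objective, not a bug.
- Heavy cell overlap (clustered layouts without separation) merges edge
  rings and biases counts downward; the top-k averaging damps but does
  not remove this.
- Only 2D images are handled; the nuclei counter's multi-level-threshold
  variant for heterogeneous stains is not implemented.
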
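# brightcount

Training-free cell counting and spatial characterization of **label-free
brightfield** microscopy images.

Label-free imaging keeps cells unperturbed, but its low contrast defeats
naive segmentation, and deep-learning alternatives need curated training
data. `brightcount` targets the everyday questions of high-content cell
culture — *how many cells are in this well, and how are they arranged?* —
using only classical image operations and geometry, so it runs on a single
image with no training and no manual thresholding. It is intended for labs
running automated plate imagers (one brightfield frame per well, optionally
a paired Hoechst nuclei frame for ground truth).

## Method

1. **Seed extraction** — blur → adaptive threshold (cells are *darker*
   than the local mean) → despeckle → binary edge magnitude → optional
   dilation → erosion; each connected component of the final mask yields
   one seed point at its centroid.
2. **Voronoi tessellation** of the seeds, clipped to the image rectangle.
   Tile area is inversely related to local cell density.
3. **3-class Gaussian mixture** (EM) on tile areas: class 1 = small tiles
   (cluster interiors), class 2 = cell-sized tiles, class 3 = empty
   background.
4. **Brute-force parameter optimization** — every combination of the six
   stage-1 parameters is scored by |mean class-2 tile area − A\*|, where
   A\* is the target cell area (mean shoelace area of ~20 traced cell
   polygons). The seed counts of the 20 best-scoring combinations are
   averaged into the cell-count estimate n̂.

Accuracy is reported as the magnitude-based relative error
(ln n̂ − ln n)/ln n, and agreement with nuclei ground truth as Spearman
rank correlation. A spatial layer computes DBSCAN clusters (eps = 40 px,
minPts = 5), within-cluster densities, a 10×8-quadrat χ² test of complete
spatial randomness, confluency, and tile-area statistics. A watershed
nuclei counter and a synthetic scene generator (exact ground truth)
support validation. See `docs/methods.md` for the full model description
and design notes.

## Worked example

```python
from brightcount import (acceptance_scene, optimize, relative_error,
                         extract_seeds, voronoi_tessellate,
                         fit_tile_classes, summarize)
from brightcount.optimizer import ParameterGrid

scene = acceptance_scene(800, seed=11)          # 512x512 px, 800 cells
print(f"target cell area: {scene.true_mean_cell_area:.2f} px^2")

est = optimize(scene.image, ParameterGrid.reduced(),
               target=scene.true_mean_cell_area, k=20, seed=0)
print(f"estimate: {est.estimate:.1f} cells")
print(f"relative error: {relative_error(est.estimate, 800):+.4f}")

seeds = extract_seeds(scene.image, est.selected.params)
tess = voronoi_tessellate(seeds)
model = fit_tile_classes(tess, seed=0)
print(summarize(seeds, tess, model).as_row())
```

prints

```
target cell area: 13.54 px^2
estimate: 754.2 cells
relative error: -0.0088
{'n_clusters': 1, 'mean_cluster_size': 1065, 'max_cluster_size': 1065,
 'chi_squared': 161.3, 'chi_squared_df': 79, 'p_value': 1.38e-07,
 'confluency': 0.546, 'tile_area_mean': 169.1, 'tile_area_sd': 88.6,
 'tile_area_cv': 0.524}
```

The estimate (754.2) is within 1% of the truth on the log scale. The
rank-1 parameter set oversegments slightly (1065 seeds, all one diffuse
DBSCAN cluster at this density); the top-20 average corrects for that.
The χ² of 161 on 79 df rejects complete spatial randomness — a hard-core
layout is *more regular* than Poisson, which the quadrat test also
detects.

## Command line

```bash
brightcount synth --counts 500,1000 --out scenes/ --nuclei     # fixtures
brightcount count --input scenes/ --target-area 13.5 \
            --grid reduced --seed 1 --out results/             # per-image CSV
brightcount nuclei --input scenes/ --offset 0.02 --out nuclei.csv
brightcount validate --results results/results.csv --nuclei-dir scenes/
brightcount spatial --seeds seeds.csv --width 512 --height 512
```

`count` writes one row per image (estimate, best parameters, cluster and
CSR statistics, confluency, tile stats) plus a per-combination audit CSV;
a traced-polygon CSV (`polygon_id,vertex_index,x,y`) can replace
`--target-area`.

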
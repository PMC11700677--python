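"""Spatial characterization of an image from its seed points and tiles.

Once the optimizer has fixed the best parameter combination, the seed
positions from that combination are clustered with DBSCAN, cluster labels
are mapped onto the Voronoi tiles, and per-image spatial descriptors are
computed: within-cluster seed density, a quadrat chi-squared test against
complete spatial randomness (CSR), confluency (area fraction of
cell-bearing tiles), and tile-area statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import EmptyClassError, ValidationError
from .imaging import SeedSet
from .mixture import TileClassModel
from .tessellation import Tessellation

#: Cluster label of noise seeds / unlabeled tiles.
NOISE = 0


@dataclass(frozen=True)
class SpatialConfig:
    """DBSCAN and quadrat-grid settings (defaults follow routine use on
    1017 x 749 px brightfield frames: eps 40 px, minPts 5, 10 x 8 grid)."""

    eps: float = 40.0
    min_pts: int = 5
    quadrat_nx: int = 10
    quadrat_ny: int = 8

    def __post_init__(self):
        if self.eps <= 0:
            raise ValidationError("eps must be > 0")
        if self.min_pts < 1:
            raise ValidationError("min_pts must be >= 1")
        if self.quadrat_nx < 1 or self.quadrat_ny < 1:
            raise ValidationError("quadrat grid dimensions must be >= 1")


@dataclass(frozen=True)
class ClusterLabeling:
    """Per-seed DBSCAN labels: cluster ids 1..n_clusters, NOISE (0) else."""

    seed_ids: np.ndarray
    labels: np.ndarray
    n_clusters: int

    def cluster_sizes(self) -> dict[int, int]:
        """Seeds per cluster id (noise excluded)."""
        ids, counts = np.unique(self.labels[self.labels != NOISE],
                                return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


@dataclass(frozen=True)
class SpatialSummary:
    """One image's spatial characterization record."""

    n_clusters: int
    mean_cluster_size: float
    max_cluster_size: int
    within_cluster_density: dict[int, float]
    chi_squared: float
    chi_squared_df: int
    p_value: float
    confluency: float
    tile_area_mean: float
    tile_area_sd: float
    tile_area_cv: float

    def as_row(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "mean_cluster_size": self.mean_cluster_size,
            "max_cluster_size": self.max_cluster_size,
            "chi_squared": self.chi_squared,
            "chi_squared_df": self.chi_squared_df,
            "p_value": self.p_value,
            "confluency": self.confluency,
            "tile_area_mean": self.tile_area_mean,
            "tile_area_sd": self.tile_area_sd,
            "tile_area_cv": self.tile_area_cv,
        }


def dbscan_cluster(seeds: SeedSet, cfg: SpatialConfig) -> ClusterLabeling:
    """Standard DBSCAN on the seed coordinates.

    A core point has >= min_pts neighbors (itself included) within eps;
    clusters are maximal density-connected sets.  Cluster ids are relabeled
    contiguously from 1 in order of first appearance along the seed order,
    which also resolves the classic border-point ambiguity
    deterministically.
    """
    if len(seeds) < 1:
        raise ValidationError("dbscan_cluster requires >= 1 seed")
    from sklearn.cluster import DBSCAN

    raw = DBSCAN(eps=cfg.eps, min_samples=cfg.min_pts).fit_predict(seeds.points)
    labels = np.zeros(len(raw), dtype=np.int64)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels[i] = mapping[lab]
    return ClusterLabeling(
        seed_ids=np.asarray(seeds.seed_ids).copy(),
        labels=labels,
        n_clusters=len(mapping),
    )


def cluster_tile_map(
    labeling: ClusterLabeling,
    tessellation: Tessellation,
    model: TileClassModel,
):
    """Annotate every tile with its seed's cluster id.

    Tiles whose seed is DBSCAN noise, and tiles the mixture model put in
    class 3 (cell-free areas), are annotated UNLABELED (cluster 0).
    Returns a DataFrame (seed_id, area, tile_class, cluster, labeled).
    """
    import pandas as pd

    lab_by_seed = dict(zip(labeling.seed_ids.tolist(), labeling.labels.tolist()))
    tile_ids = tessellation.seed_ids
    missing = [int(s) for s in tile_ids if int(s) not in lab_by_seed]
    if missing:
        raise ValidationError(f"tiles with seed_ids absent from labeling: {missing[:5]}")
    cluster = np.array([lab_by_seed[int(s)] for s in tile_ids], dtype=np.int64)
    cluster[model.assignments == 3] = NOISE
    return pd.DataFrame(
        {
            "seed_id": tile_ids,
            "area": tessellation.areas,
            "tile_class": model.assignments,
            "cluster": cluster,
            "labeled": cluster != NOISE,
        }
    )


def within_cluster_density(
    labeling: ClusterLabeling, tessellation: Tessellation
) -> dict[int, float]:
    """Seeds per px^2 for each cluster: (# seeds with the cluster id) /
    (total tile area of that cluster's seeds)."""
    lab_by_seed = dict(zip(labeling.seed_ids.tolist(), labeling.labels.tolist()))
    areas = tessellation.areas
    tile_ids = tessellation.seed_ids
    out: dict[int, float] = {}
    for cid, count in labeling.cluster_sizes().items():
        total = sum(
            areas[i]
            for i in range(len(tile_ids))
            if lab_by_seed.get(int(tile_ids[i])) == cid
        )
        out[cid] = count / total if total > 0 else float("nan")
    return out


def quadrat_counts(points: np.ndarray, width: float, height: float,
                   nx: int, ny: int) -> np.ndarray:
    """Seed counts over an nx x ny grid of equal rectangles (nx along x).

    Points on an interior grid line fall into the higher-index quadrat;
    the outer boundary is closed.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    counts, _, _ = np.histogram2d(
        pts[:, 0], pts[:, 1],
        bins=[np.linspace(0, width, nx + 1), np.linspace(0, height, ny + 1)],
    )
    return counts  # shape (nx, ny)


def quadrat_csr_test(seeds, cfg: SpatialConfig, dims=None):
    """Chi-squared test of complete spatial randomness on quadrat counts.

    chi2 = sum_q (obs_q - e)^2 / e with e = n / (nx * ny); df = nx*ny - 1;
    the p-value is the asymptotic upper chi-squared tail.

    ``seeds`` may be a SeedSet or an (n, 2) array (then ``dims=(W, H)`` is
    required).  Returns (chi_squared, df, p_value).
    """
    if isinstance(seeds, SeedSet):
        pts = seeds.points
        w, h = seeds.source_image_dims
    else:
        pts = np.asarray(seeds, dtype=np.float64).reshape(-1, 2)
        if dims is None:
            raise ValidationError("dims=(width, height) required for raw points")
        w, h = dims
    n = len(pts)
    if n == 0:
        raise ValidationError("quadrat test requires >= 1 point")
    counts = quadrat_counts(pts, w, h, cfg.quadrat_nx, cfg.quadrat_ny)
    e = n / (cfg.quadrat_nx * cfg.quadrat_ny)
    chi2 = float(((counts - e) ** 2 / e).sum())
    df = cfg.quadrat_nx * cfg.quadrat_ny - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def confluency(model: TileClassModel, tessellation: Tessellation,
               image_dims) -> float:
    """Fraction of the image covered by cell-bearing (class 1 + 2) tiles."""
    w, h = image_dims
    areas = tessellation.areas
    covered = float(areas[np.isin(model.assignments, (1, 2))].sum())
    return float(np.clip(covered / (w * h), 0.0, 1.0))


def tile_area_stats(model: TileClassModel, tessellation: Tessellation):
    """(mean, sd, cv) of the class-1 and class-2 tile areas.

    Sample sd (n-1 denominator).  With a single qualifying tile the sd and
    cv are NaN; with none an EmptyClassError is raised.
    """
    areas = tessellation.areas[np.isin(model.assignments, (1, 2))]
    if areas.size == 0:
        raise EmptyClassError("no class-1 or class-2 tiles")
    mean = float(areas.mean())
    if areas.size == 1:
        return mean, float("nan"), float("nan")
    sd = float(areas.std(ddof=1))
    cv = sd / mean if mean > 0 else float("nan")
    return mean, sd, cv


def summarize(
    seeds: SeedSet,
    tessellation: Tessellation,
    model: TileClassModel,
    cfg: SpatialConfig | None = None,
) -> SpatialSummary:
    """Full spatial characterization of one image."""
    cfg = cfg or SpatialConfig()
    labeling = dbscan_cluster(seeds, cfg)
    sizes = labeling.cluster_sizes()
    density = within_cluster_density(labeling, tessellation)
    chi2, df, p = quadrat_csr_test(seeds, cfg)
    confl = confluency(model, tessellation, seeds.source_image_dims)
    mean, sd, cv = tile_area_stats(model, tessellation)
    return SpatialSummary(
        n_clusters=labeling.n_clusters,
        mean_cluster_size=float(np.mean(list(sizes.values()))) if sizes else 0.0,
        max_cluster_size=max(sizes.values()) if sizes else 0,
        within_cluster_density=density,
        chi_squared=chi2,
        chi_squared_df=df,
        p_value=p,
        confluency=confl,
        tile_area_mean=mean,
        tile_area_sd=sd,
        tile_area_cv=cv,
    )
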
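"""Voronoi tessellation of seed points clipped to the image rectangle.

Tile area is the workhorse statistic of the whole tool: small tiles mark
locally dense cell regions, large tiles mark empty background.  The
tessellation is computed with scipy's Qhull wrapper; exact clipping to the
image rectangle [0, W] x [0, H] is obtained by mirroring every seed across
the four rectangle edges before triangulating, which makes each real seed's
cell the intersection of its unbounded cell with the rectangle, with the
rectangle edges appearing as perpendicular bisectors.

Also hosts the polygon utilities used to measure the target cell area from
manually traced cell outlines (shoelace area, mean over polygons); a CSV of
traced vertices replaces the interactive tracing GUI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi

from .exceptions import DegenerateInputError, ValidationError
from .imaging import SeedSet


@dataclass(frozen=True)
class VoronoiTile:
    """A convex Voronoi cell clipped to the image rectangle."""

    seed_id: int
    vertices: np.ndarray  # (k, 2) ordered polygon vertices, px
    area: float  # px^2
    centroid: tuple[float, float]


@dataclass(frozen=True)
class Tessellation:
    """All tiles of one image; tiles partition the bounds rectangle."""

    tiles: list[VoronoiTile]
    bounds: tuple[float, float]  # (width, height)

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def areas(self) -> np.ndarray:
        return np.array([t.area for t in self.tiles], dtype=np.float64)

    @property
    def seed_ids(self) -> np.ndarray:
        return np.array([t.seed_id for t in self.tiles], dtype=np.int64)

    def to_records(self) -> list[dict]:
        """GeoJSON-style polygon records (seed_id, vertices, area)."""
        return [
            {
                "seed_id": int(t.seed_id),
                "vertices": [[float(x), float(y)] for x, y in t.vertices],
                "area": float(t.area),
            }
            for t in self.tiles
        ]

    def to_dataframe(self):
        """Flat per-tile table (seed_id, x, y, area) with x, y the centroid."""
        import pandas as pd

        return pd.DataFrame(
            {
                "seed_id": self.seed_ids,
                "x": [t.centroid[0] for t in self.tiles],
                "y": [t.centroid[1] for t in self.tiles],
                "area": self.areas,
            }
        )


def polygon_area(vertices) -> float:
    """Absolute shoelace area of a simple polygon; orientation-independent."""
    v = np.asarray(vertices, dtype=np.float64)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValidationError("polygon_area requires >= 3 (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(vertices) -> tuple[float, float]:
    """Area-weighted centroid of a simple polygon."""
    v = np.asarray(vertices, dtype=np.float64)
    x, y = v[:, 0], v[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-300:
        return float(x.mean()), float(y.mean())
    cx = ((x + np.roll(x, -1)) * cross).sum() / (6.0 * a)
    cy = ((y + np.roll(y, -1)) * cross).sum() / (6.0 * a)
    return float(cx), float(cy)


def target_cell_area(polygons) -> float:
    """Mean shoelace area over manually traced cell polygons.

    This is the optimization target the grid search drives the cell-class
    mean tile area towards (conventionally the mean of ~20 traced cells).
    """
    polys = list(polygons)
    if not polys:
        raise ValidationError("target_cell_area requires >= 1 polygon")
    return float(np.mean([polygon_area(p) for p in polys]))


def read_polygon_csv(path):
    """Read traced polygons from a CSV of (polygon_id, vertex_index, x, y)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"polygon_id", "vertex_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValidationError(f"polygon CSV must have columns {sorted(required)}")
    polys = []
    for _, grp in df.sort_values(["polygon_id", "vertex_index"]).groupby("polygon_id"):
        polys.append(grp[["x", "y"]].to_numpy(dtype=np.float64))
    return polys


def _order_convex(vertices: np.ndarray) -> np.ndarray:
    """Order the vertices of a convex polygon counterclockwise."""
    c = vertices.mean(axis=0)
    ang = np.arctan2(vertices[:, 1] - c[1], vertices[:, 0] - c[0])
    return vertices[np.argsort(ang)]


def voronoi_tessellate(seeds: SeedSet, merge_duplicates: bool = True) -> Tessellation:
    """Voronoi tessellation of the seeds, clipped to the image rectangle.

    Every seed receives exactly one convex tile; the tiles partition the
    rectangle, so tile areas sum to W*H.  Duplicate coordinates (which would
    create zero-area tiles) are merged first.

    Raises
    ------
    DegenerateInputError
        For fewer than 3 seeds or an all-collinear seed set.
    """
    w, h = seeds.source_image_dims
    pts = np.asarray(seeds.points, dtype=np.float64)
    ids = np.asarray(seeds.seed_ids)
    if merge_duplicates and len(pts):
        _, first = np.unique(pts, axis=0, return_index=True)
        first = np.sort(first)
        pts, ids = pts[first], ids[first]
    n = len(pts)
    if n < 3:
        raise DegenerateInputError("voronoi_tessellate requires >= 3 seeds")
    spans = pts.max(axis=0) - pts.min(axis=0)
    # collinearity: rank of centered coordinates < 2
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9 * max(spans.max(), 1)) < 2:
        raise DegenerateInputError("all seeds are collinear")

    # mirror seeds across the four rectangle edges; the bisector between a
    # seed and its mirror is the edge itself, so each real cell is exactly
    # the clipped cell
    left = pts * [-1, 1]
    right = pts * [-1, 1] + [2 * w, 0]
    down = pts * [1, -1]
    up = pts * [1, -1] + [0, 2 * h]
    allpts = np.vstack([pts, left, right, down, up])
    vor = Voronoi(allpts)

    tiles = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # pragma: no cover - mirrors bound all real cells
            raise RuntimeError("unbounded Voronoi cell for an interior seed")
        verts = _order_convex(vor.vertices[region])
        # snap rounding jitter onto the rectangle edges
        verts[:, 0] = np.clip(verts[:, 0], 0.0, w)
        verts[:, 1] = np.clip(verts[:, 1], 0.0, h)
        area = polygon_area(verts)
        tiles.append(
            VoronoiTile(
                seed_id=int(ids[i]),
                vertices=verts,
                area=float(area),
                centroid=polygon_centroid(verts),
            )
        )
    return Tessellation(tiles=tiles, bounds=(float(w), float(h)))
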
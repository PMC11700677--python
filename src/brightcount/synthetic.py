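"""Synthetic fixtures with known ground truth.

Three generators:

* :func:`render_scene` — brightfield-like scenes: a bright background with a
  linear illumination gradient and Gaussian noise, cells drawn as
  dark-rimmed ellipses with a slightly darker interior, at uniform-random
  (hard-core) or clustered (parent-offspring) positions.
* :func:`render_nuclei` — the paired fluorescence view: bright Gaussian
  blobs on a dark background at the same positions.
* :func:`simulate_csr` / :func:`simulate_clustered` — raw spatial point
  patterns (homogeneous Poisson / Thomas process) for the spatial
  statistics.

All generators are pure functions of their seed.  The frozen
:data:`FIXTURE_CONFIG` is the rendering configuration used by the
validation fixtures; see docs/methods.md for how it was chosen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import PackingError, ValidationError
from .imaging import GrayImage

#: Frozen rendering configuration of the validation fixtures (512 x 512 px
#: scenes). Cells are small relative to their minimum separation so that the
#: edge-based chain resolves individual cells across the density range.
FIXTURE_CONFIG = dict(
    width=512,
    height=512,
    layout="uniform",
    cell_radius_range=(1.8, 2.6),
    axis_ratio_range=(0.75, 1.0),
    rim_contrast=0.45,
    interior_contrast=0.25,
    noise_sd=0.008,
    gradient_amplitude=0.04,
    min_separation=9.0,
)


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered scene plus its exact ground truth."""

    image: GrayImage
    true_count: int
    true_positions: np.ndarray  # (n, 2) x, y px
    true_mean_cell_area: float  # px^2, from the rendered ellipse supports
    layout: str
    render_seed: int
    config: dict = field(default_factory=dict)


def _place_uniform(n, width, height, margin, min_sep, rng, max_attempts_factor=500):
    """Hard-core dart throwing with a grid-bucket neighbor check."""
    if n == 0:
        return np.empty((0, 2))
    lo_x, hi_x = margin, width - margin
    lo_y, hi_y = margin, height - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise PackingError("margin leaves no placeable area")
    cell = max(min_sep / np.sqrt(2.0), 1e-6)
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    placed = 0
    min_sep2 = min_sep * min_sep
    attempts = 0
    max_attempts = max_attempts_factor * n
    while placed < n and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        gx, gy = int(x / cell), int(y / cell)
        ok = True
        for dx in range(-2, 3):
            for dy in range(-2, 3):
                for j in grid.get((gx + dx, gy + dy), ()):
                    ddx = pts[j, 0] - x
                    ddy = pts[j, 1] - y
                    if ddx * ddx + ddy * ddy < min_sep2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = (x, y)
            grid.setdefault((gx, gy), []).append(placed)
            placed += 1
    if placed < n:
        raise PackingError(
            f"placed {placed}/{n} cells at min separation {min_sep}"
        )
    return pts


def _place_clustered(n, width, height, margin, rng, parents_per_1000px2=None,
                     offspring_mean=50.0, offspring_sd=25.0):
    """Parent-offspring placement: each cell picks a uniform parent center
    and displaces by an isotropic Gaussian; no hard-core constraint."""
    if n == 0:
        return np.empty((0, 2))
    n_parents = max(1, int(round(n / offspring_mean)))
    parents = np.column_stack(
        [
            rng.uniform(margin, width - margin, n_parents),
            rng.uniform(margin, height - margin, n_parents),
        ]
    )
    pts = np.empty((n, 2))
    placed = 0
    while placed < n:
        parent = parents[rng.integers(0, n_parents)]
        p = parent + rng.normal(0.0, offspring_sd, 2)
        if margin <= p[0] <= width - margin and margin <= p[1] <= height - margin:
            pts[placed] = p
            placed += 1
    return pts


def render_scene(
    width: int = 512,
    height: int = 512,
    n_cells: int = 500,
    layout: str = "uniform",
    seed: int = 0,
    cell_radius_range: tuple[float, float] = (1.8, 2.6),
    axis_ratio_range: tuple[float, float] = (0.75, 1.0),
    rim_contrast: float = 0.45,
    interior_contrast: float = 0.25,
    noise_sd: float = 0.008,
    gradient_amplitude: float = 0.04,
    background: float = 0.85,
    min_separation: float | None = None,
    offspring_mean: float = 50.0,
    offspring_sd: float = 25.0,
) -> SyntheticScene:
    """Render a brightfield-like scene with known cell positions.

    Cells are ellipses with semi-major axis drawn from
    ``cell_radius_range``, a dark rim of depth ``rim_contrast`` and an
    interior darker than background by ``interior_contrast``.  ``uniform``
    layout enforces a pairwise center distance of ``min_separation``
    (default 1.2 x the maximum cell diameter); ``clustered`` uses a
    parent-offspring process with no separation constraint.
    """
    if n_cells < 0:
        raise ValidationError("n_cells must be >= 0")
    if layout not in ("uniform", "clustered"):
        raise ValidationError("layout must be 'uniform' or 'clustered'")
    rng = np.random.default_rng(seed)
    r_lo, r_hi = cell_radius_range
    if min_separation is None:
        min_separation = 1.2 * 2.0 * r_hi
    margin = r_hi + 1.0

    if layout == "uniform":
        pts = _place_uniform(n_cells, width, height, margin, min_separation, rng)
    else:
        pts = _place_clustered(
            n_cells, width, height, margin, rng,
            offspring_mean=offspring_mean, offspring_sd=offspring_sd,
        )

    # background: base level + linear illumination gradient + sensor noise
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    theta = rng.uniform(0, 2 * np.pi)
    ramp = (xx * np.cos(theta) + yy * np.sin(theta)) / max(width, height)
    ramp = ramp - ramp.mean()
    img = background + gradient_amplitude * ramp
    img += rng.normal(0.0, noise_sd, size=img.shape)

    # cells: accumulate a darkness canvas (max over cells, so overlapping
    # rims do not double-darken), then subtract
    darkness = np.zeros_like(img)
    areas = np.empty(max(n_cells, 1))
    for i in range(n_cells):
        a = rng.uniform(r_lo, r_hi)
        b = a * rng.uniform(*axis_ratio_range)
        phi = rng.uniform(0, np.pi)
        cx, cy = pts[i]
        ext = int(np.ceil(a + 3.0))
        x0, x1 = int(np.floor(cx)) - ext, int(np.floor(cx)) + ext + 1
        y0, y1 = int(np.floor(cy)) - ext, int(np.floor(cy)) + ext + 1
        x0c, x1c = max(x0, 0), min(x1, width)
        y0c, y1c = max(y0, 0), min(y1, height)
        px = xx[y0c:y1c, x0c:x1c] - cx
        py = yy[y0c:y1c, x0c:x1c] - cy
        c, s = np.cos(phi), np.sin(phi)
        u = (px * c + py * s) / a
        v = (-px * s + py * c) / b
        rho = np.sqrt(u * u + v * v)
        rim = np.exp(-0.5 * ((rho - 0.85) / 0.13) ** 2)
        depth = np.where(
            rho <= 1.0,
            interior_contrast + (rim_contrast - interior_contrast) * rim,
            rim_contrast * np.exp(-0.5 * ((rho - 1.0) / 0.10) ** 2),
        )
        patch = darkness[y0c:y1c, x0c:x1c]
        np.maximum(patch, depth, out=patch)
        areas[i] = float(np.count_nonzero(rho <= 1.0))
    img = np.clip(img - darkness, 0.0, 1.0)

    mean_area = float(areas[:n_cells].mean()) if n_cells else 0.0
    cfg = dict(
        width=width, height=height, layout=layout,
        cell_radius_range=tuple(cell_radius_range),
        axis_ratio_range=tuple(axis_ratio_range),
        rim_contrast=rim_contrast, interior_contrast=interior_contrast,
        noise_sd=noise_sd, gradient_amplitude=gradient_amplitude,
        background=background, min_separation=float(min_separation),
    )
    return SyntheticScene(
        image=GrayImage(img, pixel_size_um=1.68),
        true_count=n_cells,
        true_positions=pts,
        true_mean_cell_area=mean_area,
        layout=layout,
        render_seed=seed,
        config=cfg,
    )


def acceptance_scene(n_cells: int, seed: int) -> SyntheticScene:
    """A 512 x 512 uniform-layout scene rendered with the frozen fixture
    configuration used throughout validation."""
    cfg = {k: v for k, v in FIXTURE_CONFIG.items() if k != "layout"}
    return render_scene(layout="uniform", n_cells=n_cells, seed=seed, **cfg)


def render_nuclei(
    positions: np.ndarray,
    width: int,
    height: int,
    seed: int = 0,
    blob_sigma: float = 3.0,
    peak: float = 0.8,
    background: float = 0.05,
    noise_sd: float = 0.01,
) -> GrayImage:
    """Fluorescence-like view: bright Gaussian blobs on a dark background."""
    rng = np.random.default_rng(seed)
    img = np.full((height, width), background, dtype=np.float64)
    img += rng.normal(0.0, noise_sd, size=img.shape)
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    ext = int(np.ceil(4 * blob_sigma))
    for cx, cy in np.asarray(positions, dtype=np.float64).reshape(-1, 2):
        x0, x1 = max(int(cx) - ext, 0), min(int(cx) + ext + 1, width)
        y0, y1 = max(int(cy) - ext, 0), min(int(cy) + ext + 1, height)
        dx = xx[y0:y1, x0:x1] - cx
        dy = yy[y0:y1, x0:x1] - cy
        blob = peak * np.exp(-(dx * dx + dy * dy) / (2 * blob_sigma**2))
        np.maximum(img[y0:y1, x0:x1], background + blob, out=img[y0:y1, x0:x1])
    return GrayImage(np.clip(img, 0.0, 1.0))


def simulate_csr(n: int, width: float, height: float, seed: int = 0) -> np.ndarray:
    """n i.i.d. uniform points on [0, W) x [0, H) (binomial/CSR pattern)."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    return np.column_stack([rng.uniform(0, width, n), rng.uniform(0, height, n)])


def simulate_clustered(
    parent_intensity: float,
    offspring_mean: float,
    offspring_sd: float,
    width: float,
    height: float,
    seed: int = 0,
) -> np.ndarray:
    """Thomas process: Poisson(kappa * W * H) parents, Poisson(mu) offspring
    per parent displaced by an isotropic Gaussian, clipped to the window."""
    if parent_intensity < 0 or offspring_mean < 0 or offspring_sd < 0:
        raise ValidationError("Thomas process parameters must be >= 0")
    rng = np.random.default_rng(seed)
    n_parents = rng.poisson(parent_intensity * width * height)
    out = []
    for _ in range(n_parents):
        parent = np.array([rng.uniform(0, width), rng.uniform(0, height)])
        k = rng.poisson(offspring_mean)
        if k:
            offs = parent + rng.normal(0.0, offspring_sd, (k, 2))
            offs[:, 0] = np.clip(offs[:, 0], 0.0, np.nextafter(width, 0.0))
            offs[:, 1] = np.clip(offs[:, 1], 0.0, np.nextafter(height, 0.0))
            out.append(offs)
    if not out:
        return np.empty((0, 2))
    return np.vstack(out)


def write_scene(scene: SyntheticScene, path) -> Path:
    """Write a scene as 16-bit TIFF plus a ground-truth JSON sidecar."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.round(scene.image.pixels * 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "true_count": scene.true_count,
                "true_positions": scene.true_positions.tolist(),
                "true_mean_cell_area": scene.true_mean_cell_area,
                "layout": scene.layout,
                "render_seed": scene.render_seed,
                "config": scene.config,
            }
        )
    )
    return path
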
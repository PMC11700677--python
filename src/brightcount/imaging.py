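"""Image I/O and the classical processing chain that turns a brightfield
image into seed points.

Brightfield cells appear as dark-rimmed, low-contrast objects on a bright
background.  The chain is: Gaussian blur -> adaptive threshold (foreground =
darker than the local mean) -> morphological cleaning -> binary edge
magnitude -> optional dilation -> erosion.  Connected foreground components
of the final mask are reduced to their centroids ("seeds"), which feed the
Voronoi tessellation downstream.

Conventions
-----------
* Intensities are floats in [0, 1]; images are (height, width) arrays.
* Points are (x, y) in pixel units, x along width, y along height, 0-based.
* The structuring element of radius ``n`` is the discrete disc
  ``{(dx, dy): dx^2 + dy^2 <= n^2}`` (n = 1 gives the 5-pixel cross).
* Component labeling uses 8-connectivity by default (diagonals join).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError

#: Physical pixel pitch of the instrument the defaults were tuned on.
DEFAULT_PIXEL_SIZE_UM = 1.68


@dataclass(frozen=True)
class GrayImage:
    """A 2D grayscale intensity raster scaled to [0, 1]."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("GrayImage requires a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValidationError("GrayImage intensities must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("GrayImage intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A {0, 1} mask with the same dimensions as its source image."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("BinaryMask requires a non-empty 2D array")
        if px.dtype != np.uint8:
            uniq = np.unique(px)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValidationError("BinaryMask values must be exactly 0 or 1")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)


@dataclass(frozen=True)
class PipelineParams:
    """The six tunable knobs of the seed-extraction chain.

    blur_sigma
        Gaussian standard deviation in px.
    thr_radius
        Adaptive-threshold window half-width in px; the local mean is taken
        over a (2*thr_radius + 1)^2 box.
    thr_offset
        Fraction by which a pixel must undercut its local mean to count as
        foreground.
    clean_px
        Radius of the opening element used to despeckle the mask (0 = off).
    grow_px
        Dilation radius applied after edge detection (0 = off).
    shrink_px
        Erosion radius applied last; always >= 1 (the chain always shrinks,
        growth is the optional step).
    """

    blur_sigma: float = 2.0
    thr_radius: int = 21
    thr_offset: float = 0.05
    clean_px: int = 1
    grow_px: int = 1
    shrink_px: int = 1

    def __post_init__(self):
        if self.blur_sigma < 0:
            raise ValidationError("blur_sigma must be >= 0")
        if self.thr_radius < 1:
            raise ValidationError("thr_radius must be >= 1")
        if not 0 <= self.thr_offset < 1:
            raise ValidationError("thr_offset must lie in [0, 1)")
        if self.clean_px < 0 or self.grow_px < 0:
            raise ValidationError("clean_px and grow_px must be >= 0")
        if self.shrink_px < 0:
            raise ValidationError("shrink_px must be >= 0")
        if self.grow_px == 0 and self.shrink_px < 1:
            raise ValidationError("shrink_px must be >= 1 when grow_px is 0")


@dataclass(frozen=True)
class SeedSet:
    """One (x, y) point per detected connected object."""

    points: np.ndarray  # (n, 2) float, columns x, y
    seed_ids: np.ndarray  # (n,) int
    source_image_dims: tuple[int, int]  # (width, height)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        ids = np.asarray(self.seed_ids, dtype=np.int64).reshape(-1)
        if pts.shape[0] != ids.shape[0]:
            raise ValidationError("points and seed_ids must have equal length")
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("seed_ids must be unique")
        w, h = self.source_image_dims
        if pts.size:
            if pts[:, 0].min() < 0 or pts[:, 0].max() >= w:
                raise ValidationError("seed x coordinates must lie in [0, width)")
            if pts[:, 1].min() < 0 or pts[:, 1].max() >= h:
                raise ValidationError("seed y coordinates must lie in [0, height)")
            uniq = np.unique(pts, axis=0)
            if uniq.shape[0] != pts.shape[0]:
                raise ValidationError("duplicate seed coordinates")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "seed_ids", ids)

    def __len__(self) -> int:
        return self.points.shape[0]


def disc_element(radius: int) -> np.ndarray:
    """Discrete disc structuring element {(dx,dy): dx^2+dy^2 <= r^2}."""
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    r = int(radius)
    dy, dx = np.mgrid[-r: r + 1, -r: r + 1]
    return (dx * dx + dy * dy) <= r * r


def read_image(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> GrayImage:
    """Read a TIFF or PNG into a [0, 1] grayscale image.

    Integer dtypes are rescaled by their dtype maximum; multi-channel images
    are collapsed by an unweighted channel mean; multi-page TIFFs use the
    first page (with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
        if arr.ndim == 3 and arr.shape[0] > 1 and arr.shape[-1] not in (3, 4):
            warnings.warn(f"{path.name}: multi-page TIFF, using first page")
            arr = arr[0]
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        arr = arr.mean(axis=-1)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"{path.name}: not a non-empty 2D image")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
        if arr.max() > 1.0:  # float TIFFs occasionally store 0..255
            arr = arr / arr.max()
    arr = np.clip(arr, 0.0, 1.0)
    return GrayImage(arr, pixel_size_um=pixel_size_um)


def isoblur(img: GrayImage, sigma: float) -> GrayImage:
    """Isotropic Gaussian smoothing with reflective boundaries.

    Reflection makes the operation mass-conserving: total intensity is
    preserved to rounding error.  ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return img
    out = ndimage.gaussian_filter(img.pixels, sigma=sigma, mode="reflect")
    return GrayImage(np.clip(out, 0.0, 1.0), pixel_size_um=img.pixel_size_um)


def _local_mean(a: np.ndarray, radius: int) -> np.ndarray:
    """Box-window local mean via a summed-area table.

    Border pixels average over the truncated in-image window only.
    """
    h, w = a.shape
    sat = np.zeros((h + 1, w + 1), dtype=np.float64)
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=sat[1:, 1:])
    r = int(radius)
    y0 = np.clip(np.arange(h) - r, 0, None)
    y1 = np.clip(np.arange(h) + r + 1, None, h)
    x0 = np.clip(np.arange(w) - r, 0, None)
    x1 = np.clip(np.arange(w) + r + 1, None, w)
    total = (
        sat[y1[:, None], x1[None, :]]
        - sat[y0[:, None], x1[None, :]]
        - sat[y1[:, None], x0[None, :]]
        + sat[y0[:, None], x0[None, :]]
    )
    count = (y1 - y0)[:, None] * (x1 - x0)[None, :]
    return total / count


def adaptive_threshold(img: GrayImage, radius: int, offset: float) -> BinaryMask:
    """Mark pixels strictly darker than (1 - offset) x their local mean.

    Cells are darker than background in brightfield, so foreground = below
    the local mean.  Equality is background (strict inequality), so a
    constant image always yields an empty mask.
    """
    if radius < 1:
        raise ValidationError("radius must be >= 1")
    if not 0 <= offset < 1:
        raise ValidationError("offset must lie in [0, 1)")
    if radius > min(img.width, img.height):
        raise ValidationError("radius exceeds image dimensions")
    mean = _local_mean(img.pixels, radius)
    # the 1e-9 guard keeps summed-area rounding from flipping exact ties
    # (equality is background by convention)
    fg = img.pixels < (1.0 - offset) * mean - 1e-9
    return BinaryMask(fg.astype(np.uint8))


def clean(mask: BinaryMask, n: int) -> BinaryMask:
    """Morphological opening (erosion then dilation) with a disc of radius n.

    Removes foreground speckles smaller than the element; n = 0 is the
    identity.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    if n == 0:
        return mask
    opened = ndimage.binary_opening(mask.astype_bool(), structure=disc_element(n))
    return BinaryMask(opened.astype(np.uint8))


def edge_magnitude(mask: BinaryMask) -> BinaryMask:
    """Binary gradient-magnitude edge image of a mask.

    Central differences on a replicate-padded image, Euclidean norm,
    binarized at > 0.  Interiors of solid regions go to 0; a uniform mask
    (all 0 or all 1) maps to the all-zero image, i.e. no artificial frame
    ring is introduced at the boundary.
    """
    p = np.pad(mask.pixels.astype(np.float64), 1, mode="edge")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) * 0.5
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) * 0.5
    norm = np.hypot(gx, gy)
    return BinaryMask((norm > 0).astype(np.uint8))


def grow(mask: BinaryMask, n: int) -> BinaryMask:
    """Dilation with a disc of radius n (n = 0: identity)."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    if n == 0:
        return mask
    out = ndimage.binary_dilation(mask.astype_bool(), structure=disc_element(n))
    return BinaryMask(out.astype(np.uint8))


def shrink(mask: BinaryMask, n: int) -> BinaryMask:
    """Erosion with a disc of radius n (n = 0: identity).

    A region thinner than 2n+1 px is eliminated.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    if n == 0:
        return mask
    out = ndimage.binary_erosion(mask.astype_bool(), structure=disc_element(n))
    return BinaryMask(out.astype(np.uint8))


def label_components(mask: BinaryMask, connectivity: int = 8):
    """Label connected foreground components.

    Returns ``(labels, n)`` with labels 1..n, 0 = background.  8-connectivity
    (diagonals join) is the default used throughout the pipeline.
    """
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValidationError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask.pixels, structure=structure)
    return labels, n


def extract_seeds(
    img: GrayImage,
    params: PipelineParams,
    connectivity: int = 8,
    crop: tuple[int, int, int, int] | None = None,
) -> SeedSet:
    """Run the full chain and return one seed per connected component.

    Order: isoblur -> adaptive_threshold -> clean -> edge_magnitude -> grow
    -> shrink.  Each component contributes its unweighted pixel centroid.
    An empty final mask yields an empty SeedSet (not an error).

    ``crop`` is an optional (x0, y0, x1, y1) rectangle; seeds are computed on
    the crop and reported in crop-local coordinates.
    """
    if crop is not None:
        x0, y0, x1, y1 = crop
        img = GrayImage(img.pixels[y0:y1, x0:x1], pixel_size_um=img.pixel_size_um)
    blurred = isoblur(img, params.blur_sigma)
    mask = adaptive_threshold(blurred, params.thr_radius, params.thr_offset)
    mask = clean(mask, params.clean_px)
    mask = edge_magnitude(mask)
    mask = grow(mask, params.grow_px)
    mask = shrink(mask, params.shrink_px)
    labels, n = label_components(mask, connectivity=connectivity)
    if n == 0:
        return SeedSet(
            np.empty((0, 2)), np.empty(0, dtype=np.int64), (img.width, img.height)
        )
    centroids = ndimage.center_of_mass(mask.pixels, labels, np.arange(1, n + 1))
    pts = np.array([(c[1], c[0]) for c in centroids], dtype=np.float64)
    # distinct components can share a centroid; nudge exact duplicates so the
    # seed set stays duplicate-free (tessellation would merge them anyway)
    _, first = np.unique(pts, axis=0, return_index=True)
    if len(first) != len(pts):
        keep = np.zeros(len(pts), dtype=bool)
        keep[first] = True
        dup = np.where(~keep)[0]
        pts[dup, 0] += 1e-6 * (1 + np.arange(len(dup)))
        pts[:, 0] = np.clip(pts[:, 0], 0, img.width - 1e-9)
    return SeedSet(pts, np.arange(1, n + 1), (img.width, img.height))
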
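import numpy as np
import pytest

from brightcount import render_scene
from brightcount.imaging import BinaryMask


@pytest.fixture(scope="session")
def small_scene():
    """A small uniform scene used by several modules (30 cells, 256 px)."""
    return render_scene(width=256, height=256, n_cells=30, layout="uniform",
                        seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_mask(rng, shape=(32, 32), p=0.3) -> BinaryMask:
    return BinaryMask((rng.random(shape) < p).astype(np.uint8))


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def brute_force_local_mean(a: np.ndarray, radius: int) -> np.ndarray:
    """Truncated-window local mean by direct summation."""
    h, w = a.shape
    out = np.empty_like(a, dtype=float)
    for i in range(h):
        for j in range(w):
            win = a[max(i - radius, 0): i + radius + 1,
                    max(j - radius, 0): j + radius + 1]
            out[i, j] = win.mean()
    return out


def brute_force_components(mask: np.ndarray, connectivity: int = 8):
    """Connected components by BFS; returns list of pixel-index sets."""
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                comp = set()
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy, dx in nbrs:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                comps.append(frozenset(comp))
    return comps


def brute_force_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask)
    offs = [(dy, dx) for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if dx * dx + dy * dy <= radius * radius]
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                for dy, dx in offs:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        out[yy, xx] = 1
    return out


def brute_force_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask)
    offs = [(dy, dx) for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if dx * dx + dy * dy <= radius * radius]
    for y in range(h):
        for x in range(w):
            ok = True
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
                    ok = False
                    break
            out[y, x] = 1 if ok else 0
    return out


def brute_force_dbscan(points: np.ndarray, eps: float, min_pts: int):
    """Literal density-connectivity DBSCAN; noise label 0, clusters 1..k."""
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    neighbor = d <= eps
    core = neighbor.sum(axis=1) >= min_pts  # includes self
    labels = np.zeros(n, dtype=int)
    cid = 0
    for i in range(n):
        if labels[i] or not core[i]:
            continue
        cid += 1
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in np.where(neighbor[j])[0]:
                if labels[k] == 0:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
    return labels, cid
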
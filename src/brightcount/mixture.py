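"""Three-class Gaussian-mixture classification of Voronoi tile areas.

Tile areas of a cell image fall into three regimes: small tiles inside
dense cell clusters (class 1), cell-sized tiles at cluster edges (class 2)
and large tiles covering cell-free background (class 3).  A univariate
3-component Gaussian mixture with unequal variances is fitted to the areas
by Expectation-Maximization and every tile is assigned to its
maximum-responsibility component, relabeled so class 1 has the smallest
mean.

The EM is implemented here rather than delegated because the surrounding
tool needs its internals: the per-iteration log-likelihood trajectory
(monotonicity is an asserted invariant), a degeneracy/convergence flag the
optimizer reacts to, deterministic k-means++ initialization from a caller
seed, a variance floor, and tie-breaking toward the lower class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .exceptions import DegenerateInputError, EmptyClassError
from .tessellation import Tessellation

#: EM stops when the relative log-likelihood improvement drops below this.
EM_RTOL = 1e-8
#: Hard iteration cap.
EM_MAX_ITER = 500
#: Component variances are floored at this fraction of the sample variance.
VARIANCE_FLOOR_FRAC = 1e-6


@dataclass(frozen=True)
class TileClassModel:
    """Fitted 3-component mixture over tile areas plus per-tile labels."""

    means: np.ndarray  # (3,) component means, ascending, px^2
    variances: np.ndarray  # (3,) px^4
    weights: np.ndarray  # (3,) mixing proportions, sum 1
    assignments: np.ndarray  # (n_tiles,) labels in {1, 2, 3}
    loglik: float
    n_iter: int
    converged: bool
    degenerate: bool = False
    loglik_trace: np.ndarray = field(default=None, repr=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "weights": self.weights.tolist(),
                "loglik": self.loglik,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "degenerate": self.degenerate,
            }
        )


def _kmeans_init(x: np.ndarray, k: int, seed: int):
    """Deterministic k-means initialization of means/variances/weights."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed & 0x7FFFFFFF)
    labels = km.fit_predict(x.reshape(-1, 1))
    means = np.empty(k)
    var = np.empty(k)
    wts = np.empty(k)
    gvar = x.var()
    for j in range(k):
        sel = x[labels == j]
        means[j] = sel.mean() if sel.size else x.mean()
        var[j] = sel.var() if sel.size > 1 else gvar
        wts[j] = max(sel.size, 1)
    wts = wts / wts.sum()
    return means, np.maximum(var, VARIANCE_FLOOR_FRAC * gvar), wts


def fit_areas(areas: np.ndarray, seed: int, n_components: int = 3,
              log_transform: bool = False) -> TileClassModel:
    """Fit the mixture directly to a vector of tile areas.

    See :func:`fit_tile_classes` for semantics.  ``log_transform`` fits on
    log areas instead of raw areas (classification is unchanged in spirit;
    means are reported back on the raw scale's log if enabled — off by
    default, matching the raw-area density view of the data).
    """
    x = np.asarray(areas, dtype=np.float64).ravel()
    if x.size < 3 * n_components:
        raise DegenerateInputError(
            f"need >= {3 * n_components} tiles, got {x.size}"
        )
    if np.any(x <= 0):
        raise DegenerateInputError("tile areas must be positive")
    if log_transform:
        x = np.log(x)

    gvar = x.var()
    if gvar <= 0 or np.ptp(x) < 1e-12 * max(abs(x.mean()), 1.0):
        # all areas (numerically) identical: a single point mass; report one
        # effective component and fall back to the middle class
        m = float(x.mean())
        return TileClassModel(
            means=np.array([m, m, m]),
            variances=np.zeros(3),
            weights=np.array([0.0, 1.0, 0.0]),
            assignments=np.full(x.size, 2, dtype=np.int64),
            loglik=np.inf,
            n_iter=0,
            converged=False,
            degenerate=True,
            loglik_trace=np.empty(0),
        )

    means, var, wts = _kmeans_init(x, n_components, seed)
    floor = VARIANCE_FLOOR_FRAC * gvar
    n = x.size
    trace = []
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, EM_MAX_ITER + 1):
        # E-step: log responsibilities
        logp = (
            -0.5 * (x[:, None] - means[None, :]) ** 2 / var[None, :]
            - 0.5 * np.log(2 * np.pi * var[None, :])
            + np.log(wts[None, :])
        )
        norm = logsumexp(logp, axis=1)
        new_loglik = float(norm.sum())
        trace.append(new_loglik)
        resp = np.exp(logp - norm[:, None])
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        wts = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, floor)
        if new_loglik - loglik < EM_RTOL * abs(new_loglik) and it > 1:
            converged = True
            loglik = new_loglik
            break
        loglik = new_loglik

    # final E-step under the converged parameters, then relabel ascending
    logp = (
        -0.5 * (x[:, None] - means[None, :]) ** 2 / var[None, :]
        - 0.5 * np.log(2 * np.pi * var[None, :])
        + np.log(wts[None, :])
    )
    order = np.argsort(means, kind="stable")
    logp = logp[:, order]
    # argmax returns the first maximum -> ties break toward the lower class
    labels = np.argmax(logp, axis=1) + 1
    return TileClassModel(
        means=means[order],
        variances=var[order],
        weights=wts[order],
        assignments=labels.astype(np.int64),
        loglik=loglik,
        n_iter=it,
        converged=converged,
        degenerate=False,
        loglik_trace=np.array(trace),
    )


def fit_tile_classes(tessellation: Tessellation, seed: int,
                     log_transform: bool = False) -> TileClassModel:
    """Classify the tiles of a tessellation into three area classes.

    Class 1 = smallest-mean component (dense cluster interiors), class 2 =
    middle (cell-sized tiles), class 3 = largest (cell-free areas).  A
    degenerate sample (all areas identical) yields a flagged model with all
    tiles in class 2.

    Raises
    ------
    DegenerateInputError
        For fewer than 9 tiles or non-positive areas.
    """
    return fit_areas(tessellation.areas, seed=seed, log_transform=log_transform)


def mean_class_area(model: TileClassModel, tessellation: Tessellation,
                    cell_class: int) -> float:
    """Mean tile area over the tiles assigned to ``cell_class``.

    Raises
    ------
    EmptyClassError
        If no tile carries that label (the optimizer treats the parameter
        combination as invalid).
    """
    if cell_class not in (1, 2, 3):
        raise ValueError("cell_class must be 1, 2 or 3")
    areas = tessellation.areas
    sel = model.assignments == cell_class
    if not np.any(sel):
        raise EmptyClassError(f"no tiles in class {cell_class}")
    return float(areas[sel].mean())
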
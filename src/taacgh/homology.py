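"""Zeroth Betti number (connected components) of Vietoris-Rips filtrations.

For component counting only the 1-skeleton of the Rips complex matters: two
points are joined by an edge when their Euclidean distance is <= epsilon
(ties connect).  beta0(epsilon) is therefore the number of connected
components of the epsilon-threshold graph, computed here with a union-find
over distance-sorted edges — a single pass yields the full merge profile,
whose heights coincide with the single-linkage dendrogram heights.  No
higher simplices are ever materialized and no external TDA engine is used.

The hot loop (batched union-find across many clouds) is JIT-compiled with
numba; the per-epsilon routine :func:`betti0_at` is an independent plain
implementation used for spot checks and cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "FiltrationGrid",
    "BettiCurve",
    "betti0_at",
    "betti0_curve",
    "merge_heights",
    "merge_heights_batch",
    "curves_from_heights",
    "build_grid",
    "pairwise_distances",
]

DEFAULT_GRID_STEP = 0.05
"""Default filtration step.  The analysis is insensitive to the exact value
as long as the grid resolves the merge heights; 0.05 resolves log2-ratio
scale comfortably."""


@dataclass(frozen=True)
class FiltrationGrid:
    """Uniform grid of filtration values starting at 0."""

    epsilons: np.ndarray
    step: float

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilons, dtype=float)
        if eps.ndim != 1 or eps.size < 2 or eps[0] != 0.0:
            raise ValueError("grid must be a 1-d array starting at 0 with >= 2 values")
        if np.any(np.diff(eps) <= 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "epsilons", eps)

    def __len__(self) -> int:
        return self.epsilons.size


@dataclass(frozen=True)
class BettiCurve:
    """beta0 evaluated along a filtration grid for one point cloud."""

    grid: FiltrationGrid
    beta0: np.ndarray


def pairwise_distances(clouds: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances for a batch of equally-sized clouds.

    Parameters
    ----------
    clouds
        Array ``(N, m, D)`` (or ``(m, D)`` for a single cloud).

    Returns
    -------
    ndarray ``(N, m*(m-1)//2)`` of upper-triangle distances.
    """
    clouds = np.asarray(clouds, dtype=float)
    if clouds.ndim == 2:
        clouds = clouds[None]
    m = clouds.shape[1]
    ii, jj = np.triu_indices(m, 1)
    diff = clouds[:, ii, :] - clouds[:, jj, :]
    return np.sqrt(np.einsum("ned,ned->ne", diff, diff))


@njit(cache=True)
def _uf_merge_heights(dist: np.ndarray, order: np.ndarray, ii: np.ndarray,
                      jj: np.ndarray, m: int, out: np.ndarray) -> None:
    """Union-find over distance-sorted edges; records the m-1 merge heights."""
    n_rows, n_edges = dist.shape
    parent = np.empty(m, dtype=np.int64)
    for r in range(n_rows):
        for v in range(m):
            parent[v] = v
        merged = 0
        for e in range(n_edges):
            idx = order[r, e]
            a = ii[idx]
            b = jj[idx]
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            while parent[b] != b:
                parent[b] = parent[parent[b]]
                b = parent[b]
            if a != b:
                parent[a] = b
                out[r, merged] = dist[r, idx]
                merged += 1
                if merged == m - 1:
                    break


def merge_heights_batch(clouds: np.ndarray) -> np.ndarray:
    """Ascending component-merge heights for each cloud in a batch.

    Height ``h_k`` is the edge length at which the ``k``-th union occurs when
    edges are inserted in increasing distance order, so
    ``beta0(eps) = m - #{h_k <= eps}``.  The heights equal the single-linkage
    dendrogram merge distances.
    """
    clouds = np.asarray(clouds, dtype=float)
    if clouds.ndim == 2:
        clouds = clouds[None]
    n, m = clouds.shape[0], clouds.shape[1]
    if m == 1:
        return np.zeros((n, 0))
    ii, jj = np.triu_indices(m, 1)
    dist = pairwise_distances(clouds)
    order = np.argsort(dist, axis=1)
    out = np.empty((n, m - 1))
    _uf_merge_heights(dist, order, ii.astype(np.int64), jj.astype(np.int64), m, out)
    return out


def merge_heights(cloud: np.ndarray) -> np.ndarray:
    """Merge heights of a single cloud (see :func:`merge_heights_batch`)."""
    return merge_heights_batch(np.asarray(cloud)[None])[0]


def betti0_at(cloud: np.ndarray, epsilon: float) -> int:
    """Number of connected components of the epsilon-threshold graph.

    Plain union-find over all point pairs with distance <= epsilon.  Kept
    independent of the sorted-edge path so the two routes can be checked
    against each other.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    cloud = np.asarray(cloud, dtype=float)
    if cloud.ndim != 2 or cloud.shape[0] == 0:
        raise ValueError("cloud must be a non-empty (m, D) array")
    m = cloud.shape[0]
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    dist = pairwise_distances(cloud)[0]
    ii, jj = np.triu_indices(m, 1)
    components = m
    for a, b, d in zip(ii, jj, dist):
        if d <= epsilon:
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[ra] = rb
                components -= 1
    return components


def curves_from_heights(heights: np.ndarray, m: int, grid: FiltrationGrid) -> np.ndarray:
    """beta0 curves ``(N, len(grid))`` from batched merge heights."""
    heights = np.sort(np.asarray(heights, dtype=float), axis=1)
    eps = grid.epsilons
    # count of merges with height <= eps, per cloud and grid value
    counts = (heights[:, None, :] <= eps[None, :, None]).sum(axis=2)
    return (m - counts).astype(np.int64)


def betti0_curve(cloud: np.ndarray, grid: FiltrationGrid) -> BettiCurve:
    """beta0 along a grid, via one sorted-edge union-find pass."""
    cloud = np.asarray(cloud, dtype=float)
    m = cloud.shape[0]
    heights = merge_heights_batch(cloud[None])
    beta0 = curves_from_heights(heights, m, grid)[0]
    return BettiCurve(grid=grid, beta0=beta0)


def build_grid(clouds: Iterable[np.ndarray] | np.ndarray,
               step: float = DEFAULT_GRID_STEP) -> FiltrationGrid:
    """Uniform grid from 0 past the largest pairwise distance of any cloud.

    The end point is ``ceil(max_distance / step) * step`` so every beta0
    curve in the comparison reaches 1 within the grid.  All-coincident
    clouds yield the minimal grid ``{0, step}``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if isinstance(clouds, np.ndarray) and clouds.ndim in (2, 3):
        max_d = float(pairwise_distances(clouds).max(initial=0.0))
    else:
        max_d = 0.0
        seen = False
        for c in clouds:
            seen = True
            d = pairwise_distances(np.asarray(c))
            if d.size:
                max_d = max(max_d, float(d.max()))
        if not seen:
            raise ValueError("no clouds supplied")
    return grid_for_max_distance(max_d, step)


def grid_for_max_distance(max_distance: float, step: float = DEFAULT_GRID_STEP) -> FiltrationGrid:
    """Grid from 0 to the smallest step multiple >= ``max_distance``."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = max(1, int(np.ceil(max_distance / step - 1e-9)))
    while n * step < max_distance:  # guard float round-off
        n += 1
    return FiltrationGrid(epsilons=np.arange(n + 1) * step, step=step)
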
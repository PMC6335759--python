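"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: Voronoi adjacency is
recomputed by explicit half-plane intersection, and per-pixel non-negative
least squares by exhaustive enumeration of active sets.
"""

from __future__ import annotations

import itertools

import numpy as np
from shapely.geometry import Polygon


def _halfplane(pi: np.ndarray, pj: np.ndarray, extent: float) -> Polygon:
    """Polygon approximating the half-plane of points closer to pi than pj."""
    m = (pi + pj) / 2.0
    d = pj - pi
    d = d / np.linalg.norm(d)
    t = np.array([-d[1], d[0]])
    L = extent
    corners = [
        m + t * L,
        m - t * L,
        m - t * L - d * 3 * L,
        m + t * L - d * 3 * L,
    ]
    return Polygon(corners)


def voronoi_adjacency_bruteforce(
    points: np.ndarray, roi_polygon: Polygon, eps: float = 1e-9
) -> set[tuple[int, int]]:
    """O(n^2) Voronoi adjacency: build each cell as the intersection of the
    ROI with all bisector half-planes, then test shared boundary length."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    minx, miny, maxx, maxy = roi_polygon.bounds
    extent = 4.0 * (np.hypot(maxx - minx, maxy - miny) + np.ptp(pts, axis=0).max())
    cells = []
    for i in range(n):
        cell = roi_polygon
        # exact pruning: the bisector of (i, j) can only cut the current
        # cell if |pi - pj| / 2 is below the farthest cell vertex from pi;
        # visiting j by increasing distance lets us stop at the first
        # provably irrelevant bisector
        order = np.argsort(np.linalg.norm(pts - pts[i], axis=1))
        for j in order:
            if j == i or cell.is_empty:
                continue
            reach = np.max(
                np.linalg.norm(
                    np.asarray(cell.exterior.coords) - pts[i], axis=1
                )
            )
            if np.linalg.norm(pts[j] - pts[i]) / 2.0 > reach:
                break
            cell = cell.intersection(_halfplane(pts[i], pts[j], extent))
        cells.append(cell)
    # half-plane corners carry ~1e-9 rounding, so twin edges of adjacent
    # cells are not exactly coincident; measure shared length via a tiny
    # buffer (area / (2*tol) ~ shared length; point contacts give ~tol^2)
    tol = 1e-6
    edges = set()
    for i, j in itertools.combinations(range(n), 2):
        if cells[i].is_empty or cells[j].is_empty:
            continue
        inter = cells[i].buffer(tol).intersection(cells[j])
        if inter.area / (2 * tol) > 1e-3:
            edges.add((i, j))
    return edges


def nnls_bruteforce(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exhaustive active-set NNLS: try every support, keep the feasible
    solution with minimal residual.  Exact for small variable counts."""
    n = A.shape[1]
    best_c = np.zeros(n)
    best_r = float(np.linalg.norm(b))
    for k in range(1, n + 1):
        for support in itertools.combinations(range(n), k):
            sub = A[:, support]
            sol, *_ = np.linalg.lstsq(sub, b, rcond=None)
            if np.any(sol < -1e-12):
                continue
            c = np.zeros(n)
            c[list(support)] = np.maximum(sol, 0.0)
            r = float(np.linalg.norm(A @ c - b))
            if r < best_r - 1e-15:
                best_r = r
                best_c = c
    return best_c


def rook_adjacency(n_rows: int, n_cols: int) -> dict[int, list[int]]:
    """4-neighborhood adjacency of a perfect square grid, indexed row-major.

    On an exact square lattice the Voronoi cells are squares, so Voronoi
    adjacency (positive shared edge length) is exactly rook adjacency —
    diagonal contacts are single points.
    """
    adj: dict[int, list[int]] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            nbrs = []
            if r > 0:
                nbrs.append(i - n_cols)
            if r < n_rows - 1:
                nbrs.append(i + n_cols)
            if c > 0:
                nbrs.append(i - 1)
            if c < n_cols - 1:
                nbrs.append(i + 1)
            adj[i] = nbrs
    return adj
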
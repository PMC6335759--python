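"""Voronoi-adjacency neighbor graphs and cell-sociology statistics.

Two cells are *neighbors* when their Voronoi polygons — clipped to the
region of interest — share a boundary segment of positive length.  Because
the Voronoi polygon approximates the cell membrane, this neighborhood
definition adapts to local packing without any distance cutoff: tightly
packed immune cells and widely spaced tumor cells are treated alike.

For a focal cell, the *neighbor frequency* of phenotype N is the fraction
of its non-excluded Voronoi neighbors carrying N; per region these are
averaged over all focal cells of each phenotype to give the mean ± SD
neighbor frequency for every ordered (focal, neighbor) phenotype pair.
Cell *density* (cells/mm²) is reported alongside: density and neighbor
frequency are deliberately decoupled — two rare phenotypes that cluster
together have low densities but neighbor frequencies near 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import csr_matrix
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from .phenotyping import EXCLUDED, PHENOTYPES
from .segmentation import DEFAULT_PIXEL_SPACING_UM

__all__ = [
    "ROI",
    "NeighborGraph",
    "DegenerateGeometryError",
    "build_graph",
    "neighbor_frequency",
    "summarize",
    "SociologyResult",
]

logger = logging.getLogger(__name__)

#: minimum shared Voronoi boundary length (px) for adjacency; excludes
#: point-contact corners arising from cocircular degeneracies
ADJACENCY_EPS = 1e-9


class DegenerateGeometryError(ValueError):
    """Fewer than 3 cells, or all cells collinear: no Voronoi tessellation."""


@dataclass
class ROI:
    """A region of interest: a simple polygon in pixel coordinates."""

    polygon: Polygon
    pixel_spacing_um: float = DEFAULT_PIXEL_SPACING_UM

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid:
            raise ValueError("ROI polygon is not a simple valid polygon")
        if self.polygon.area <= 0:
            raise ValueError("ROI polygon has zero area")

    @classmethod
    def rectangle(
        cls, x0: float, y0: float, x1: float, y1: float,
        pixel_spacing_um: float = DEFAULT_PIXEL_SPACING_UM,
    ) -> "ROI":
        return cls(shapely.box(x0, y0, x1, y1), pixel_spacing_um)

    @property
    def area_px2(self) -> float:
        return float(self.polygon.area)

    @property
    def area_mm2(self) -> float:
        return self.area_px2 * (self.pixel_spacing_um / 1000.0) ** 2


@dataclass
class NeighborGraph:
    """Symmetric Voronoi-adjacency graph over cells within an ROI."""

    ids: np.ndarray                      # cell ids, graph order
    adjacency: csr_matrix                # boolean, symmetric, no self-edges
    edges: pd.DataFrame                  # id_a, id_b (a < b), shared_edge_len_px
    roi: ROI
    _index: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {int(c): i for i, c in enumerate(self.ids)}

    @property
    def n_nodes(self) -> int:
        return self.ids.size

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, cell_id: int) -> np.ndarray:
        """Cell ids Voronoi-adjacent to ``cell_id``."""
        i = self._index[int(cell_id)]
        sl = slice(self.adjacency.indptr[i], self.adjacency.indptr[i + 1])
        return self.ids[self.adjacency.indices[sl]]

    def degree(self) -> np.ndarray:
        return np.diff(self.adjacency.indptr)


def _dedupe_points(pts: np.ndarray) -> np.ndarray:
    """Jitter exact duplicate coordinates by 1e-6 px so qhull sees distinct
    generators; the perturbation is deterministic and far below pixel scale."""
    _, first, counts = np.unique(pts, axis=0, return_index=True, return_counts=True)
    if np.all(counts == 1):
        return pts
    pts = pts.copy()
    seen: dict[tuple[float, float], int] = {}
    for i, (x, y) in enumerate(pts):
        key = (float(x), float(y))
        k = seen.get(key, 0)
        if k:
            pts[i, 0] = x + 1e-6 * k
            pts[i, 1] = y + 1e-6 * k
        seen[key] = k + 1
    logger.warning("jittered %d duplicate centroids by 1e-6 px",
                   int(np.sum(counts - 1)))
    return pts


def _ridge_segments(vor: Voronoi, far_len: float) -> np.ndarray:
    """Endpoint coordinates ``(n_ridges, 2, 2)`` of every Voronoi ridge,
    with unbounded ridges extended ``far_len`` beyond their finite vertex."""
    segs = np.empty((len(vor.ridge_points), 2, 2))
    center = vor.points.mean(axis=0)
    for r, ((p, q), (v1, v2)) in enumerate(zip(vor.ridge_points, vor.ridge_vertices)):
        if v1 >= 0 and v2 >= 0:
            segs[r, 0] = vor.vertices[v1]
            segs[r, 1] = vor.vertices[v2]
        else:
            v = v2 if v1 < 0 else v1
            t = vor.points[q] - vor.points[p]
            t = t / np.linalg.norm(t)
            nvec = np.array([-t[1], t[0]])
            midpoint = (vor.points[p] + vor.points[q]) / 2.0
            if np.dot(midpoint - center, nvec) < 0:
                nvec = -nvec
            segs[r, 0] = vor.vertices[v]
            segs[r, 1] = vor.vertices[v] + nvec * far_len
    return segs


def build_graph(cells: pd.DataFrame, roi: ROI) -> NeighborGraph:
    """Build the Voronoi-adjacency graph of cell centroids within an ROI.

    The Voronoi diagram of all in-ROI centroids is computed and every ridge
    is clipped to the ROI polygon; an edge is kept iff the clipped shared
    boundary has length above :data:`ADJACENCY_EPS`.  Cells whose centroid
    falls outside the ROI are ignored; cells whose polygon merely touches
    the ROI boundary remain valid nodes.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 in-ROI cells, or all collinear.
    """
    shapely.prepare(roi.polygon)
    inside = shapely.intersects_xy(
        roi.polygon, cells["x"].to_numpy(float), cells["y"].to_numpy(float)
    )
    sub = cells.loc[inside]
    if len(sub) < len(cells):
        logger.info("dropped %d cells outside the ROI", len(cells) - len(sub))
    ids = sub["id"].to_numpy(int)
    pts = sub[["x", "y"]].to_numpy(float)
    if len(pts) < 3:
        raise DegenerateGeometryError(f"need >= 3 cells inside ROI, got {len(pts)}")
    if np.linalg.matrix_rank(pts - pts[0], tol=1e-9) < 2:
        raise DegenerateGeometryError("all cell centroids are collinear")
    pts = _dedupe_points(pts)

    vor = Voronoi(pts)
    minx, miny, maxx, maxy = roi.polygon.bounds
    far_len = 4.0 * float(np.hypot(maxx - minx, maxy - miny) + np.ptp(pts, axis=0).max())
    segs = _ridge_segments(vor, far_len)
    lines = shapely.linestrings(segs)
    clipped = shapely.intersection(lines, roi.polygon)
    lengths = shapely.length(clipped)
    keep = lengths > ADJACENCY_EPS

    pairs = vor.ridge_points[keep]
    lens = lengths[keep]
    n = len(pts)
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    adj = csr_matrix((np.ones(i.size, dtype=np.int8), (i, j)), shape=(n, n))
    a = np.minimum(ids[pairs[:, 0]], ids[pairs[:, 1]])
    b = np.maximum(ids[pairs[:, 0]], ids[pairs[:, 1]])
    order = np.lexsort((b, a))
    edges = pd.DataFrame(
        {"id_a": a[order], "id_b": b[order], "shared_edge_len_px": lens[order]}
    )
    return NeighborGraph(ids=ids, adjacency=adj, edges=edges, roi=roi)


def _phenotype_array(graph: NeighborGraph, cells: pd.DataFrame) -> np.ndarray:
    phen = cells.set_index("id")["phenotype"]
    return phen.reindex(graph.ids).to_numpy()


def neighbor_frequency(
    graph: NeighborGraph, cells: pd.DataFrame, cell_id: int, phenotype: str
) -> float:
    """Fraction of a focal cell's non-excluded neighbors with ``phenotype``.

    Excluded neighbors count in neither numerator nor denominator.  Raises
    if the focal cell has no eligible neighbor (such cells are skipped, not
    zeroed, in per-region aggregation).
    """
    phen = cells.set_index("id")["phenotype"]
    nbr = graph.neighbors(cell_id)
    nbr_phen = phen.reindex(nbr).to_numpy()
    eligible = nbr_phen != EXCLUDED
    n_elig = int(eligible.sum())
    if n_elig == 0:
        raise ValueError(f"cell {cell_id} has no non-excluded neighbors")
    return float(np.sum(nbr_phen[eligible] == phenotype) / n_elig)


def per_cell_frequencies(
    graph: NeighborGraph, cells: pd.DataFrame, phenotypes: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Neighbor-frequency table: one row per (eligible focal cell, phenotype N).

    Focal cells that are excluded or have zero eligible neighbors are
    skipped (and logged).  Within a row set for one focal cell the
    frequencies over all phenotypes sum to 1.
    """
    phen = _phenotype_array(graph, cells)
    if phenotypes is None:
        phenotypes = tuple(p for p in PHENOTYPES if p != EXCLUDED)
    A = graph.adjacency
    elig = A @ (phen != EXCLUDED).astype(np.float64)
    focal_ok = (phen != EXCLUDED) & (elig > 0)
    n_skipped = int(np.sum((phen != EXCLUDED) & (elig == 0)))
    if n_skipped:
        logger.info("%d focal cells skipped (no eligible neighbors)", n_skipped)
    rows = []
    for N in phenotypes:
        nbrN = A @ (phen == N).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(elig > 0, nbrN / np.maximum(elig, 1e-300), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "id": graph.ids[focal_ok],
                    "focal": phen[focal_ok],
                    "neighbor": N,
                    "frequency": f[focal_ok],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class SociologyResult:
    """Per-region sociology summary.

    ``frequencies``: one row per ordered (focal, neighbor) phenotype pair
    with the mean and SD (ddof=1; 0 for a single focal cell) of per-cell
    neighbor frequencies and the number of focal cells aggregated.
    ``densities``: one row per phenotype, cells/mm² over the clipped ROI.
    """

    frequencies: pd.DataFrame
    densities: pd.DataFrame
    roi: ROI


def pair_frequency_matrix(
    adjacency: csr_matrix, phen: np.ndarray, focal_types: list, neighbor_types: list
) -> np.ndarray:
    """Mean per-cell neighbor frequency for every (focal, neighbor) pair.

    Vectorised kernel shared with the Monte Carlo permutation test.  Entry
    ``(F, N)`` is NaN when no focal cell of type F has an eligible neighbor.
    """
    eligible_nbr = (phen != EXCLUDED).astype(np.float64)
    elig = adjacency @ eligible_nbr
    out = np.full((len(focal_types), len(neighbor_types)), np.nan)
    nbr_counts = {
        N: adjacency @ (phen == N).astype(np.float64) for N in neighbor_types
    }
    for fi, F in enumerate(focal_types):
        sel = (phen == F) & (elig > 0)
        if not sel.any():
            continue
        denom = elig[sel]
        for ni, N in enumerate(neighbor_types):
            out[fi, ni] = float(np.mean(nbr_counts[N][sel] / denom))
    return out


def summarize(
    graph: NeighborGraph,
    cells: pd.DataFrame,
    phenotypes: tuple[str, ...] | None = None,
) -> SociologyResult:
    """Aggregate neighbor frequencies and densities over one region.

    For every ordered (focal, neighbor) pair of non-excluded phenotypes:
    mean and SD of per-cell neighbor frequencies over all focal cells with
    at least one eligible neighbor (pairs with no such focal cells are
    reported with ``n_focal_cells=0`` and null statistics).  Densities are
    per-phenotype counts (excluded cells reported separately) divided by
    the ROI area in mm².
    """
    phen = _phenotype_array(graph, cells)
    if phenotypes is None:
        phenotypes = tuple(p for p in PHENOTYPES if p != EXCLUDED)
    A = graph.adjacency
    elig = A @ (phen != EXCLUDED).astype(np.float64)
    rows = []
    nbr_counts = {N: A @ (phen == N).astype(np.float64) for N in phenotypes}
    for F in phenotypes:
        sel = (phen == F) & (elig > 0)
        n_focal = int(sel.sum())
        for N in phenotypes:
            if n_focal == 0:
                rows.append((F, N, np.nan, np.nan, 0))
                continue
            f = nbr_counts[N][sel] / elig[sel]
            sd = float(np.std(f, ddof=1)) if n_focal > 1 else 0.0
            rows.append((F, N, float(np.mean(f)), sd, n_focal))
    freq = pd.DataFrame(
        rows, columns=["focal", "neighbor", "mean_frequency", "sd", "n_focal_cells"]
    )
    dens_rows = []
    for P in tuple(phenotypes) + (EXCLUDED,):
        count = int(np.sum(phen == P))
        dens_rows.append((P, count, count / graph.roi.area_mm2))
    dens = pd.DataFrame(dens_rows, columns=["phenotype", "count", "density_per_mm2"])
    return SociologyResult(frequencies=freq, densities=dens, roi=graph.roi)
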
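"""Nuclei segmentation from a hematoxylin concentration map.

Individual nuclei are extracted by iterative Otsu thresholding with size
rules, plus watershed splitting on the Euclidean distance transform:

1. A first Otsu threshold binarises the map; components below ``min_size``
   (50 px at 0.33 um/px) are discarded as debris.
2. Touching nuclei are split by a watershed seeded at h-maxima of each
   component's distance transform.
3. Components still larger than ``split_size`` (1000 px) are re-thresholded
   with Otsu restricted to their own pixels (an automatically *higher*
   threshold); fragments of at least ``fragment_size`` (150 px) become
   separate objects and the parent's area is repartitioned among them, while
   smaller fragments stay with their parent.
4. Steps 2-3 repeat for up to ``max_iter`` (3) passes.

Components are 8-connected throughout; Otsu uses 256 bins over each
component's min-max range, which makes the whole procedure invariant to a
positive rescaling of the input map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import find_boundaries, relabel_sequential, watershed

__all__ = ["LabelImage", "SegmentationParams", "segment_nuclei", "refine_boundaries"]

logger = logging.getLogger(__name__)

#: physical pixel pitch of the imaging system, um per pixel side
DEFAULT_PIXEL_SPACING_UM = 0.33


@dataclass
class LabelImage:
    """Integer nucleus label map: 0 = background, k >= 1 = nucleus id."""

    labels: np.ndarray
    pixel_spacing_um: float = DEFAULT_PIXEL_SPACING_UM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def areas(self) -> np.ndarray:
        """Pixel area per label, index 0 unused."""
        return np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)

    def centroids(self) -> np.ndarray:
        """``(n_labels, 2)`` array of (x, y) = (col, row) centroids."""
        n = self.n_labels
        if n == 0:
            return np.empty((0, 2))
        cy_cx = ndi.center_of_mass(
            np.ones_like(self.labels, dtype=float), self.labels, np.arange(1, n + 1)
        )
        arr = np.asarray(cy_cx, dtype=float)
        return arr[:, ::-1].copy()


@dataclass
class SegmentationParams:
    min_size: int = 50          # px; smaller components removed as debris
    split_size: int = 1000      # px; larger components re-thresholded
    fragment_size: int = 150    # px; re-threshold fragments this big split off
    max_iter: int = 3
    h: float = 2.0              # h-maxima depth for watershed seeding, px
    pixel_spacing_um: float = DEFAULT_PIXEL_SPACING_UM


def _otsu(values: np.ndarray) -> float:
    """Otsu threshold over the values' own min-max range, 256 bins.

    Ties in the between-class variance (plateaus arise when the histogram
    has an empty gap between modes) are broken at the plateau midpoint, so
    the threshold falls mid-gap rather than hugging the lower mode.  The
    histogram spans the data's own range, making the threshold equivariant
    under positive rescaling.
    """
    if values.size == 0:
        return 0.0
    if np.ptp(values) == 0:
        return float(values.flat[0])
    hist, edges = np.histogram(values, bins=256)
    hist = hist.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2
    w1 = np.cumsum(hist)
    w2 = w1[-1] - w1
    m1 = np.cumsum(hist * centers)
    mu1 = np.divide(m1, w1, out=np.zeros_like(m1), where=w1 > 0)
    mu2 = np.divide(m1[-1] - m1, w2, out=np.zeros_like(m1), where=w2 > 0)
    var = w1 * w2 * (mu1 - mu2) ** 2
    var = var[:-1]  # threshold between bins i and i+1
    plateau = np.flatnonzero(var >= var.max() * (1 - 1e-12))
    i = plateau[len(plateau) // 2]
    return float(edges[i + 1])


def _remove_small(labels: np.ndarray, min_size: int) -> np.ndarray:
    areas = np.bincount(labels.ravel())
    kill = np.flatnonzero(areas < min_size)
    kill = kill[kill > 0]
    if kill.size:
        labels = labels.copy()
        labels[np.isin(labels, kill)] = 0
    return labels


def _merge_small_pieces(pieces: np.ndarray, min_size: int) -> np.ndarray:
    """Merge sub-``min_size`` pieces into the sibling they touch most."""
    struct = np.ones((3, 3), bool)
    while True:
        areas = np.bincount(pieces.ravel())
        small = [p for p in np.flatnonzero(areas < min_size) if p > 0 and areas[p] > 0]
        if not small:
            return pieces
        merged_any = False
        for p in small:
            m = pieces == p
            ring = ndi.binary_dilation(m, structure=struct) & ~m
            cand = pieces[ring]
            cand = cand[cand > 0]
            if cand.size:
                vals, counts = np.unique(cand, return_counts=True)
                pieces = pieces.copy()
                pieces[m] = vals[np.argmax(counts)]
                merged_any = True
        if not merged_any:
            return pieces


def _split_component(comp: np.ndarray, h: float, min_size: int) -> np.ndarray | None:
    """Watershed-split one boolean component; ``None`` when no split occurs.

    Seeds are h-maxima of the component's distance transform (h suppresses
    shallow secondary peaks, so roughly convex nuclei are not over-split);
    resulting pieces below ``min_size`` are merged back into siblings.
    """
    padded = np.pad(comp, 1)
    edt = ndi.distance_transform_edt(padded)
    peaks = h_maxima(edt, h)
    markers = cc_label(peaks, connectivity=2)
    if markers.max() <= 1:
        return None
    ws = watershed(-edt, markers, mask=padded, connectivity=2)
    ws = ws[1:-1, 1:-1]
    # any pixel unreached by a marker joins the nearest basin via merge below
    orphan = comp & (ws == 0)
    if orphan.any():
        ws = ws.copy()
        ws[orphan] = cc_label(orphan, connectivity=2)[orphan] + markers.max()
    ws = _merge_small_pieces(ws, min_size)
    if np.unique(ws[ws > 0]).size <= 1:
        return None
    return ws


def _watershed_split(labels: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Apply distance-transform watershed splitting to every component."""
    out = labels.copy()
    next_id = int(labels.max()) + 1
    for k, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        comp = labels[sl] == k
        ws = _split_component(comp, params.h, params.min_size)
        if ws is None:
            continue
        region = out[sl]
        for i, p in enumerate(np.unique(ws[ws > 0])):
            m = (ws == p) & comp
            if i == 0:
                region[m] = k
            else:
                region[m] = next_id
                next_id += 1
    return out


def _rethreshold_oversized(
    labels: np.ndarray, cmap: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, bool]:
    """Re-run Otsu inside each oversized component; split off large fragments.

    The parent's full pixel set is repartitioned among fragments of at least
    ``fragment_size`` px by a watershed seeded at those fragments (so
    sub-threshold pixels and small fragments reattach to the nearest large
    fragment). A component yielding fewer than two large fragments is left
    unchanged.
    """
    areas = np.bincount(labels.ravel())
    oversized = [k for k in np.flatnonzero(areas > params.split_size) if k > 0]
    if not oversized:
        return labels, False
    out = labels.copy()
    next_id = int(labels.max()) + 1
    changed = False
    for k in oversized:
        comp = labels == k
        t = _otsu(cmap[comp])
        core = comp & (cmap > t)
        frags = cc_label(core, connectivity=2)
        frag_areas = np.bincount(frags.ravel())
        big = [f for f in np.flatnonzero(frag_areas >= params.fragment_size) if f > 0]
        if len(big) < 2:
            continue
        markers = np.zeros_like(labels)
        for f in big:
            markers[frags == f] = next_id
            next_id += 1
        edt = ndi.distance_transform_edt(comp)
        ws = watershed(-edt, markers=markers, mask=comp, connectivity=2)
        out[comp] = ws[comp]
        changed = True
    return out, changed


def segment_nuclei(
    hematoxylin_map: np.ndarray, params: SegmentationParams | None = None
) -> LabelImage:
    """Segment individual nuclei from a hematoxylin concentration map.

    See the module docstring for the full procedure.  An all-zero map yields
    an empty label image (not an error); non-finite input raises.
    """
    params = params or SegmentationParams()
    cmap = np.asarray(hematoxylin_map, dtype=float)
    if cmap.ndim != 2:
        raise ValueError("concentration map must be 2-D")
    if not np.all(np.isfinite(cmap)):
        raise ValueError("concentration map contains non-finite values")
    if np.any(cmap < 0):
        raise ValueError("concentration map must be non-negative")
    if np.ptp(cmap) == 0:
        return LabelImage(np.zeros(cmap.shape, np.int32), params.pixel_spacing_um)

    t = _otsu(cmap)
    labels = cc_label(cmap > t, connectivity=2).astype(np.int32)
    labels = _remove_small(labels, params.min_size)
    labels, _, _ = relabel_sequential(labels)
    labels = _watershed_split(labels, params)

    for _ in range(1, params.max_iter):
        labels, changed = _rethreshold_oversized(labels, cmap, params)
        if not changed:
            break
        labels = _watershed_split(labels, params)

    labels = _remove_small(labels, params.min_size)
    labels, _, _ = relabel_sequential(labels)
    return LabelImage(labels.astype(np.int32), params.pixel_spacing_um)


def refine_boundaries(
    label_image: LabelImage,
    cmap: np.ndarray,
    cutoff_fraction: float = 0.5,
) -> LabelImage:
    """Trim dim boundary pixels from each nucleus.

    A boundary pixel is returned to background when its concentration lies
    below ``cutoff_fraction`` of its component's own Otsu level.  Topology is
    preserved: a removal that would empty or disconnect a nucleus is reverted
    for that nucleus.
    """
    labels = label_image.labels
    cmap = np.asarray(cmap, dtype=float)
    if cmap.shape != labels.shape:
        raise ValueError("map shape does not match label image")
    out = labels.copy()
    boundary = find_boundaries(labels, mode="inner", connectivity=2)
    for k in range(1, label_image.n_labels + 1):
        comp = labels == k
        if not comp.any():
            continue
        level = _otsu(cmap[comp])
        drop = comp & boundary & (cmap < cutoff_fraction * level)
        if not drop.any():
            continue
        kept = comp & ~drop
        if kept.any() and cc_label(kept, connectivity=2).max() == 1:
            out[drop] = 0
        else:
            logger.debug("refinement reverted for label %d (topology)", k)
    return LabelImage(out, label_image.pixel_spacing_um)
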
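"""Cell phenotyping from per-stain integrated intensities.

Each segmented nucleus is scored for CD3, CD8 and CD79a by integrating the
unmixed concentration of each marker over the nucleus mask (optionally
dilated by a small ring, since these are membranous markers).  A per-slide
threshold per stain converts the integrated intensities into three binary
calls, and a three-level binary decision tree maps the 2^3 = 8 sign patterns
onto phenotypes:

====================  =================================
sign pattern          phenotype
====================  =================================
CD3+ CD8-  CD79a-     CD3_T       (helper T cell)
CD3+ CD8+  CD79a-     CD3_CD8_T   (cytotoxic T cell)
CD3- CD8-  CD79a+     CD79A_B     (B / plasma cell)
CD3- CD8-  CD79a-     UNSTAINED   (tumor / stroma)
CD3- CD8+  CD79a-     UNSTAINED   (rare; artifact / NK)
CD3- CD8+  CD79a+     UNSTAINED   (rare; artifact)
CD3+ CD8-  CD79a+     conflict    (T/B overlap candidate)
CD3+ CD8+  CD79a+     conflict    (T/B overlap candidate)
====================  =================================

Conflicted cells (incompatible T and B lineage markers) are either split
into a T cell beside a B cell — when the two stains' intensity-weighted
centroids are far enough apart to indicate two overlapping nuclei — or
excluded from analysis.  The convention here is that larger concentration
means more positive; an inverted 0-255 integrated-intensity scale from
legacy software can be imported by setting ``scale_direction="below"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.segmentation import expand_labels

from .segmentation import LabelImage, _otsu
from .unmixing import ConcentrationMaps

__all__ = [
    "UNSTAINED",
    "CD3_T",
    "CD3_CD8_T",
    "CD79A_B",
    "EXCLUDED",
    "PHENOTYPES",
    "MARKERS",
    "ThresholdSet",
    "integrate_intensity",
    "auto_thresholds",
    "classify",
    "resolve_conflicts",
    "phenotype_cells",
]

logger = logging.getLogger(__name__)

UNSTAINED = "UNSTAINED"
CD3_T = "CD3_T"
CD3_CD8_T = "CD3_CD8_T"
CD79A_B = "CD79A_B"
EXCLUDED = "EXCLUDED"
PHENOTYPES = (UNSTAINED, CD3_T, CD3_CD8_T, CD79A_B, EXCLUDED)

MARKERS = ("cd3", "cd8", "cd79a")

_CONFLICT = "CONFLICT"

#: sign pattern (cd3, cd8, cd79a) -> phenotype before conflict resolution
DECISION_TREE: dict[tuple[bool, bool, bool], str] = {
    (True, False, False): CD3_T,
    (True, True, False): CD3_CD8_T,
    (False, False, True): CD79A_B,
    (False, False, False): UNSTAINED,
    (False, True, False): UNSTAINED,   # CD3-CD8+: rare, kept unstained
    (False, True, True): UNSTAINED,    # CD3-CD8+CD79a+: rare, kept unstained
    (True, False, True): _CONFLICT,    # CD3+CD79a+
    (True, True, True): _CONFLICT,     # CD3+CD8+CD79a+
}


def raw_group_name(pattern: tuple[bool, bool, bool]) -> str:
    cd3, cd8, cd79a = pattern
    return (
        f"CD3{'+' if cd3 else '-'}"
        f"CD8{'+' if cd8 else '-'}"
        f"CD79a{'+' if cd79a else '-'}"
    )


@dataclass
class ThresholdSet:
    """Per-stain positivity thresholds on the integrated-intensity scale.

    One threshold per stain per slide, applied to every area imaged from
    that slide.  ``scale_direction="above"`` (default) treats values above
    the threshold as positive; ``"below"`` supports inverted legacy scales.
    """

    thresholds: dict[str, float]
    scale_direction: str = "above"

    def __post_init__(self) -> None:
        if self.scale_direction not in ("above", "below"):
            raise ValueError("scale_direction must be 'above' or 'below'")
        missing = [m for m in MARKERS if m not in self.thresholds]
        if missing:
            raise ValueError(f"missing thresholds for stains: {missing}")

    def is_positive(self, stain: str, values: np.ndarray) -> np.ndarray:
        t = self.thresholds[stain]
        values = np.asarray(values)
        return values > t if self.scale_direction == "above" else values < t


def integrate_intensity(
    label_image: LabelImage,
    maps: ConcentrationMaps,
    membrane_ring_px: int = 2,
    hematoxylin_stain: str = "hematoxylin",
) -> pd.DataFrame:
    """Integrate each stain's concentration over every segmented nucleus.

    The nuclear stain is summed over the nucleus mask only; membranous
    markers are summed over the nucleus expanded by ``membrane_ring_px``
    pixels (label territories never overlap).  Also records, per marker, the
    intensity-weighted centroid within the nucleus — used downstream to
    decide whether a doubly-stained cell is two overlapping nuclei.

    Returns a cell table with one row per nucleus: ``id, x, y, area_px``,
    one ``I_<stain>`` column per stain and ``cx_/cy_<marker>`` weighted
    centroids.
    """
    labels = label_image.labels
    n = label_image.n_labels
    ids = np.arange(1, n + 1)
    for name, m in maps.maps.items():
        if m.shape != labels.shape:
            raise ValueError(f"map {name!r} shape {m.shape} != labels {labels.shape}")
    expanded = expand_labels(labels, distance=membrane_ring_px) if membrane_ring_px else labels
    cents = label_image.centroids()
    out = pd.DataFrame(
        {
            "id": ids,
            "x": cents[:, 0] if n else np.empty(0),
            "y": cents[:, 1] if n else np.empty(0),
            "area_px": label_image.areas()[1:],
        }
    )
    for name in maps.stains:
        m = maps.maps[name]
        mask = labels if name == hematoxylin_stain else expanded
        out[f"I_{name}"] = ndi.sum_labels(m, mask, ids) if n else np.empty(0)
    for marker in MARKERS:
        if marker not in maps.maps:
            continue
        m = maps.maps[marker]
        if n:
            tot = ndi.sum_labels(m, labels, ids)
            cy = np.asarray(ndi.center_of_mass(m + 1e-300, labels, ids), dtype=float)
            # fall back to the nucleus centroid where the stain is absent
            weak = tot <= 0
            cx_m, cy_m = cy[:, 1], cy[:, 0]
            cx_m = np.where(weak, cents[:, 0], cx_m)
            cy_m = np.where(weak, cents[:, 1], cy_m)
        else:
            cx_m = cy_m = np.empty(0)
        out[f"cx_{marker}"] = cx_m
        out[f"cy_{marker}"] = cy_m
    return out


def auto_thresholds(cells: pd.DataFrame, stains: tuple[str, ...] = MARKERS) -> ThresholdSet:
    """Default per-slide thresholds: Otsu on each stain's integrated-intensity
    histogram across all cells of the slide (stands in for interactive visual
    thresholding)."""
    thr = {}
    for s in stains:
        col = f"I_{s}"
        if col not in cells.columns:
            raise ValueError(f"cell table lacks column {col!r}")
        thr[s] = _otsu(cells[col].to_numpy(dtype=float))
    return ThresholdSet(thr)


def classify(cells: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Assign each cell its decision-tree leaf (``raw_group``) and provisional
    phenotype from the three marker calls."""
    for m in MARKERS:
        if f"I_{m}" not in cells.columns:
            raise ValueError(f"cell table lacks stain column I_{m}")
    cells = cells.copy()
    pos = {m: thresholds.is_positive(m, cells[f"I_{m}"].to_numpy(dtype=float)) for m in MARKERS}
    patterns = list(zip(pos["cd3"], pos["cd8"], pos["cd79a"]))
    cells["raw_group"] = [raw_group_name(p) for p in patterns]
    cells["phenotype"] = [DECISION_TREE[p] for p in patterns]
    if "origin" not in cells.columns:
        cells["origin"] = "segmented"
    if "parent_id" not in cells.columns:
        cells["parent_id"] = -1
    return cells


def resolve_conflicts(
    cells: pd.DataFrame,
    overlap_min_offset_px: float = 2.0,
) -> pd.DataFrame:
    """Resolve incompatible-lineage (CD3+CD79a+) marker conflicts.

    A conflicted cell whose CD3- and CD79a-weighted centroids are at least
    ``overlap_min_offset_px`` apart is treated as two overlapping nuclei the
    segmentation could not separate: a second nucleus is added beside the
    first, one assigned as a T cell (keeping its CD8 status) and one as a B
    cell, each at its own stain's weighted centroid.  Conflicted cells
    without that geometric evidence are excluded from analysis.  Cells
    lacking weighted-centroid columns (e.g. imported tables) cannot show
    overlap evidence and are excluded.
    """
    cells = cells.copy()
    if "phenotype" not in cells.columns:
        raise ValueError("run classify() before resolve_conflicts()")
    conflict = cells["phenotype"] == _CONFLICT
    if not conflict.any():
        return cells
    has_geometry = all(
        c in cells.columns for c in ("cx_cd3", "cy_cd3", "cx_cd79a", "cy_cd79a")
    )
    next_id = int(cells["id"].max()) + 1
    new_rows = []
    for idx in cells.index[conflict]:
        row = cells.loc[idx]
        if has_geometry:
            dx = row["cx_cd3"] - row["cx_cd79a"]
            dy = row["cy_cd3"] - row["cy_cd79a"]
            offset = float(np.hypot(dx, dy))
        else:
            offset = 0.0
        t_type = CD3_CD8_T if "CD8+" in row["raw_group"] else CD3_T
        if offset >= overlap_min_offset_px:
            # overlapping T and B nuclei: the parent keeps the majority
            # stain's identity in place, the minority stain gets a new
            # nucleus at its own weighted centroid
            minority_is_b = row["I_cd79a"] <= row["I_cd3"]
            if minority_is_b:
                cells.loc[idx, "phenotype"] = t_type
                child_type = CD79A_B
                child_x, child_y = row["cx_cd79a"], row["cy_cd79a"]
            else:
                cells.loc[idx, "phenotype"] = CD79A_B
                child_type = t_type
                child_x, child_y = row["cx_cd3"], row["cy_cd3"]
            child = row.copy()
            child["id"] = next_id
            child["x"], child["y"] = child_x, child_y
            child["phenotype"] = child_type
            child["origin"] = "split_added"
            child["parent_id"] = int(row["id"])
            new_rows.append(child)
            next_id += 1
        else:
            cells.loc[idx, "phenotype"] = EXCLUDED
            logger.debug("cell %d excluded (conflict, offset %.2f px)", row["id"], offset)
    if new_rows:
        cells = pd.concat([cells, pd.DataFrame(new_rows)], ignore_index=True)
    return cells


def phenotype_cells(
    cells: pd.DataFrame,
    thresholds: ThresholdSet | None = None,
    overlap_min_offset_px: float = 2.0,
) -> pd.DataFrame:
    """Classify and conflict-resolve a cell table in one call.

    ``thresholds=None`` derives per-slide Otsu thresholds automatically.
    """
    thresholds = thresholds or auto_thresholds(cells)
    return resolve_conflicts(classify(cells, thresholds), overlap_min_offset_px)
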
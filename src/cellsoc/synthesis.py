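"""Synthetic tissue, image cubes and cohorts with known ground truth.

Every stage of the pipeline is testable without patient material via three
generators:

* :func:`generate_tissue` — labeled point patterns inside an ROI.  The
  tumor background is a jittered hexagonal lattice (epithelial sheets pack
  roughly hexagonally, and the jittered lattice gives non-degenerate
  Voronoi cells); immune phenotypes are placed by one of four regimes that
  span the null-to-structured continuum: ``uniform`` (random labels),
  ``clustered`` (Neyman-Scott clusters), ``segregated`` (disjoint spatial
  blocks) and ``infiltrated`` (a mixing fraction of immune cells dispersed
  among the tumor lattice, the rest clustered).
* :func:`render_cube` — a forward optical model of the stained slide:
  ground-truth per-stain concentration maps (Gaussian nuclear and marker
  blobs) are mixed through the stain spectra, ``I = blank · 10^(−C·S)``,
  with optional Gaussian noise on the OD scale.
* :func:`generate_cohort` — two-outcome patient cohorts whose group
  difference is injected purely through the infiltration mixing fraction,
  never through immune counts: densities stay matched while the
  tumor-immune neighbor frequency separates the groups.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .phenotyping import CD3_CD8_T, CD3_T, CD79A_B, UNSTAINED
from .segmentation import DEFAULT_PIXEL_SPACING_UM
from .sociology import ROI, build_graph, pair_frequency_matrix
from .unmixing import ConcentrationMaps, SpectralCube, StainSpectrum

__all__ = [
    "TissueModel",
    "generate_tissue",
    "ring_tissue",
    "checkerboard_tissue",
    "default_spectra",
    "default_wavelengths",
    "render_cube",
    "generate_cohort",
]

#: default centre-to-centre lattice spacing, px (~10 um at 0.33 um/px)
DEFAULT_SPACING_PX = 30.0
#: positional jitter SD as a fraction of the lattice spacing
LATTICE_JITTER = 0.15

DEFAULT_PROPORTIONS = {UNSTAINED: 0.82, CD3_T: 0.07, CD3_CD8_T: 0.07, CD79A_B: 0.04}


@dataclass
class TissueModel:
    """Parameters of one synthetic labeled point pattern."""

    n_cells: int = 400
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    regime: str = "uniform"          # uniform | clustered | segregated | infiltrated
    cluster_radius: float = 18.0     # px; offspring SD of Neyman-Scott clusters
    mean_cluster_size: float = 15.0  # expected cells per cluster parent
    mixing_fraction: float = 0.5     # infiltrated: share of immune cells dispersed
    spacing_px: float = DEFAULT_SPACING_PX
    roi: ROI | None = None           # default: square sized to fit n_cells
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"phenotype proportions sum to {total}, not 1")
        if self.regime not in ("uniform", "clustered", "segregated", "infiltrated"):
            raise ValueError(f"unknown spatial regime {self.regime!r}")
        if self.roi is None:
            # hexagonal packing: n sites need area n * s^2 * sqrt(3)/2
            side = float(np.sqrt(self.n_cells * self.spacing_px**2 * np.sqrt(3) / 2))
            self.roi = ROI.rectangle(0, 0, side, side)
        if np.sqrt(self.roi.area_px2 / self.n_cells) < 1.0:
            raise ValueError(
                "infeasible density: mean nearest-neighbor spacing below 1 px"
            )


def _hex_sites(roi: ROI, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal lattice sites inside the ROI polygon."""
    minx, miny, maxx, maxy = roi.polygon.bounds
    dy = spacing * np.sqrt(3) / 2
    ys = np.arange(miny + dy / 2, maxy, dy)
    pts = []
    for r, y in enumerate(ys):
        x0 = minx + (spacing / 2 if r % 2 else spacing / 4)
        xs = np.arange(x0, maxx, spacing)
        pts.append(np.column_stack([xs, np.full(xs.size, y)]))
    pts = np.concatenate(pts) if pts else np.empty((0, 2))
    pts = pts + rng.normal(0.0, LATTICE_JITTER * spacing, size=pts.shape)
    keep = shapely.intersects_xy(roi.polygon, pts[:, 0], pts[:, 1])
    return pts[keep]


def _uniform_in_roi(n: int, roi: ROI, rng: np.random.Generator) -> np.ndarray:
    """Uniform random points inside the ROI polygon (rejection sampling)."""
    minx, miny, maxx, maxy = roi.polygon.bounds
    out = np.empty((n, 2))
    have = 0
    while have < n:
        m = max(2 * (n - have), 16)
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        keep = shapely.intersects_xy(roi.polygon, cand[:, 0], cand[:, 1])
        cand = cand[keep]
        take = min(n - have, len(cand))
        out[have : have + take] = cand[:take]
        have += take
    return out


def _clustered_points(
    n: int, model: TissueModel, rng: np.random.Generator
) -> np.ndarray:
    """Neyman-Scott: Gaussian offspring around uniform cluster parents."""
    roi = model.roi
    pts = np.empty((n, 2))
    have = 0
    while have < n:
        parent = _uniform_in_roi(1, roi, rng)[0]
        size = min(n - have, max(1, int(rng.poisson(model.mean_cluster_size))))
        placed = 0
        while placed < size:
            cand = parent + rng.normal(0, model.cluster_radius, size=(size - placed, 2))
            keep = shapely.intersects_xy(roi.polygon, cand[:, 0], cand[:, 1])
            cand = cand[keep]
            take = min(size - placed, len(cand))
            pts[have : have + take] = cand[:take]
            have += take
            placed += take
            if len(cand) == 0:  # parent near boundary; fall back near the parent
                near = parent + rng.normal(0, 0.5, 2)
                if not shapely.intersects_xy(roi.polygon, near[0], near[1]):
                    near = parent
                pts[have] = near
                have += 1
                placed += 1
    return pts[:n]


def _counts_from_proportions(
    n: int, proportions: dict[str, float], rng: np.random.Generator
) -> dict[str, int]:
    names = list(proportions)
    draw = rng.multinomial(n, [proportions[k] for k in names])
    return dict(zip(names, draw.tolist()))


def generate_tissue(model: TissueModel) -> tuple[pd.DataFrame, ROI]:
    """Generate a labeled cell table under the model's spatial regime.

    Returns the cell table (``id, x, y, phenotype, origin, parent_id``) and
    the ROI.  Reproducible given ``model.seed``; all points lie inside the
    ROI polygon.
    """
    rng = np.random.default_rng(model.seed)
    roi = model.roi
    counts = _counts_from_proportions(model.n_cells, model.proportions, rng)
    tumor_like = {p: c for p, c in counts.items() if p == UNSTAINED}
    immune = {p: c for p, c in counts.items() if p != UNSTAINED and c > 0}

    sites = _hex_sites(roi, model.spacing_px, rng)
    rng.shuffle(sites)

    xs, ys, phen = [], [], []

    def _take_sites(k: int) -> np.ndarray:
        nonlocal sites
        if k > len(sites):  # lattice exhausted; top up uniformly
            extra = _uniform_in_roi(k - len(sites), roi, rng)
            sites = np.concatenate([sites, extra])
        out, sites = sites[:k], sites[k:]
        return out

    if model.regime == "uniform":
        pts = _take_sites(model.n_cells)
        labels = np.repeat(list(counts), [counts[k] for k in counts])
        rng.shuffle(labels)
        xs, ys, phen = pts[:, 0], pts[:, 1], labels
    elif model.regime == "segregated":
        # disjoint vertical blocks: tumor left, immune right
        minx, _, maxx, _ = roi.polygon.bounds
        n_tumor = sum(tumor_like.values())
        split = minx + (maxx - minx) * n_tumor / max(model.n_cells, 1)
        left = sites[sites[:, 0] < split]
        right = sites[sites[:, 0] >= split]
        parts, labels = [], []
        pts_t = left[:n_tumor]
        if len(pts_t) < n_tumor:
            pts_t = np.concatenate(
                [pts_t, _uniform_in_roi(n_tumor - len(pts_t), roi, rng)]
            )
        parts.append(pts_t)
        labels += [UNSTAINED] * n_tumor
        off = 0
        for p, c in immune.items():
            pts_i = right[off : off + c]
            off += c
            if len(pts_i) < c:
                pts_i = np.concatenate(
                    [pts_i, _uniform_in_roi(c - len(pts_i), roi, rng)]
                )
            parts.append(pts_i)
            labels += [p] * c
        pts = np.concatenate(parts)
        xs, ys, phen = pts[:, 0], pts[:, 1], np.array(labels)
    else:  # clustered / infiltrated
        n_tumor = sum(tumor_like.values())
        parts = [_take_sites(n_tumor)]
        labels = [UNSTAINED] * n_tumor
        for p, c in immune.items():
            if model.regime == "clustered":
                n_mix = 0
            else:
                n_mix = int(rng.binomial(c, np.clip(model.mixing_fraction, 0, 1)))
            if n_mix:
                parts.append(_take_sites(n_mix))
                labels += [p] * n_mix
            if c - n_mix:
                parts.append(_clustered_points(c - n_mix, model, rng))
                labels += [p] * (c - n_mix)
        pts = np.concatenate(parts)
        xs, ys, phen = pts[:, 0], pts[:, 1], np.array(labels)

    cells = pd.DataFrame(
        {
            "id": np.arange(1, len(xs) + 1),
            "x": np.asarray(xs, float),
            "y": np.asarray(ys, float),
            "phenotype": phen,
            "origin": "segmented",
            "parent_id": -1,
        }
    )
    return cells, roi


def ring_tissue(
    neighbor_phenotypes: list[str],
    focal_phenotype: str,
    radius: float = 30.0,
    rotation: float = 0.0,
) -> tuple[pd.DataFrame, ROI, int]:
    """A focal cell surrounded by an evenly spaced ring of neighbors.

    With a generous ROI the focal cell's Voronoi polygon is the inner
    k-gon, adjacent to every ring cell and nothing else — the textbook
    configuration for worked neighbor-frequency examples.  Returns
    ``(cells, roi, focal_id)``; the focal cell has id 1.
    """
    k = len(neighbor_phenotypes)
    if k < 3:
        raise ValueError("need at least 3 ring neighbors")
    ang = rotation + 2 * np.pi * np.arange(k) / k
    xs = np.concatenate([[0.0], radius * np.cos(ang)])
    ys = np.concatenate([[0.0], radius * np.sin(ang)])
    cells = pd.DataFrame(
        {
            "id": np.arange(1, k + 2),
            "x": xs,
            "y": ys,
            "phenotype": [focal_phenotype] + list(neighbor_phenotypes),
            "origin": "segmented",
            "parent_id": -1,
        }
    )
    roi = ROI.rectangle(-3 * radius, -3 * radius, 3 * radius, 3 * radius)
    return cells, roi, 1


def checkerboard_tissue(
    n_side: int = 16,
    phenotypes: tuple[str, str] = (UNSTAINED, CD3_T),
    spacing: float = DEFAULT_SPACING_PX,
) -> tuple[pd.DataFrame, ROI]:
    """Two phenotypes alternating on a square grid (maximal unlike-neighbor
    contact; used to demonstrate strong colocalization z-scores)."""
    ii, jj = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    xs = (jj.ravel() + 0.5) * spacing
    ys = (ii.ravel() + 0.5) * spacing
    phen = np.where((ii + jj).ravel() % 2 == 0, phenotypes[0], phenotypes[1])
    cells = pd.DataFrame(
        {
            "id": np.arange(1, xs.size + 1),
            "x": xs,
            "y": ys,
            "phenotype": phen,
            "origin": "segmented",
            "parent_id": -1,
        }
    )
    roi = ROI.rectangle(0, 0, n_side * spacing, n_side * spacing)
    return cells, roi


def default_wavelengths(n_bands: int = 16) -> np.ndarray:
    """Band centres in nm: 20 nm steps from 420 nm (matching a tunable-filter
    acquisition from 420-720 nm)."""
    return 420.0 + 20.0 * np.arange(n_bands)


def default_spectra(wavelengths: np.ndarray | None = None) -> list[StainSpectrum]:
    """Plausible absorbance spectra for the four-stain panel.

    Gaussian absorbance bumps with distinct peak wavelengths stand in for
    measured chromogen spectra: hematoxylin (nuclear counterstain), Ferangi
    Blue (CD3), DAB (CD8) and Warp Red (CD79a).  Synthetic but linearly
    independent, which is all the unmixing model requires.
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths)

    def bump(peak: float, width: float) -> np.ndarray:
        return np.exp(-0.5 * ((wl - peak) / width) ** 2)

    return [
        StainSpectrum("hematoxylin", bump(590.0, 55.0)),
        StainSpectrum("cd3", bump(650.0, 45.0)),       # Ferangi Blue
        StainSpectrum("cd8", bump(470.0, 85.0)),       # DAB (broad brown)
        StainSpectrum("cd79a", bump(520.0, 40.0)),     # Warp Red
    ]


#: which marker stains each phenotype deposits, besides hematoxylin
_PHENOTYPE_STAINS = {
    UNSTAINED: (),
    CD3_T: ("cd3",),
    CD3_CD8_T: ("cd3", "cd8"),
    CD79A_B: ("cd79a",),
}


def _add_blob(
    img: np.ndarray, x: float, y: float, sigma: float, amplitude: float
) -> None:
    """Accumulate a Gaussian blob into ``img`` over a local window."""
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-0.5 * ((ys[:, None] ** 2 + xs[None, :] ** 2) / sigma**2))
    img[y0:y1, x0:x1] += amplitude * g


def render_cube(
    cells: pd.DataFrame,
    spectra: list[StainSpectrum] | None = None,
    wavelengths: np.ndarray | None = None,
    shape: tuple[int, int] | None = None,
    noise_sd: float = 0.0,
    blank_intensity: float = 4000.0,
    nucleus_sigma: float = 3.0,
    marker_sigma: float = 4.5,
    nucleus_amplitude: float = 1.0,
    marker_amplitude: float = 0.8,
    seed: int = 0,
) -> tuple[SpectralCube, ConcentrationMaps]:
    """Forward-model a stained-slide image cube from a cell table.

    Each cell deposits a Gaussian hematoxylin blob at its centroid plus
    slightly wider blobs of its phenotype's marker stains (membranous
    markers extend beyond the nucleus).  Ground-truth concentrations are
    mixed to OD through the spectra, optional Gaussian noise (SD in OD
    units) is added, and intensities follow ``blank · 10^(−OD)``.

    Returns the raw intensity cube and the ground-truth concentration maps.
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths)
    spectra = default_spectra(wl) if spectra is None else spectra
    for sp in spectra:
        if sp.absorbance.size != wl.size:
            raise ValueError(f"spectrum {sp.name!r} does not match band count")
    if shape is None:
        side = int(np.ceil(max(cells["x"].max(), cells["y"].max()) + 8 * marker_sigma))
        shape = (side, side)
    names = [sp.name for sp in spectra]
    truth = {name: np.zeros(shape) for name in names}
    for row in cells.itertuples():
        _add_blob(truth["hematoxylin"], row.x, row.y, nucleus_sigma, nucleus_amplitude)
        for stain in _PHENOTYPE_STAINS.get(row.phenotype, ()):
            if stain in truth:
                _add_blob(truth[stain], row.x, row.y, marker_sigma, marker_amplitude)
    C = np.stack([truth[name] for name in names], axis=-1)
    S = np.stack([sp.absorbance for sp in spectra])
    od = C @ S
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
        np.maximum(od, 0.0, out=od)
    intensity = blank_intensity * 10.0 ** (-od)
    cube = SpectralCube(
        data=intensity,
        wavelengths=wl,
        blank_reference=np.full(wl.size, blank_intensity),
    )
    maps = ConcentrationMaps(
        stains=names,
        maps=truth,
        residual=np.zeros(shape),
        n_iterations=0,
        converged=True,
        spectra={sp.name: sp.absorbance.copy() for sp in spectra},
    )
    return cube, maps


def generate_cohort(
    n_recurrent: int = 11,
    n_non_recurrent: int = 8,
    rois_per_patient: int = 5,
    effect: float = 0.45,
    base_mixing: float = 0.15,
    patient_sd: float = 0.08,
    n_cells: int = 250,
    immune_fraction: float = 0.10,
    immune_phenotype: str = CD3_CD8_T,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-outcome cohort with a pure-infiltration group effect.

    Every ROI draws its immune cell count from the same Binomial(n_cells,
    immune_fraction) regardless of outcome, so immune *density* differs
    between groups only by sampling noise.  What differs is the spatial
    regime: non-recurrent patients disperse a larger fraction of their
    immune cells among the tumor lattice (mixing ``base_mixing + effect``
    vs ``base_mixing``, patient-level Gaussian variation ``patient_sd``,
    clipped to [0, 1]).  ``effect=0`` gives an exchangeable null.

    Returns one row per ROI: ``patient_id, roi_id, outcome, density,
    sociology`` where density is the immune density (cells/mm²) and
    sociology the mean tumor→immune neighbor frequency.
    """
    rng = np.random.default_rng(seed)
    rows = []
    patients = [("R%02d" % (i + 1), "recurrent", base_mixing) for i in range(n_recurrent)]
    patients += [
        ("N%02d" % (i + 1), "non_recurrent", base_mixing + effect)
        for i in range(n_non_recurrent)
    ]
    for patient_id, outcome, mix_mean in patients:
        mixing = float(np.clip(rng.normal(mix_mean, patient_sd), 0.0, 1.0))
        for r in range(rois_per_patient):
            n_immune = int(rng.binomial(n_cells, immune_fraction))
            n_immune = max(n_immune, 1)
            props = {
                UNSTAINED: (n_cells - n_immune) / n_cells,
                immune_phenotype: n_immune / n_cells,
            }
            model = TissueModel(
                n_cells=n_cells,
                proportions=props,
                regime="infiltrated",
                mixing_fraction=mixing,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            cells, roi = generate_tissue(model)
            graph = build_graph(cells, roi)
            phen = (
                cells.set_index("id")["phenotype"].reindex(graph.ids).to_numpy()
            )
            M = pair_frequency_matrix(
                graph.adjacency, phen, [UNSTAINED], [immune_phenotype]
            )
            count = int(np.sum(phen == immune_phenotype))
            rows.append(
                {
                    "patient_id": patient_id,
                    "roi_id": f"{patient_id}_roi{r + 1}",
                    "outcome": outcome,
                    "density": count / roi.area_mm2,
                    "sociology": float(M[0, 0]),
                }
            )
    return pd.DataFrame(rows)
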
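"""Readers and writers for the pipeline's on-disk formats.

Conventions (documented in every file header where applicable):

* coordinates are pixel units, origin top-left, ``x`` = column, ``y`` = row,
  0-based;
* CSV: UTF-8, comma separated, header row, ``.`` decimal, floats at 9
  significant digits;
* image cubes and maps: multi-page TIFF, one page per band / stain;
* ROI polygons: GeoJSON in pixel coordinates;
* spectra, configuration and provenance: JSON.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, mapping, shape

from .segmentation import DEFAULT_PIXEL_SPACING_UM, LabelImage
from .sociology import ROI, NeighborGraph, SociologyResult
from .unmixing import ConcentrationMaps, SpectralCube, StainSpectrum

__all__ = [
    "read_cube",
    "write_cube",
    "read_spectra",
    "write_spectra",
    "write_concentration_maps",
    "read_concentration_maps",
    "read_labels",
    "write_labels",
    "read_cells",
    "write_cells",
    "read_roi",
    "write_roi",
    "write_edges",
    "write_sociology",
    "write_provenance",
]

FLOAT_FORMAT = "%.9g"


# ---------------------------------------------------------------------------
# spectral cubes and spectra

def read_cube(cube_path: str | Path, sidecar_path: str | Path) -> tuple[SpectralCube, list[StainSpectrum]]:
    """Read a multi-page TIFF cube plus its JSON sidecar.

    The sidecar holds ``wavelengths_nm``, ``stains`` (name + absorbance per
    band) and optionally ``blank_reference`` (per-band scalars).
    """
    data = tifffile.imread(str(cube_path))
    if data.ndim != 3:
        raise ValueError(f"expected a multi-page TIFF cube, got shape {data.shape}")
    data = np.moveaxis(data, 0, -1)  # pages are bands
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
    blank = meta.get("blank_reference")
    blank = np.asarray(blank, dtype=float) if blank is not None else None
    spectra = [
        StainSpectrum(s["name"], np.asarray(s["absorbance"], dtype=float))
        for s in meta.get("stains", [])
    ]
    cube = SpectralCube(data=data, wavelengths=wavelengths, blank_reference=blank)
    return cube, spectra


def write_cube(
    cube: SpectralCube,
    spectra: list[StainSpectrum],
    cube_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    tifffile.imwrite(str(cube_path), np.moveaxis(cube.data, -1, 0).astype(np.float32))
    meta: dict = {"wavelengths_nm": cube.wavelengths.tolist()}
    if cube.blank_reference is not None:
        meta["blank_reference"] = np.asarray(cube.blank_reference).tolist()
    meta["stains"] = [
        {"name": sp.name, "absorbance": sp.absorbance.tolist()} for sp in spectra
    ]
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_spectra(path: str | Path) -> tuple[list[StainSpectrum], np.ndarray | None]:
    with open(path) as fh:
        meta = json.load(fh)
    spectra = [
        StainSpectrum(s["name"], np.asarray(s["absorbance"], dtype=float))
        for s in meta["stains"]
    ]
    wl = meta.get("wavelengths_nm")
    return spectra, (np.asarray(wl, dtype=float) if wl is not None else None)


def write_spectra(
    spectra: list[StainSpectrum], path: str | Path, wavelengths: np.ndarray | None = None
) -> None:
    meta: dict = {
        "stains": [
            {"name": sp.name, "absorbance": sp.absorbance.tolist()} for sp in spectra
        ]
    }
    if wavelengths is not None:
        meta["wavelengths_nm"] = np.asarray(wavelengths).tolist()
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1)


def write_concentration_maps(maps: ConcentrationMaps, out_dir: str | Path) -> None:
    """One 32-bit float TIFF per stain plus the residual and run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in maps.stains:
        tifffile.imwrite(str(out / f"{name}.tif"), maps.maps[name].astype(np.float32))
    tifffile.imwrite(str(out / "residual.tif"), maps.residual.astype(np.float32))
    meta = {
        "stains": maps.stains,
        "n_iterations": maps.n_iterations,
        "converged": maps.converged,
        "spectra": {k: v.tolist() for k, v in maps.spectra.items()},
    }
    with open(out / "unmix_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_concentration_maps(out_dir: str | Path) -> ConcentrationMaps:
    out = Path(out_dir)
    with open(out / "unmix_meta.json") as fh:
        meta = json.load(fh)
    maps = {
        name: tifffile.imread(str(out / f"{name}.tif")).astype(float)
        for name in meta["stains"]
    }
    residual = tifffile.imread(str(out / "residual.tif")).astype(float)
    return ConcentrationMaps(
        stains=meta["stains"],
        maps=maps,
        residual=residual,
        n_iterations=meta["n_iterations"],
        converged=meta["converged"],
        spectra={k: np.asarray(v) for k, v in meta.get("spectra", {}).items()},
    )


# ---------------------------------------------------------------------------
# label images and cell tables

def write_labels(labels: LabelImage, path: str | Path) -> None:
    arr = labels.labels
    if arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 nuclei; cannot write 16-bit label TIFF")
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_labels(
    path: str | Path, pixel_spacing_um: float = DEFAULT_PIXEL_SPACING_UM
) -> LabelImage:
    return LabelImage(tifffile.imread(str(path)).astype(np.int32), pixel_spacing_um)


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# ROI polygons

def read_roi(
    path: str | Path, pixel_spacing_um: float = DEFAULT_PIXEL_SPACING_UM
) -> ROI:
    """Read a GeoJSON polygon (Feature, FeatureCollection or bare geometry)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        gj = gj["features"][0]
    if gj.get("type") == "Feature":
        spacing = gj.get("properties", {}).get("pixel_spacing_um", pixel_spacing_um)
        geom = shape(gj["geometry"])
        return ROI(Polygon(geom), spacing)
    return ROI(Polygon(shape(gj)), pixel_spacing_um)


def write_roi(roi: ROI, path: str | Path) -> None:
    feature = {
        "type": "Feature",
        "properties": {
            "pixel_spacing_um": roi.pixel_spacing_um,
            "coordinate_convention": "pixels, origin top-left, x=column, y=row, 0-based",
        },
        "geometry": mapping(roi.polygon),
    }
    with open(path, "w") as fh:
        json.dump(feature, fh, indent=1)


# ---------------------------------------------------------------------------
# sociology outputs

def write_edges(graph: NeighborGraph, path: str | Path) -> None:
    graph.edges.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_sociology(result: SociologyResult, out_dir: str | Path, roi_id: str = "roi") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    freq = result.frequencies.copy()
    freq.insert(0, "roi", roi_id)
    freq.to_csv(out / "sociology.csv", index=False, float_format=FLOAT_FORMAT)
    dens = result.densities.copy()
    dens.insert(0, "roi", roi_id)
    dens.to_csv(out / "density.csv", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# provenance

def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    out_path: str | Path,
    inputs: dict[str, str | Path] | None = None,
    seeds: dict[str, int] | None = None,
    parameters: dict | None = None,
) -> None:
    """Write a provenance sidecar: package version, timestamp, input hashes,
    seeds and stage parameters."""
    from . import __version__

    block = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            k: {"path": str(v), "sha256": _sha256(v)}
            for k, v in (inputs or {}).items()
            if Path(v).exists()
        },
        "seeds": seeds or {},
        "parameters": parameters or {},
    }
    with open(out_path, "w") as fh:
        json.dump(block, fh, indent=1)
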
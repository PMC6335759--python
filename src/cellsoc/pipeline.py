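"""End-to-end pipeline: unmix → segment → phenotype → sociology → Monte Carlo.

Stages whose inputs are supplied directly are skipped: starting from a cell
table bypasses unmixing and segmentation, and a cell table that already
carries a ``phenotype`` column bypasses phenotyping.  Re-running with an
identical configuration and seed reproduces identical output CSVs.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import pandas as pd

from . import io, montecarlo, phenotyping, segmentation, sociology, unmixing
from .config import ConfigError, RunConfig

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _phenotype_stage(cells: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    sec = cfg.section("phenotype")
    thresholds = None
    if "thresholds" in sec:
        thresholds = phenotyping.ThresholdSet(
            {k: float(v) for k, v in sec["thresholds"].items()},
            sec.get("scale_direction", "above"),
        )
    return phenotyping.phenotype_cells(
        cells,
        thresholds=thresholds,
        overlap_min_offset_px=float(sec.get("overlap_min_offset_px", 2.0)),
    )


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns a name → path map of artifacts.

    Raises :class:`ConfigError` on inconsistent configuration; stage errors
    propagate after partial outputs have been written.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    seeds: dict[str, int] = {}
    roi_path = cfg.input_path("roi")
    roi = io.read_roi(roi_path)

    cells_path = cfg.input_path("cells")
    if cells_path is not None:
        cells = io.read_cells(cells_path)
        logger.info("starting from cell table (%d cells); unmix/segment skipped",
                    len(cells))
    else:
        cube_path = cfg.input_path("cube")
        spectra_path = cfg.input_path("spectra")
        if spectra_path is None:
            raise ConfigError("/inputs/spectra required when starting from a cube")
        cube, _ = io.read_cube(cube_path, spectra_path)
        spectra, _ = io.read_spectra(spectra_path)
        usec = cfg.section("unmix")
        od = unmixing.to_optical_density(cube)
        maps = unmixing.mcr_als_unmix(
            od,
            spectra,
            max_iter=int(usec.get("max_iter", 50)),
            tol=float(usec.get("tol", 1e-6)),
            refine_spectra=bool(usec.get("refine_spectra", False)),
        )
        io.write_concentration_maps(maps, out / "maps")
        artifacts["maps"] = out / "maps"

        ssec = cfg.section("segment")
        params = segmentation.SegmentationParams(
            min_size=int(ssec.get("min_size", 50)),
            split_size=int(ssec.get("split_size", 1000)),
            fragment_size=int(ssec.get("fragment_size", 150)),
            max_iter=int(ssec.get("max_iter", 3)),
            h=float(ssec.get("h", 2.0)),
            pixel_spacing_um=float(ssec.get("pixel_spacing_um", roi.pixel_spacing_um)),
        )
        labels = segmentation.segment_nuclei(maps["hematoxylin"], params)
        labels = segmentation.refine_boundaries(labels, maps["hematoxylin"])
        io.write_labels(labels, out / "nuclei.tif")
        artifacts["nuclei"] = out / "nuclei.tif"
        psec = cfg.section("phenotype")
        cells = phenotyping.integrate_intensity(
            labels, maps, membrane_ring_px=int(psec.get("membrane_ring_px", 2))
        )

    if "phenotype" not in cells.columns:
        cells = _phenotype_stage(cells, cfg)
    cells_out = out / "cells.csv"
    io.write_cells(cells, cells_out)
    artifacts["cells"] = cells_out

    graph = sociology.build_graph(cells, roi)
    io.write_edges(graph, out / "edges.csv")
    artifacts["edges"] = out / "edges.csv"
    result = sociology.summarize(graph, cells)
    io.write_sociology(result, out, roi_id=roi_path.stem)
    artifacts["sociology"] = out / "sociology.csv"
    artifacts["density"] = out / "density.csv"

    msec = cfg.section("montecarlo")
    if msec.get("enabled", True):
        present = sorted(
            p
            for p in cells.loc[cells["phenotype"] != phenotyping.EXCLUDED, "phenotype"].unique()
        )
        pairs_cfg = msec.get("pairs", "all")
        if pairs_cfg == "all":
            pairs = list(itertools.product(present, present))
        else:
            pairs = [tuple(p) for p in pairs_cfg]
        seeds["montecarlo"] = cfg.seed
        results = montecarlo.permutation_test_all(
            graph, cells, pairs,
            n_iter=int(msec.get("n_iter", montecarlo.DEFAULT_N_ITER)),
            seed=cfg.seed,
        )
        table = montecarlo.results_table(results, roi_id=roi_path.stem)
        table.to_csv(out / "montecarlo.csv", index=False, float_format=io.FLOAT_FORMAT)
        artifacts["montecarlo"] = out / "montecarlo.csv"

    inputs = {
        k: p for k, p in {
            "roi": roi_path, "cells": cells_path,
            "cube": cfg.input_path("cube"), "spectra": cfg.input_path("spectra"),
        }.items() if p is not None
    }
    io.write_provenance(out / "provenance.json", inputs=inputs, seeds=seeds,
                        parameters=cfg.raw)
    artifacts["provenance"] = out / "provenance.json"
    return artifacts
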
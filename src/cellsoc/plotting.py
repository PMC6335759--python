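"""Plotting utilities (presentation only; no part of the data contract)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["benefit_heatmap"]


def benefit_heatmap(scores: pd.DataFrame, path: str | None = None):
    """Patient × verdict heatmap of ROI benefit scores.

    ``scores`` is the output of :func:`cellsoc.cohort.roi_benefit_score`,
    optionally with a ``cell_type`` column when several phenotypes were
    scored.  Rows are cell types (or a single row), columns are patients,
    cell colour encodes the summed per-ROI benefit.
    """
    df = scores.copy()
    if "cell_type" not in df.columns:
        df["cell_type"] = "all"
    pivot = df.pivot_table(
        index="cell_type", columns="patient_id", values="sociology_delta",
        aggfunc="sum",
    )
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * pivot.shape[1]), 1 + pivot.shape[0]))
    vmax = max(1, int(np.nanmax(np.abs(pivot.to_numpy()))))
    im = ax.imshow(pivot.to_numpy(), cmap="RdYlGn", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=8)
    fig.colorbar(im, ax=ax, label="sociology benefit (sum of ROI scores)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
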
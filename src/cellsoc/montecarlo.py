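"""Fixed-position label-permutation test for neighbor-frequency z-scores.

Whether an observed mean neighbor frequency could arise from a random
arrangement of the same cells is assessed by permuting phenotype labels
over the *fixed* cell positions (the tessellation and adjacency never
change), keeping the number of cells of each phenotype exactly fixed —
sampling labels without replacement, not i.i.d. resampling.  Excluded
cells keep their label and position in every replicate.

For each (focal, neighbor) pair the mean neighbor frequency is recomputed
for ``n_iter`` (default 500) permutations and

    z = (observed − mean(replicates)) / sd(replicates)        (sd: ddof=1)

Highly negative z indicates avoidance, highly positive z colocalization;
|z| > 3 is deemed non-random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotyping import EXCLUDED
from .sociology import NeighborGraph, _phenotype_array, pair_frequency_matrix

__all__ = ["NullDistribution", "permutation_test", "permutation_test_all"]

#: default number of label permutations
DEFAULT_N_ITER = 500
#: |z| above this is deemed non-random
Z_CUTOFF = 3.0


@dataclass
class NullDistribution:
    """Permutation null for one (focal, neighbor) phenotype pair."""

    focal: str
    neighbor: str
    observed: float
    replicates: np.ndarray
    n_iter: int
    seed: int
    z: float | None          # None when the null is degenerate (sd == 0)
    degenerate: bool

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.replicates, ddof=1))

    @property
    def nonrandom(self) -> bool:
        return self.z is not None and abs(self.z) > Z_CUTOFF


def _replicate_matrix(
    graph: NeighborGraph,
    phen: np.ndarray,
    pairs: list[tuple[str, str]],
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_iter, n_pairs) mean neighbor frequencies under label permutation."""
    movable = phen != EXCLUDED
    idx = np.flatnonzero(movable)
    labels = phen.copy()
    focal_types = sorted({f for f, _ in pairs})
    nbr_types = sorted({n for _, n in pairs})
    fi = {F: i for i, F in enumerate(focal_types)}
    ni = {N: i for i, N in enumerate(nbr_types)}
    out = np.empty((n_iter, len(pairs)))
    for r in range(n_iter):
        labels[idx] = phen[idx][rng.permutation(idx.size)]
        M = pair_frequency_matrix(graph.adjacency, labels, focal_types, nbr_types)
        for c, (F, N) in enumerate(pairs):
            out[r, c] = M[fi[F], ni[N]]
    return out


def permutation_test_all(
    graph: NeighborGraph,
    cells: pd.DataFrame,
    pairs: list[tuple[str, str]],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> list[NullDistribution]:
    """Permutation test for several phenotype pairs sharing one replicate set.

    All pairs are evaluated on the same ``n_iter`` label permutations, which
    both saves work and makes the joint null coherent.  Reproducible given
    ``seed``.  Raises if a requested phenotype has no cells.
    """
    phen = _phenotype_array(graph, cells)
    present = set(phen[phen != EXCLUDED])
    for F, N in pairs:
        for p in (F, N):
            if p not in present:
                raise ValueError(f"phenotype {p!r} has no (non-excluded) cells")
    focal_types = sorted({f for f, _ in pairs})
    nbr_types = sorted({n for _, n in pairs})
    obs = pair_frequency_matrix(graph.adjacency, phen, focal_types, nbr_types)
    fi = {F: i for i, F in enumerate(focal_types)}
    ni = {N: i for i, N in enumerate(nbr_types)}
    rng = np.random.default_rng(seed)
    reps = _replicate_matrix(graph, phen, pairs, n_iter, rng)
    results = []
    for c, (F, N) in enumerate(pairs):
        col = reps[:, c]
        observed = float(obs[fi[F], ni[N]])
        sd = float(np.std(col, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            z, degenerate = None, True
        else:
            z, degenerate = float((observed - np.mean(col)) / sd), False
        results.append(
            NullDistribution(
                focal=F, neighbor=N, observed=observed, replicates=col.copy(),
                n_iter=n_iter, seed=seed, z=z, degenerate=degenerate,
            )
        )
    return results


def permutation_test(
    graph: NeighborGraph,
    cells: pd.DataFrame,
    pair: tuple[str, str],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> NullDistribution:
    """Permutation test for one (focal, neighbor) phenotype pair."""
    return permutation_test_all(graph, cells, [pair], n_iter=n_iter, seed=seed)[0]


def results_table(results: list[NullDistribution], roi_id: str = "") -> pd.DataFrame:
    """Flatten permutation results into the standard output table."""
    return pd.DataFrame(
        {
            "roi": roi_id,
            "focal": [r.focal for r in results],
            "neighbor": [r.neighbor for r in results],
            "observed": [r.observed for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "z": [r.z if r.z is not None else np.nan for r in results],
            "nonrandom": [r.nonrandom for r in results],
            "degenerate": [r.degenerate for r in results],
            "n_iter": [r.n_iter for r in results],
            "seed": [r.seed for r in results],
        }
    )
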
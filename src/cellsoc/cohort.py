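"""Cohort-level comparison of density and sociology metrics.

Two questions are addressed for a cohort of patients with a binary outcome
(e.g. recurrent vs non-recurrent disease), each patient contributing
several regions of interest (ROIs):

* do the outcome groups differ in a metric (cell density, or mean neighbor
  frequency)? — a two-sided Mann-Whitney U rank-sum test on per-patient
  values;
* does the sociology metric classify individual patients better than the
  density metric? — a per-ROI +1/0/−1 benefit score.

For the benefit score, each outcome group's mean ± SD interval is computed
per metric over ROI-level values (by default leaving the evaluated
patient's own ROIs out).  An ROI value is *informative* when it lies in
exactly one group's interval, which is then its call.  Per ROI: +1 when the
density is uninformative but sociology calls the true outcome; −1 when
sociology calls the wrong outcome; 0 otherwise.  ROI scores are summed per
patient: Σ > 0 → improved, Σ < 0 → misclassified, Σ = 0 → no change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = ["compare_groups", "roi_benefit_score", "ClassificationScore"]

logger = logging.getLogger(__name__)

#: exact rank-sum distribution is used up to this per-group size (no ties)
EXACT_MAX_N = 20


def _group_values(
    cohort: pd.DataFrame, value_col: str, group_col: str, patient_col: str | None
) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    groups = sorted(cohort[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 outcome groups, got {groups}")
    if patient_col is not None:
        agg = cohort.groupby([patient_col, group_col], sort=True)[value_col].mean()
        agg = agg.reset_index()
    else:
        agg = cohort
    a = agg.loc[agg[group_col] == groups[0], value_col].to_numpy(float)
    b = agg.loc[agg[group_col] == groups[1], value_col].to_numpy(float)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"empty outcome group among {groups}")
    return a, b, (groups[0], groups[1])


def compare_groups(
    cohort: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "outcome",
    patient_col: str | None = "patient_id",
) -> float:
    """Two-sided Mann-Whitney U p-value between the two outcome groups.

    ROI-level rows are first averaged per patient (set ``patient_col=None``
    to rank the rows as given).  The exact rank-sum distribution is used
    when both groups have at most 20 values and there are no ties; the
    normal approximation with tie correction otherwise.
    """
    a, b, _ = _group_values(cohort, value_col, group_col, patient_col)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


@dataclass
class ClassificationScore:
    """Per-patient outcome of the density-vs-sociology ROI benefit score."""

    patient_id: str
    outcome: str
    density_correct: bool     # density informative and right in >= 1 ROI
    sociology_delta: int      # sum of per-ROI {+1, 0, -1}
    verdict: str              # improved | no_change | misclassified


def _interval_call(
    value: float, intervals: dict[str, tuple[float, float]]
) -> str | None:
    """Group name when ``value`` lies in exactly one group's interval."""
    hits = [g for g, (lo, hi) in intervals.items() if lo <= value <= hi]
    return hits[0] if len(hits) == 1 else None


def _group_intervals(
    rows: pd.DataFrame, value_col: str, group_col: str
) -> dict[str, tuple[float, float]]:
    out = {}
    for g, sub in rows.groupby(group_col):
        v = sub[value_col].to_numpy(float)
        mu = float(np.mean(v))
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        if sd == 0.0:
            logger.info("zero-SD interval for group %r (n=%d); collapses to a point",
                        g, v.size)
        out[g] = (mu - sd, mu + sd)
    return out


def roi_benefit_score(
    cohort: pd.DataFrame,
    density_col: str = "density",
    sociology_col: str = "sociology",
    group_col: str = "outcome",
    patient_col: str = "patient_id",
    leave_one_out: bool = True,
) -> pd.DataFrame:
    """Score, per patient, whether sociology beats density at classification.

    ``cohort`` holds one row per ROI with the two metric columns.  Group
    mean ± SD intervals are computed over ROI-level values pooled across the
    group's patients; with ``leave_one_out`` (default) the evaluated
    patient's own ROIs are excluded from those statistics (falling back to
    the full group when the patient is its group's only member).

    Returns one row per patient: ``patient_id, outcome, density_correct,
    sociology_delta, verdict``.
    """
    for col in (density_col, sociology_col, group_col, patient_col):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks column {col!r}")
    groups = sorted(cohort[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 outcome groups, got {groups}")
    records = []
    for patient, mine in cohort.groupby(patient_col, sort=True):
        outcome = mine[group_col].iloc[0]
        if mine[group_col].nunique() > 1:
            raise ValueError(f"patient {patient!r} has multiple outcomes")
        ref = cohort[cohort[patient_col] != patient] if leave_one_out else cohort
        if set(ref[group_col].unique()) != set(groups):
            logger.info("patient %r is its group's only member; using full group",
                        patient)
            ref = cohort
        dens_iv = _group_intervals(ref, density_col, group_col)
        soc_iv = _group_intervals(ref, sociology_col, group_col)
        delta = 0
        density_correct = False
        for _, roi in mine.iterrows():
            dens_call = _interval_call(float(roi[density_col]), dens_iv)
            soc_call = _interval_call(float(roi[sociology_col]), soc_iv)
            if dens_call == outcome:
                density_correct = True
            if soc_call is not None and soc_call != outcome:
                delta -= 1
            elif dens_call is None and soc_call == outcome:
                delta += 1
        verdict = (
            "improved" if delta > 0 else "misclassified" if delta < 0 else "no_change"
        )
        records.append(
            ClassificationScore(
                patient_id=str(patient),
                outcome=str(outcome),
                density_correct=density_correct,
                sociology_delta=delta,
                verdict=verdict,
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])
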
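import itertools

import numpy as np
import pandas as pd
import pytest

from cellsoc import (
    CD3_CD8_T,
    CD3_T,
    CD79A_B,
    EXCLUDED,
    UNSTAINED,
    ConcentrationMaps,
    LabelImage,
    ThresholdSet,
    classify,
    integrate_intensity,
    resolve_conflicts,
)
from cellsoc.phenotyping import DECISION_TREE, raw_group_name

THR = ThresholdSet({"cd3": 10.0, "cd8": 10.0, "cd79a": 10.0})


def make_cells(rows):
    """rows: list of (I_cd3, I_cd8, I_cd79a) with optional centroid info."""
    df = pd.DataFrame(rows)
    df.insert(0, "id", np.arange(1, len(df) + 1))
    for col, default in (("x", 0.0), ("y", 0.0)):
        if col not in df.columns:
            df[col] = default
    return df


def _maps(stains, arrays):
    return ConcentrationMaps(
        stains=list(stains),
        maps=dict(zip(stains, arrays)),
        residual=np.zeros(arrays[0].shape),
        n_iterations=1,
        converged=True,
    )


class TestIntegrateIntensity:
    def test_zero_maps_give_zero_intensities(self):
        labels = np.zeros((20, 20), np.int32)
        labels[5:10, 5:10] = 1
        maps = _maps(["hematoxylin", "cd3", "cd8", "cd79a"], [np.zeros((20, 20))] * 4)
        out = integrate_intensity(LabelImage(labels), maps)
        assert (out[["I_hematoxylin", "I_cd3", "I_cd8", "I_cd79a"]] == 0).all().all()

    def test_constant_concentration_sums_over_area(self):
        labels = np.zeros((20, 20), np.int32)
        labels[5:15, 5:15] = 1  # 100 px
        hem = np.full((20, 20), 0.5)
        maps = _maps(["hematoxylin"], [hem])
        out = integrate_intensity(LabelImage(labels), maps, membrane_ring_px=0)
        assert out.loc[0, "I_hematoxylin"] == pytest.approx(50.0)
        assert out.loc[0, "area_px"] == 100

    def test_known_per_nucleus_totals(self):
        labels = np.zeros((30, 30), np.int32)
        labels[2:6, 2:6] = 1    # 16 px
        labels[20:25, 20:25] = 2  # 25 px
        cd3 = np.zeros((30, 30))
        cd3[2:6, 2:6] = 2.0
        cd3[20:25, 20:25] = 0.4
        maps = _maps(["cd3"], [cd3])
        out = integrate_intensity(LabelImage(labels), maps, membrane_ring_px=0)
        assert out["I_cd3"].to_numpy() == pytest.approx([32.0, 10.0])

    def test_membrane_ring_extends_marker_integration(self):
        labels = np.zeros((21, 21), np.int32)
        labels[9:12, 9:12] = 1
        cd3 = np.ones((21, 21))
        maps = _maps(["cd3"], [cd3])
        no_ring = integrate_intensity(LabelImage(labels), maps, membrane_ring_px=0)
        ring = integrate_intensity(LabelImage(labels), maps, membrane_ring_px=2)
        assert ring.loc[0, "I_cd3"] > no_ring.loc[0, "I_cd3"]

    def test_shape_mismatch_rejected(self):
        labels = np.zeros((10, 10), np.int32)
        maps = _maps(["cd3"], [np.zeros((12, 12))])
        with pytest.raises(ValueError, match="shape"):
            integrate_intensity(LabelImage(labels), maps)


class TestClassify:
    def test_decision_tree_has_exactly_eight_leaves(self):
        assert len(DECISION_TREE) == 8
        assert set(DECISION_TREE) == set(itertools.product([False, True], repeat=3))

    def test_all_sign_patterns_enumerate_eight_groups(self):
        rows = [
            {"I_cd3": 20.0 * c3, "I_cd8": 20.0 * c8, "I_cd79a": 20.0 * c79}
            for c3, c8, c79 in itertools.product([0, 1], repeat=3)
        ]
        out = classify(make_cells(rows), THR)
        assert out["raw_group"].nunique() == 8

    def test_cytotoxic_t_cell_leaf(self):
        out = classify(make_cells([{"I_cd3": 50.0, "I_cd8": 50.0, "I_cd79a": 0.0}]), THR)
        assert out.loc[0, "phenotype"] == CD3_CD8_T
        assert out.loc[0, "raw_group"] == "CD3+CD8+CD79a-"

    def test_all_negative_is_unstained(self):
        out = classify(make_cells([{"I_cd3": 1.0, "I_cd8": 1.0, "I_cd79a": 1.0}]), THR)
        assert out.loc[0, "phenotype"] == UNSTAINED

    def test_inverted_scale_direction(self):
        thr = ThresholdSet({"cd3": 234.0, "cd8": 234.0, "cd79a": 234.0}, "below")
        out = classify(
            make_cells([{"I_cd3": 100.0, "I_cd8": 255.0, "I_cd79a": 255.0}]), thr
        )
        assert out.loc[0, "phenotype"] == CD3_T

    def test_missing_stain_column_rejected(self):
        with pytest.raises(ValueError, match="I_cd8"):
            classify(make_cells([{"I_cd3": 1.0, "I_cd79a": 1.0}]), THR)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        cells = make_cells(
            [
                {"I_cd3": v, "I_cd8": 0.0, "I_cd79a": 0.0}
                for v in rng.uniform(0, 100, 50)
            ]
        )
        counts = []
        for t in (80.0, 50.0, 20.0):
            thr = ThresholdSet({"cd3": t, "cd8": 10.0, "cd79a": 10.0})
            out = classify(cells, thr)
            counts.append((out["raw_group"].str.startswith("CD3+")).sum())
        assert counts == sorted(counts)


class TestResolveConflicts:
    def test_cd8_only_cell_becomes_unstained_without_split(self):
        cells = classify(make_cells([{"I_cd3": 0.0, "I_cd8": 50.0, "I_cd79a": 0.0}]), THR)
        out = resolve_conflicts(cells)
        assert len(out) == 1
        assert out.loc[0, "phenotype"] == UNSTAINED

    def test_overlapping_conflict_splits_into_t_and_b(self):
        cells = classify(
            make_cells(
                [
                    {
                        "I_cd3": 60.0,
                        "I_cd8": 0.0,
                        "I_cd79a": 40.0,
                        "x": 10.0,
                        "y": 10.0,
                        "cx_cd3": 8.0,
                        "cy_cd3": 10.0,
                        "cx_cd79a": 12.0,
                        "cy_cd79a": 10.0,
                    }
                ]
            ),
            THR,
        )
        out = resolve_conflicts(cells, overlap_min_offset_px=2.0)
        assert len(out) == 2
        assert set(out["phenotype"]) == {CD3_T, CD79A_B}
        child = out[out["origin"] == "split_added"].iloc[0]
        assert child["parent_id"] == 1
        assert child["phenotype"] == CD79A_B  # minority stain
        assert (child["x"], child["y"]) == (12.0, 10.0)

    def test_triple_positive_split_keeps_cd8_status(self):
        cells = classify(
            make_cells(
                [
                    {
                        "I_cd3": 60.0,
                        "I_cd8": 30.0,
                        "I_cd79a": 40.0,
                        "cx_cd3": 0.0,
                        "cy_cd3": 0.0,
                        "cx_cd79a": 5.0,
                        "cy_cd79a": 0.0,
                    }
                ]
            ),
            THR,
        )
        out = resolve_conflicts(cells)
        assert set(out["phenotype"]) == {CD3_CD8_T, CD79A_B}

    def test_conflict_without_offset_evidence_excluded(self):
        cells = classify(
            make_cells(
                [
                    {
                        "I_cd3": 60.0,
                        "I_cd8": 0.0,
                        "I_cd79a": 40.0,
                        "cx_cd3": 10.0,
                        "cy_cd3": 10.0,
                        "cx_cd79a": 10.5,
                        "cy_cd79a": 10.0,
                    }
                ]
            ),
            THR,
        )
        out = resolve_conflicts(cells, overlap_min_offset_px=2.0)
        assert len(out) == 1
        assert out.loc[0, "phenotype"] == EXCLUDED

    def test_conservation_splits_add_exactly_one(self):
        rows = [
            {"I_cd3": 0.0, "I_cd8": 0.0, "I_cd79a": 0.0},
            {"I_cd3": 50.0, "I_cd8": 0.0, "I_cd79a": 0.0},
            {
                "I_cd3": 60.0, "I_cd8": 0.0, "I_cd79a": 40.0,
                "cx_cd3": 0.0, "cy_cd3": 0.0, "cx_cd79a": 9.0, "cy_cd79a": 0.0,
            },
        ]
        cells = classify(make_cells(rows), THR)
        out = resolve_conflicts(cells)
        assert len(out) == 4
        assert (out["origin"] == "split_added").sum() == 1

    def test_determinism(self):
        rng = np.random.default_rng(1)
        rows = [
            {
                "I_cd3": rng.uniform(0, 100),
                "I_cd8": rng.uniform(0, 100),
                "I_cd79a": rng.uniform(0, 100),
                "cx_cd3": rng.uniform(0, 5),
                "cy_cd3": 0.0,
                "cx_cd79a": rng.uniform(0, 5),
                "cy_cd79a": 0.0,
            }
            for _ in range(30)
        ]
        cells = make_cells(rows)
        a = resolve_conflicts(classify(cells, THR))
        b = resolve_conflicts(classify(cells, THR))
        pd.testing.assert_frame_equal(a, b)


def test_raw_group_name_formatting():
    assert raw_group_name((True, False, True)) == "CD3+CD8-CD79a+"
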
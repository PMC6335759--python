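import numpy as np
import pandas as pd
import pytest

from cellsoc import (
    CD3_T,
    EXCLUDED,
    ROI,
    UNSTAINED,
    DegenerateGeometryError,
    TissueModel,
    build_graph,
    generate_tissue,
    neighbor_frequency,
    per_cell_frequencies,
    ring_tissue,
    summarize,
)
from oracles import rook_adjacency, voronoi_adjacency_bruteforce


def cells_from_points(pts, phenotypes=None):
    n = len(pts)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "x": [p[0] for p in pts],
            "y": [p[1] for p in pts],
            "phenotype": phenotypes if phenotypes is not None else [UNSTAINED] * n,
        }
    )


class TestBuildGraph:
    def test_triangle_is_complete(self):
        cells = cells_from_points([(0, 0), (10, 0), (5, 8)])
        g = build_graph(cells, ROI.rectangle(-50, -50, 60, 60))
        assert g.n_edges == 3
        for cid in (1, 2, 3):
            assert len(g.neighbors(cid)) == 2

    def test_cocircular_square_has_no_diagonal_edges(self):
        # four cocircular points: the central Voronoi vertex is a point
        # contact between diagonal cells and must not create adjacency
        cells = cells_from_points([(0, 0), (1, 0), (0, 1), (1, 1)])
        g = build_graph(cells, ROI.rectangle(-0.5, -0.5, 1.5, 1.5))
        assert g.n_edges == 4
        assert all(len(g.neighbors(c)) == 2 for c in (1, 2, 3, 4))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_halfplane_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 120))
        pts = rng.uniform(0, 200, size=(n, 2))
        roi = ROI.rectangle(0, 0, 200, 200)
        cells = cells_from_points(pts)
        g = build_graph(cells, roi)
        got = {
            (min(a, b) - 1, max(a, b) - 1)
            for a, b in zip(g.edges["id_a"], g.edges["id_b"])
        }
        expected = voronoi_adjacency_bruteforce(pts, roi.polygon)
        assert got == expected

    def test_roi_clipping_removes_distant_adjacency(self):
        # the two far-apart base points of a triangle share only a distant
        # ridge (below y ~ -26.7); a tight ROI clips it away entirely
        pts = [(0, 0), (100, 0), (50, 30)]
        cells = cells_from_points(pts)
        wide = build_graph(cells, ROI.rectangle(-200, -400, 300, 400))
        tight = build_graph(cells, ROI.rectangle(-200, -20, 300, 40))
        pair = (1, 2)
        wide_pairs = set(zip(wide.edges["id_a"], wide.edges["id_b"]))
        tight_pairs = set(zip(tight.edges["id_a"], tight.edges["id_b"]))
        assert pair in wide_pairs
        assert pair not in tight_pairs

    def test_symmetry_and_no_self_edges(self):
        cells, roi = _random_tissue(150, seed=9)
        g = build_graph(cells, roi)
        A = g.adjacency
        assert (A != A.T).nnz == 0
        assert A.diagonal().sum() == 0

    def test_cells_outside_roi_ignored(self):
        pts = [(1, 1), (5, 1), (3, 4), (50, 50)]
        cells = cells_from_points(pts)
        g = build_graph(cells, ROI.rectangle(0, 0, 10, 10))
        assert g.n_nodes == 3

    def test_too_few_cells_raises(self):
        cells = cells_from_points([(0, 0), (5, 5)])
        with pytest.raises(DegenerateGeometryError):
            build_graph(cells, ROI.rectangle(-1, -1, 10, 10))

    def test_collinear_cells_raise(self):
        cells = cells_from_points([(0, 0), (1, 1), (2, 2), (3, 3)])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            build_graph(cells, ROI.rectangle(-1, -1, 10, 10))

    def test_duplicate_centroids_jittered(self):
        cells = cells_from_points([(0, 0), (0, 0), (5, 0), (2, 4)])
        g = build_graph(cells, ROI.rectangle(-10, -10, 10, 10))
        assert g.n_nodes == 4


def _random_tissue(n, seed):
    model = TissueModel(
        n_cells=n,
        regime="uniform",
        proportions={UNSTAINED: 0.6, CD3_T: 0.4},
        seed=seed,
    )
    return generate_tissue(model)


class TestNeighborFrequency:
    def test_five_neighbor_worked_example(self):
        cells, roi, focal = ring_tissue(
            ["red", "blue", "yellow", "yellow", "yellow"], "red"
        )
        g = build_graph(cells, roi)
        assert neighbor_frequency(g, cells, focal, "red") == pytest.approx(0.2)
        assert neighbor_frequency(g, cells, focal, "blue") == pytest.approx(0.2)
        assert neighbor_frequency(g, cells, focal, "yellow") == pytest.approx(0.6)

    def test_homogeneous_eight_neighbor_example(self):
        cells, roi, focal = ring_tissue(["red"] * 8, "red")
        g = build_graph(cells, roi)
        assert neighbor_frequency(g, cells, focal, "red") == pytest.approx(1.0)

    def test_thirteen_neighbor_example_to_three_decimals(self):
        cells, roi, focal = ring_tissue(["red"] * 10 + ["blue"] * 2 + ["green"], "blue")
        g = build_graph(cells, roi)
        assert round(neighbor_frequency(g, cells, focal, "red"), 3) == 0.769
        assert round(neighbor_frequency(g, cells, focal, "blue"), 3) == 0.154
        assert round(neighbor_frequency(g, cells, focal, "green"), 3) == 0.077

    def test_excluded_neighbors_out_of_numerator_and_denominator(self):
        labels = ["red", "red", EXCLUDED, "blue"]
        cells, roi, focal = ring_tissue(labels, "red")
        g = build_graph(cells, roi)
        assert neighbor_frequency(g, cells, focal, "red") == pytest.approx(2 / 3)
        assert neighbor_frequency(g, cells, focal, "blue") == pytest.approx(1 / 3)

    def test_all_neighbors_excluded_raises(self):
        cells, roi, focal = ring_tissue([EXCLUDED] * 4, "red")
        g = build_graph(cells, roi)
        with pytest.raises(ValueError, match="no non-excluded"):
            neighbor_frequency(g, cells, focal, "red")


class TestSummarize:
    def test_homogeneous_tissue_mean_one_sd_zero(self):
        cells, roi = _random_tissue(80, seed=3)
        cells["phenotype"] = UNSTAINED
        g = build_graph(cells, roi)
        res = summarize(g, cells)
        row = res.frequencies.query("focal == @UNSTAINED and neighbor == @UNSTAINED")
        assert row["mean_frequency"].iloc[0] == pytest.approx(1.0)
        assert row["sd"].iloc[0] == pytest.approx(0.0)
        assert row["n_focal_cells"].iloc[0] == len(cells)

    def test_grid_fixture_matches_rook_adjacency_hand_count(self):
        # perfect 4x5 grid: Voronoi adjacency is exactly rook adjacency,
        # so the expected means are computable independently of the package
        n_rows, n_cols = 4, 5
        rng = np.random.default_rng(11)
        labels = rng.choice([UNSTAINED, CD3_T], size=n_rows * n_cols)
        xs = [(c + 0.5) * 10 for r in range(n_rows) for c in range(n_cols)]
        ys = [(r + 0.5) * 10 for r in range(n_rows) for c in range(n_cols)]
        cells = pd.DataFrame(
            {"id": np.arange(1, 21), "x": xs, "y": ys, "phenotype": labels}
        )
        g = build_graph(cells, ROI.rectangle(0, 0, n_cols * 10, n_rows * 10))
        res = summarize(g, cells)
        adj = rook_adjacency(n_rows, n_cols)
        for F in (UNSTAINED, CD3_T):
            for N in (UNSTAINED, CD3_T):
                fr = [
                    np.mean([labels[j] == N for j in adj[i]])
                    for i in range(20)
                    if labels[i] == F
                ]
                row = res.frequencies.query("focal == @F and neighbor == @N")
                assert row["mean_frequency"].iloc[0] == pytest.approx(np.mean(fr))
                assert row["n_focal_cells"].iloc[0] == len(fr)

    def test_density_is_count_over_area(self):
        # 200 cells in a 0.1 mm^2 ROI -> 2000 cells/mm^2
        side_px = np.sqrt(0.1) / (0.33 / 1000)  # 0.1 mm^2 square, 0.33 um px
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, side_px, size=(200, 2))
        cells = cells_from_points(pts)
        g = build_graph(cells, ROI.rectangle(0, 0, side_px, side_px))
        res = summarize(g, cells)
        dens = res.densities.set_index("phenotype")["density_per_mm2"]
        assert dens[UNSTAINED] == pytest.approx(2000.0, rel=1e-6)

    def test_missing_focal_phenotype_reported_null(self):
        cells, roi = _random_tissue(50, seed=5)
        cells["phenotype"] = UNSTAINED
        g = build_graph(cells, roi)
        res = summarize(g, cells, phenotypes=(UNSTAINED, CD3_T))
        row = res.frequencies.query("focal == @CD3_T and neighbor == @UNSTAINED")
        assert row["n_focal_cells"].iloc[0] == 0
        assert np.isnan(row["mean_frequency"].iloc[0])

    def test_per_cell_frequencies_sum_to_one(self):
        cells, roi = _random_tissue(120, seed=6)
        g = build_graph(cells, roi)
        freq = per_cell_frequencies(g, cells)
        sums = freq.groupby("id")["frequency"].sum()
        assert np.allclose(sums, 1.0)

    def test_invariance_under_similarity_transform(self):
        cells, roi = _random_tissue(90, seed=7)
        g = build_graph(cells, roi)
        base = summarize(g, cells).frequencies

        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        scale, shift = 2.5, np.array([37.0, -11.0])
        pts = cells[["x", "y"]].to_numpy() @ R.T * scale + shift
        moved = cells.copy()
        moved["x"], moved["y"] = pts[:, 0], pts[:, 1]
        import shapely

        poly = shapely.transform(
            roi.polygon, lambda a: a @ R.T * scale + shift
        )
        g2 = build_graph(moved, ROI(poly, roi.pixel_spacing_um))
        moved_res = summarize(g2, moved).frequencies
        pd.testing.assert_frame_equal(base, moved_res)

    def test_rare_clustered_phenotypes_high_frequency_low_density(self):
        # density and neighbor frequency are decoupled: two rare phenotypes
        # packed into one tight cluster neighbor each other almost always
        rng = np.random.default_rng(8)
        background = rng.uniform(0, 1000, size=(300, 2))
        cluster = rng.normal(500, 5, size=(30, 2))
        pts = np.vstack([background, cluster])
        labels = [UNSTAINED] * 300 + ["rare_a"] * 15 + ["rare_b"] * 15
        cells = cells_from_points(pts, labels)
        g = build_graph(cells, ROI.rectangle(0, 0, 1000, 1000))
        res = summarize(g, cells, phenotypes=(UNSTAINED, "rare_a", "rare_b"))
        f = res.frequencies.set_index(["focal", "neighbor"])["mean_frequency"]
        dens = res.densities.set_index("phenotype")["density_per_mm2"]
        assert dens["rare_a"] < 0.1 * dens[UNSTAINED]
        cross = f[("rare_a", "rare_b")] + f[("rare_a", "rare_a")]
        assert cross > 0.8  # rare cells overwhelmingly neighbor each other
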
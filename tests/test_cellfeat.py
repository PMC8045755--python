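"""Per-nucleus morphometry and Delaunay distance features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk, ellipse

from histomorph.cellfeat import (
    build_neighbor_graph,
    compute_distance_features,
    compute_nucleus_features,
    extract_cell_features,
)

TRIANGLE = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])


def _region_image(rr, cc, color=(120, 60, 200), shape=(100, 100)):
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    img = np.zeros((*shape, 3), np.uint8)
    img[rr, cc] = color
    return mask, img


class TestNucleusFeatures:
    def test_axis_ratio_of_ellipse(self):
        rr, cc = ellipse(50, 50, 20, 10)
        mask, img = _region_image(rr, cc)
        f = compute_nucleus_features(mask, img)
        assert f["ratio"] == pytest.approx(2.0, abs=0.05)
        assert f["major"] == pytest.approx(40.0, rel=0.05)

    def test_uniform_color_means(self):
        rr, cc = disk((50, 50), 8)
        mask, img = _region_image(rr, cc, color=(120, 60, 200))
        f = compute_nucleus_features(mask, img)
        assert (f["rMean"], f["gMean"], f["bMean"]) == (120.0, 60.0, 200.0)

    def test_disk_area_and_roundness(self):
        rr, cc = disk((50, 50), 10)
        mask, img = _region_image(rr, cc)
        f = compute_nucleus_features(mask, img)
        assert f["ratio"] == pytest.approx(1.0, abs=0.05)
        assert f["area"] == pytest.approx(100 * np.pi, rel=0.05)

    def test_single_pixel_clamped(self):
        mask, img = _region_image(np.array([5]), np.array([5]))
        with pytest.warns(UserWarning, match="degenerate"):
            f = compute_nucleus_features(mask, img)
        assert f["minor"] == 1.0
        assert f["ratio"] >= 1.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_nucleus_features(np.zeros((10, 10), bool), np.zeros((10, 10, 3), np.uint8))


class TestNeighborGraph:
    def test_triangle_fully_connected(self):
        assert build_neighbor_graph(TRIANGLE) == {(0, 1), (0, 2), (1, 2)}

    def test_unit_square_one_diagonal(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        edges = build_neighbor_graph(pts)
        diagonals = {(0, 3), (1, 2)}
        assert len(edges & diagonals) == 1
        assert len(edges) == 5  # 4 hull edges + exactly one diagonal

    def test_two_points_single_edge(self):
        assert build_neighbor_graph(np.array([[0.0, 0.0], [2.0, 1.0]])) == {(0, 1)}

    def test_single_point_empty_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert build_neighbor_graph(np.array([[1.0, 1.0]])) == set()

    def test_collinear_points_form_path(self):
        pts = np.array([[0.0, 0.0], [0.0, 2.0], [0.0, 1.0], [0.0, 3.0]])
        edges = build_neighbor_graph(pts)
        # path in coordinate order: 0-2, 2-1, 1-3
        assert edges == {(0, 2), (1, 2), (1, 3)}


class TestDistanceFeatures:
    def test_triangle_worked_example(self):
        edges = build_neighbor_graph(TRIANGLE)
        df = compute_distance_features(edges, TRIANGLE)
        assert tuple(df.loc[0]) == (3.5, 4.0, 3.0)  # node at the right angle
        assert tuple(df.loc[1]) == (4.0, 5.0, 3.0)

    def test_single_neighbor_all_equal(self):
        df = compute_distance_features({(0, 1)}, np.array([[0.0, 0.0], [0.0, 7.0]]))
        assert (df.loc[0] == 7.0).all()

    def test_isolated_node_nan(self):
        df = compute_distance_features({(0, 1)}, np.array([[0, 0], [0, 1], [9, 9]], float))
        assert df.loc[2].isna().all()

    def test_max_edge_length_prunes(self):
        edges = {(0, 1), (1, 2)}
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 100.0]])
        df = compute_distance_features(edges, pts, max_edge_length=10)
        assert df.loc[2].isna().all()
        assert df.loc[0, "distMean"] == 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_order_invariants_random_points(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(12, 2))
        edges = build_neighbor_graph(pts)
        df = compute_distance_features(edges, pts)
        ok = df.dropna()
        assert (ok["distMin"] <= ok["distMean"] + 1e-12).all()
        assert (ok["distMean"] <= ok["distMax"] + 1e-12).all()
        # symmetry: each edge contributes to both endpoints
        for i, j in edges:
            d = float(np.hypot(*(pts[i] - pts[j])))
            assert df.loc[i, "distMin"] <= d + 1e-9 <= df.loc[i, "distMax"] + 2e-9
            assert df.loc[j, "distMin"] <= d + 1e-9 <= df.loc[j, "distMax"] + 2e-9


class TestExtractCellFeatures:
    def test_full_table_on_tile(self, tile50):
        image, mask, truth = tile50
        table = extract_cell_features(mask.astype(np.int32), image)
        assert len(table) == 50
        feature_cols = [c for c in table.columns if c not in ("id", "row", "col")]
        assert len(feature_cols) == 10
        assert (table["area"].to_numpy() == truth["area"].to_numpy()).all()
        assert table["ratio"].min() >= 1.0

    def test_permutation_invariance(self, tile50):
        image, mask, _ = tile50
        table = extract_cell_features(mask.astype(np.int32), image)
        # relabel nuclei in reverse order; same rows modulo sorting
        remap = np.zeros(51, np.int32)
        remap[1:] = np.arange(50, 0, -1)
        table2 = extract_cell_features(remap[mask.astype(np.int32)], image)
        a = table.sort_values(["row", "col"]).reset_index(drop=True).drop(columns="id")
        b = table2.sort_values(["row", "col"]).reset_index(drop=True).drop(columns="id")
        pd.testing.assert_frame_equal(a, b)

    def test_micron_scaling(self, tile50):
        image, mask, _ = tile50
        px = extract_cell_features(mask.astype(np.int32), image)
        um = extract_cell_features(mask.astype(np.int32), image, scale_um_per_px=0.5)
        assert np.allclose(um["area"], px["area"] * 0.25)
        assert np.allclose(um["distMean"].dropna(), px["distMean"].dropna() * 0.5)
        assert np.allclose(um["ratio"], px["ratio"])  # dimensionless
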
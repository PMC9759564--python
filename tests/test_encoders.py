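"""Geometry and invariants of the three image encodings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tab2pix import (EncodingConfig, encode_bar_graph, encode_combined,
                     encode_dataset, encode_distance_matrix, encode_row,
                     minmax_normalize, simulate, SimSpec)
from tab2pix.encoders import bar_graph_width, upscale

unit_floats = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
vectors = st.lists(unit_floats, min_size=1, max_size=20).map(np.array)
pair_vectors = st.lists(unit_floats, min_size=2, max_size=20).map(np.array)


class TestBarGraph:
    def test_base_width_formula(self):
        # psi*d + gamma*(d+1) with the default psi=1, gamma=2
        assert bar_graph_width(10) == 32
        assert encode_bar_graph(np.zeros(10)).pixels.shape == (32, 32)

    @pytest.mark.parametrize("psi,expected", [(1, 32), (2, 42), (4, 62)])
    def test_px_variants_change_width(self, psi, expected):
        cfg = EncodingConfig(method="bar_graph", psi=psi)
        assert encode_bar_graph(np.zeros(10), cfg).pixels.shape[0] == expected

    def test_single_full_bar_fills_middle_column(self):
        # d=1: side 5, the bar occupies column 2 from bottom to top
        img = encode_bar_graph(np.array([1.0])).pixels
        expected = np.zeros((5, 5))
        expected[:, 2] = 1.0
        np.testing.assert_array_equal(img, expected)

    def test_zero_vector_gives_blank_canvas(self):
        assert encode_bar_graph(np.zeros(7)).pixels.sum() == 0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(x=vectors, psi=st.sampled_from([1, 2, 4]))
    def test_foreground_count_matches_rounded_heights(self, x, psi):
        cfg = EncodingConfig(method="bar_graph", psi=psi)
        img = encode_bar_graph(x, cfg).pixels
        side = bar_graph_width(x.size, psi)
        expected = int(np.floor(x * side + 0.5).sum()) * psi
        assert img.shape == (side, side)
        assert int(img.sum()) == expected
        assert set(np.unique(img)) <= {0.0, 1.0}

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            encode_bar_graph(np.array([0.5, 1.2]))


class TestDistanceMatrix:
    def test_three_point_oracle(self):
        # brute-force pairwise |x_i - x_j| divided by its maximum
        cfg = EncodingConfig(method="distance_matrix", upscale=1)
        img = encode_distance_matrix(np.array([0.0, 0.5, 1.0]), cfg).pixels
        np.testing.assert_allclose(
            img, [[0, 0.5, 1], [0.5, 0, 0.5], [1, 0.5, 0]])

    def test_constant_vector_gives_zero_matrix(self):
        cfg = EncodingConfig(method="distance_matrix", upscale=1)
        img = encode_distance_matrix(np.full(4, 0.3), cfg).pixels
        assert img.sum() == 0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(x=pair_vectors)
    def test_symmetric_zero_diagonal_max_normalized(self, x):
        cfg = EncodingConfig(method="distance_matrix", upscale=1)
        m = encode_distance_matrix(x, cfg).pixels
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_array_equal(np.diag(m), 0)
        if np.ptp(x) > 0:
            assert m.max() == 1.0

    def test_default_upscale_replicates_pixels_threefold(self):
        x = np.array([0.0, 0.5, 1.0])
        base = encode_distance_matrix(
            x, EncodingConfig(method="distance_matrix", upscale=1)).pixels
        scaled = encode_distance_matrix(x).pixels
        assert scaled.shape == (9, 9)
        np.testing.assert_array_equal(scaled, np.kron(base, np.ones((3, 3))))

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            encode_distance_matrix(np.array([0.5]))


class TestCombined:
    def test_two_feature_example(self):
        img = encode_combined(np.array([0.2, 0.8])).pixels
        assert img.shape == (6, 6, 3)
        np.testing.assert_allclose(img[0:3, :, 2], 0.2)
        np.testing.assert_allclose(img[3:6, :, 2], 0.8)

    def test_first_channel_is_upscaled_distance_matrix(self):
        x = np.linspace(0, 1, 5)
        combined = encode_combined(x).pixels
        dist = encode_distance_matrix(
            x, EncodingConfig(method="distance_matrix", upscale=3)).pixels
        np.testing.assert_array_equal(combined[:, :, 0], dist)

    def test_second_channel_is_center_cropped_bar_graph(self):
        x = np.linspace(0, 1, 4)
        combined = encode_combined(x).pixels
        bars = encode_bar_graph(x).pixels  # 14x14 for d=4
        np.testing.assert_array_equal(combined[:, :, 1], bars[1:-1, 1:-1])

    def test_constant_vector_degenerates_cleanly(self):
        img = encode_combined(np.full(3, 0.4)).pixels
        assert img[:, :, 0].sum() == 0
        np.testing.assert_allclose(img[:, :, 2], 0.4)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(x=pair_vectors)
    def test_square_3d_canvas_with_unit_intensities(self, x):
        img = encode_combined(x).pixels
        s = 3 * x.size
        assert img.shape == (s, s, 3)
        assert img.min() >= 0 and img.max() <= 1


class TestDatasetEncoding:
    def test_images_manifest_and_quantization(self, normalized_dataset, tmp_path):
        cfg = EncodingConfig(method="combined")
        images = encode_dataset(normalized_dataset, cfg, tmp_path)
        assert len(images) == normalized_dataset.n_rows
        manifest = (tmp_path / "manifest.csv").read_text().strip().splitlines()
        assert len(manifest) == normalized_dataset.n_rows + 1
        pngs = sorted(tmp_path.glob("*.png"))
        assert len(pngs) == normalized_dataset.n_rows

    def test_field_order_commutes_with_permutation(self, normalized_dataset):
        d = normalized_dataset.n_features
        order = tuple(range(d, 0, -1))
        cfg = EncodingConfig(method="bar_graph", field_order=order)
        direct = encode_row(normalized_dataset.features[0], cfg)
        manual = encode_bar_graph(normalized_dataset.features[0][::-1])
        np.testing.assert_array_equal(direct.pixels, manual.pixels)

    def test_invalid_field_order_rejected(self, normalized_dataset):
        cfg = EncodingConfig(method="bar_graph", field_order=(1, 1, 2, 3, 4, 5))
        with pytest.raises(ValueError, match="permutation"):
            encode_row(normalized_dataset.features[0], cfg)

    def test_unnormalized_dataset_rejected(self, small_dataset, tmp_path):
        with pytest.raises(ValueError, match="normalize"):
            encode_dataset(small_dataset, EncodingConfig(), tmp_path)

    def test_encoding_is_deterministic(self, normalized_dataset):
        cfg = EncodingConfig(method="combined")
        a = encode_row(normalized_dataset.features[3], cfg).pixels
        b = encode_row(normalized_dataset.features[3], cfg).pixels
        np.testing.assert_array_equal(a, b)


def test_upscale_is_exact_block_replication():
    rng = np.random.default_rng(0)
    img = rng.random((4, 4))
    up = upscale(img, 3)
    for i in range(4):
        for j in range(4):
            np.testing.assert_array_equal(
                up[3 * i:3 * i + 3, 3 * j:3 * j + 3], img[i, j])
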
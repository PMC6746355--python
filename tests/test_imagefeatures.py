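"""Gabor bank, dense SIFT + VBOW, HSV histogram, word vectors and fusion."""

import numpy as np
import pytest

from eegretrieve.imagefeatures import (
    FeatureBlock,
    WordVectorTable,
    build_gabor_bank,
    dense_sift,
    fuse,
    gabor_features,
    gabor_kernel,
    hsv_histogram,
    range_normalize_rows,
    semantic_vector,
    train_codebook,
    vbow_histogram,
)


def gabor_scalar(x, y, lam, theta, psi, sigma, gamma):
    """Oracle: direct scalar evaluation of the Gabor equation (real part)."""
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    return (np.exp(-(xr ** 2 + gamma ** 2 * yr ** 2) / (2 * sigma ** 2))
            * np.cos(2 * np.pi * xr / lam + psi))


class TestGaborBank:
    def test_default_bank_has_32_filters(self):
        bank = build_gabor_bank()
        assert len(bank) == 32
        assert len({(p["theta"], p["sigma"]) for p in bank.params}) == 32

    def test_kernel_matches_scalar_formula(self):
        k = gabor_kernel(ksize=9, sigma=3.0, theta=0.7, lam=6.0,
                         gamma=0.5, psi=0.0)
        for row, col in [(0, 0), (4, 4), (2, 7), (8, 1)]:
            x, y = col - 4, row - 4
            assert k[row, col] == pytest.approx(
                gabor_scalar(x, y, 6.0, 0.7, 0.0, 3.0, 0.5), abs=1e-12)

    def test_orthogonal_orientations_are_transposes_at_unit_aspect(self):
        k0 = gabor_kernel(31, 3.0, 0.0, 6.0, 1.0, 0.0)
        k90 = gabor_kernel(31, 3.0, np.pi / 2, 6.0, 1.0, 0.0)
        np.testing.assert_allclose(k90, k0.T, atol=1e-12)

    def test_even_ksize_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            build_gabor_bank(ksize=30)


class TestGaborFeatures:
    def test_vector_length_32(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        assert gabor_features(img, build_gabor_bank()).shape == (32,)

    def test_zero_image_gives_zero_vector(self):
        out = gabor_features(np.zeros((16, 16)), build_gabor_bank())
        np.testing.assert_allclose(out, 0.0)

    def test_matches_nested_loop_convolution_oracle(self):
        """Each entry equals a direct 'same'-mode convolution + sum."""
        rng = np.random.default_rng(1)
        img = rng.random((8, 8))
        bank = build_gabor_bank(n_orientations=2, sigmas=(2.0,), ksize=5)
        got = gabor_features(img, bank, standardize=False)
        std = img    # oracle on the un-standardised image
        for j, kern in enumerate(bank.filters):
            acc = 0.0
            kh = kern.shape[0] // 2
            for r in range(8):
                for c in range(8):
                    v = 0.0
                    for dr in range(-kh, kh + 1):
                        for dc in range(-kh, kh + 1):
                            rr, cc = r - dr, c - dc
                            if 0 <= rr < 8 and 0 <= cc < 8:
                                v += std[rr, cc] * kern[dr + kh, dc + kh]
                    acc += v
            assert got[j] == pytest.approx(acc, abs=1e-6)

    def test_commutes_with_intensity_scaling(self):
        rng = np.random.default_rng(2)
        img = rng.random((24, 24))
        bank = build_gabor_bank(sigmas=(2.0, 3.0))
        base = gabor_features(img, bank, standardize=False)
        scaled = gabor_features(3.5 * img, bank, standardize=False)
        np.testing.assert_allclose(scaled, 3.5 * base, rtol=1e-10)


class TestDenseSift:
    def test_descriptor_dimensionality_and_grid_count(self):
        rng = np.random.default_rng(3)
        img = rng.random((64, 64))
        descs = dense_sift(img, grid_step=8, patch_size=16)
        assert descs.shape[1] == 128
        assert len(descs) == 7 * 7      # (64-16)/8+1 per axis

    def test_uniform_image_has_no_gradients(self):
        descs = dense_sift(np.full((48, 48), 0.5), grid_step=8)
        assert np.linalg.norm(descs, axis=1).max() < 1e-9

    def test_tiny_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="support"):
            descs = dense_sift(np.zeros((8, 8)))
        assert descs.shape == (0, 128)

    def test_rotation_permutes_orientation_mass(self):
        """A vertical-edge image and its 90-degree rotation put their
        gradient energy in orientation bins a quarter-turn apart."""
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0               # vertical edge: horizontal gradient
        d1 = dense_sift(img, grid_step=32, patch_size=32)[0].reshape(4, 4, 8)
        d2 = dense_sift(np.rot90(img), grid_step=32,
                        patch_size=32)[0].reshape(4, 4, 8)
        b1 = np.argmax(d1.sum(axis=(0, 1)))
        b2 = np.argmax(d2.sum(axis=(0, 1)))
        assert (b1 - b2) % 8 == 2       # 90 deg = 2 bins of 45 deg


class TestCodebook:
    def test_k_distinct_points_are_their_own_centroids(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 128)) * 10
        cb = train_codebook(pts, k=5, seed=0)
        d = np.linalg.norm(pts[:, None] - cb.centroids[None], axis=2)
        assert d.min(axis=1).max() < 1e-6

    def test_two_blob_centroids_near_blob_means(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 0.01, size=(50, 128))
        b = rng.normal(1.0, 0.01, size=(50, 128))
        cb = train_codebook(np.vstack([a, b]), k=2, seed=0)
        means = sorted(cb.centroids.mean(axis=1))
        assert means[0] == pytest.approx(0.0, abs=0.1)
        assert means[1] == pytest.approx(1.0, abs=0.1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(60, 128))
        cb1 = train_codebook(pts, k=4, seed=9)
        cb2 = train_codebook(pts, k=4, seed=9)
        np.testing.assert_array_equal(cb1.centroids, cb2.centroids)


class TestVbow:
    def test_exact_centroid_hits(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 128)) * 5
        cb = train_codebook(pts, k=10, seed=0)
        descs = np.stack([cb.centroids[3], cb.centroids[3], cb.centroids[7]])
        hist = vbow_histogram(descs, cb)
        assert hist[3] == 2 and hist[7] == 1 and hist.sum() == 3

    def test_histogram_sums_to_descriptor_count(self):
        rng = np.random.default_rng(8)
        cb = train_codebook(rng.normal(size=(20, 128)), k=6, seed=0)
        descs = rng.normal(size=(37, 128))
        assert vbow_histogram(descs, cb).sum() == 37

    def test_matches_exhaustive_nearest_neighbour_oracle(self):
        rng = np.random.default_rng(9)
        cb = train_codebook(rng.normal(size=(30, 128)), k=8, seed=0)
        descs = rng.normal(size=(100, 128))
        expected = np.zeros(8)
        for d in descs:
            dists = [np.linalg.norm(d - c) for c in cb.centroids]
            expected[int(np.argmin(dists))] += 1
        np.testing.assert_array_equal(vbow_histogram(descs, cb), expected)

    def test_empty_descriptor_list_gives_zero_histogram(self):
        rng = np.random.default_rng(10)
        cb = train_codebook(rng.normal(size=(20, 128)), k=4, seed=0)
        assert vbow_histogram(np.empty((0, 128)), cb).sum() == 0


class TestHsvHistogram:
    def test_output_length_48(self):
        rng = np.random.default_rng(11)
        img = rng.integers(0, 256, size=(10, 10, 3), dtype=np.uint8)
        assert hsv_histogram(img).shape == (48,)

    def test_uniform_colour_concentrates_one_bin_per_channel(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[..., 0] = 200
        img[..., 1] = 60
        img[..., 2] = 40
        hist = hsv_histogram(img)
        for c in range(3):
            chan = hist[c * 16:(c + 1) * 16]
            assert (chan > 0).sum() == 1
            assert chan.sum() == 100

    def test_bins_match_per_pixel_conversion_oracle(self):
        import colorsys

        img = np.array([[[255, 0, 0], [0, 255, 0]],
                        [[10, 20, 200], [128, 128, 128]]], dtype=np.uint8)
        hist = hsv_histogram(img)
        expected = np.zeros(48)
        for px in img.reshape(-1, 3):
            h, s, v = colorsys.rgb_to_hsv(*(px / 255.0))
            for c, val in enumerate((h, s, v)):
                expected[c * 16 + min(int(val * 16), 15)] += 1
        np.testing.assert_array_equal(hist, expected)

    def test_channel_sums_conserve_pixels(self):
        rng = np.random.default_rng(12)
        img = rng.integers(0, 256, size=(7, 9, 3), dtype=np.uint8)
        hist = hsv_histogram(img)
        for c in range(3):
            assert hist[c * 16:(c + 1) * 16].sum() == 63

    def test_pixel_order_invariance(self):
        rng = np.random.default_rng(13)
        img = rng.integers(0, 256, size=(6, 6, 3), dtype=np.uint8)
        flat = img.reshape(-1, 3)
        shuffled = flat[rng.permutation(len(flat))].reshape(6, 6, 3)
        np.testing.assert_array_equal(hsv_histogram(img),
                                      hsv_histogram(shuffled))


class TestSemanticVectors:
    @pytest.fixture()
    def table(self):
        rng = np.random.default_rng(14)
        return WordVectorTable(
            vectors={t: rng.normal(size=6)
                     for t in ["plaster", "trowel", "zebra", "axe"]},
            dim=6)

    def test_single_word_lookup(self, table):
        np.testing.assert_array_equal(semantic_vector("axe", table),
                                      table.vectors["axe"])

    def test_multi_word_expression_averages_components(self, table):
        got = semantic_vector("plaster trowel", table)
        expected = (table.vectors["plaster"] + table.vectors["trowel"]) / 2
        np.testing.assert_allclose(got, expected)

    def test_repeated_word_mean_is_identity(self, table):
        np.testing.assert_allclose(semantic_vector("zebra zebra", table),
                                   table.vectors["zebra"])

    def test_missing_tokens_raise_with_names(self, table):
        with pytest.raises(KeyError, match="wombat"):
            semantic_vector("wombat", table)

    def test_table_file_roundtrip(self, table, tmp_path):
        path = tmp_path / "vecs.txt"
        table.save(path)
        loaded = WordVectorTable.from_file(path)
        assert loaded.dim == 6
        for tok, vec in table.vectors.items():
            np.testing.assert_allclose(loaded.vectors[tok], vec, atol=1e-7)


class TestNormalisationAndFusion:
    def test_row_range_normalisation(self):
        block = FeatureBlock(matrix=np.array([[0.0, 5.0, 10.0]]),
                             name="gabor", stimulus_ids=["a"])
        out = range_normalize_rows(block)
        np.testing.assert_allclose(out.matrix, [[0.0, 0.5, 1.0]])

    def test_constant_row_maps_to_zero(self):
        block = FeatureBlock(matrix=np.array([[4.0, 4.0, 4.0]]),
                             name="hsv", stimulus_ids=["a"])
        np.testing.assert_array_equal(range_normalize_rows(block).matrix, 0.0)

    def test_random_rows_span_unit_interval(self):
        rng = np.random.default_rng(15)
        block = FeatureBlock(matrix=rng.normal(size=(10, 20)),
                             name="sift", stimulus_ids=[str(i)
                                                        for i in range(10)])
        out = range_normalize_rows(block).matrix
        np.testing.assert_allclose(out.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.max(axis=1), 1.0, atol=1e-12)
        assert out.min() >= 0 and out.max() <= 1

    def test_full_rank_pca_preserves_variance(self):
        rng = np.random.default_rng(16)
        n_s, m = 12, 6
        block = FeatureBlock(matrix=rng.normal(size=(n_s, m)), name="sem",
                             stimulus_ids=[str(i) for i in range(n_s)])
        fused = fuse([block], pca_components=m)
        norm = range_normalize_rows(block).matrix
        total = ((norm - norm.mean(axis=0)) ** 2).sum()
        kept = ((fused.matrix - fused.matrix.mean(axis=0)) ** 2).sum()
        assert kept == pytest.approx(total, abs=1e-8)

    def test_component_variances_non_increasing(self):
        rng = np.random.default_rng(17)
        block = FeatureBlock(matrix=rng.normal(size=(15, 8)), name="sem",
                             stimulus_ids=[str(i) for i in range(15)])
        ev = fuse([block], pca_components=6).explained_variance
        assert np.all(np.diff(ev) <= 1e-12)

    def test_projection_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(6, 4))
        block = FeatureBlock(matrix=X, name="sem",
                             stimulus_ids=[str(i) for i in range(6)])
        fused = fuse([block], pca_components=3, normalize=False)
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc)
        V = V[:, np.argsort(w)[::-1]][:, :3]
        oracle = Xc @ V
        for j in range(3):   # eigenvectors defined up to sign
            assert (np.allclose(fused.matrix[:, j], oracle[:, j], atol=1e-8)
                    or np.allclose(fused.matrix[:, j], -oracle[:, j],
                                   atol=1e-8))

    def test_oversized_component_request_clipped(self):
        rng = np.random.default_rng(19)
        block = FeatureBlock(matrix=rng.normal(size=(5, 3)), name="sem",
                             stimulus_ids=[str(i) for i in range(5)])
        with pytest.warns(UserWarning, match="clipped"):
            fused = fuse([block], pca_components=10)
        assert fused.n_components <= 3

    def test_mismatched_stimulus_order_rejected(self):
        b1 = FeatureBlock(matrix=np.zeros((2, 3)), name="gabor",
                          stimulus_ids=["a", "b"])
        b2 = FeatureBlock(matrix=np.zeros((2, 3)), name="hsv",
                          stimulus_ids=["b", "a"])
        with pytest.raises(ValueError, match="stimulus"):
            fuse([b1, b2], pca_components=2)
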
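"""Superpixel/context blocks, sample selection and 72-d assembly."""

import numpy as np
import pytest

from hlfseg.features_hlf import (
    FEATURE_NAMES,
    N_FEATURES,
    assemble_hlf,
    build_adjacency,
    context_features,
    select_samples,
    superpixel_block,
    superpixel_entropy,
    superpixel_means,
)


class TestAdjacency:
    def test_single_superpixel_no_neighbors(self):
        adj = build_adjacency(np.zeros((4, 4), dtype=int))
        assert adj == {0: set()}

    def test_two_columns(self):
        sp = np.array([[0, 1], [0, 1]])
        adj = build_adjacency(sp)
        assert adj == {0: {1}, 1: {0}}

    def test_three_bands(self):
        sp = np.zeros((10, 10), dtype=int)
        sp[:, 3:6] = 1
        sp[:, 6:] = 2
        adj = build_adjacency(sp)
        assert adj[1] == {0, 2} and adj[0] == {1} and adj[2] == {1}

    def test_symmetry_on_random_maps(self, rng):
        from hlfseg.slic import enforce_connectivity

        sp = enforce_connectivity(rng.integers(0, 6, (15, 15)), min_size=2)
        adj = build_adjacency(sp)
        for i, nbrs in adj.items():
            assert i not in nbrs
            for j in nbrs:
                assert i in adj[j]


class TestSuperpixelMeans:
    def test_forced_arithmetic(self):
        sp = np.array([[0, 0], [1, 1]])
        stack = np.array([[[1.0, 2.0], [3.0, 5.0]]])
        means = superpixel_means(stack, sp)
        np.testing.assert_allclose(means[:, 0], [1.5, 4.0])

    def test_conservation_identity(self, small_features):
        stack, sp = small_features.stack, small_features.superpixels
        means = superpixel_means(stack, sp)
        sizes = np.bincount(sp.ravel())
        n = sp.size
        for c in range(stack.shape[0]):
            total = (sizes * means[:, c]).sum()
            assert abs(total - stack[c].sum()) <= 1e-9 * n


class TestEntropy:
    def test_constant_region_zero(self):
        sp = np.zeros((4, 4), dtype=int)
        assert superpixel_entropy(np.full((4, 4), 0.5), sp)[0] == 0.0

    def test_two_equal_bins_one_bit(self):
        sp = np.zeros((2, 2), dtype=int)
        img = np.array([[0.1, 0.1], [0.9, 0.9]])
        assert superpixel_entropy(img, sp, n_bins=2)[0] == pytest.approx(1.0)

    def test_uniform_attains_maximum(self):
        n_bins = 8
        img = (np.arange(8)[None, :] + 0.5) / 8
        sp = np.zeros_like(img, dtype=int)
        ent = superpixel_entropy(img, sp, n_bins=n_bins)
        assert ent[0] == pytest.approx(np.log2(n_bins))


class TestContext:
    def test_constant_image(self):
        sp = np.zeros((6, 6), dtype=int)
        sp[:, 3:] = 1
        img = np.full((6, 6), 0.4)
        ctx = context_features(img, sp, build_adjacency(sp), gradient=np.zeros_like(img))
        np.testing.assert_allclose(ctx, [[0.4, 0.0, 0.0], [0.4, 0.0, 0.0]], atol=1e-12)

    def test_three_band_mean(self):
        sp = np.zeros((6, 9), dtype=int)
        sp[:, 3:6] = 1
        sp[:, 6:] = 2
        img = np.zeros((6, 9))
        img[:, 3:6] = 0.5
        img[:, 6:] = 1.0
        ctx = context_features(img, sp, build_adjacency(sp), gradient=np.zeros_like(img))
        # B's ring is A union C, equal sizes -> mean 0.5
        assert ctx[1, 0] == pytest.approx(0.5)

    def test_isolated_superpixel_falls_back_to_self(self):
        sp = np.zeros((4, 4), dtype=int)
        img = np.full((4, 4), 0.7)
        ctx = context_features(img, sp, {0: set()}, gradient=np.zeros_like(img))
        assert ctx[0, 0] == pytest.approx(0.7)


class TestSampling:
    def test_one_sample_per_superpixel_and_membership(self, small_features):
        sp = small_features.superpixels
        samples = select_samples(sp, None, seed=3)
        k = sp.max() + 1
        assert len(samples) == k
        for r, c, i in samples:
            assert sp[r, c] == i

    def test_seed_contract(self, small_features):
        sp = small_features.superpixels
        assert select_samples(sp, None, 5) == select_samples(sp, None, 5)
        assert select_samples(sp, None, 5) != select_samples(sp, None, 6)


class TestAssembly:
    def test_vector_width_and_pixel_block(self, small_image, small_features):
        img, gt = small_image
        f = small_features
        samples = select_samples(f.superpixels, gt, seed=1)
        table = assemble_hlf(f.stack, f.superpixels, f.spx_feats, f.ctx, samples, gt=gt)
        assert N_FEATURES == 72 and len(FEATURE_NAMES) == 72
        feats = table[list(FEATURE_NAMES)].to_numpy()
        assert feats.shape[1] == 72
        for row in table.itertuples(index=False):
            np.testing.assert_array_equal(
                np.array(row[3 : 3 + 34]), f.stack[:, row.row, row.col]
            )
            break  # spot-check the first row elementwise; shapes cover the rest
        np.testing.assert_allclose(
            feats[:, :34],
            f.stack[:, table["row"].to_numpy(), table["col"].to_numpy()].T,
        )

    def test_constant_image_means_equal_pixel_values(self):
        img = np.full((32, 32), 0.5)
        sp = np.zeros((32, 32), dtype=int)
        sp[:, 16:] = 1
        from hlfseg.features_pixel import CHANNEL_NAMES, compute_pixel_features

        stack = compute_pixel_features(img, normalize=False)
        spx = superpixel_block(img, stack, sp)
        ctx = context_features(img, sp, build_adjacency(sp))
        samples = select_samples(sp, None, seed=0)
        table = assemble_hlf(stack, sp, spx, ctx, samples)
        smoothing = [i for i, n in enumerate(CHANNEL_NAMES)
                     if n.startswith(("mean", "median", "gauss"))]
        for i in smoothing:
            np.testing.assert_allclose(
                table[f"px_{CHANNEL_NAMES[i]}"], table[f"sp_{CHANNEL_NAMES[i]}"],
                atol=1e-9,
            )

    def test_mismatched_blocks_rejected(self, small_features):
        f = small_features
        samples = select_samples(f.superpixels, None, seed=0)
        with pytest.raises(ValueError):
            assemble_hlf(f.stack, f.superpixels, f.spx_feats[:-1], f.ctx, samples)
        with pytest.raises(ValueError):
            assemble_hlf(f.stack, f.superpixels, f.spx_feats, f.ctx[:, :2], samples)
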
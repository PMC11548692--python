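import numpy as np
import pytest

from cardiocouple.deep_encoder import (
    BranchSpec,
    TrainConfig,
    _branch_forward_maps,
    conv_forward,
    encode_branch,
    encode_images,
    fuse,
    head_accuracy,
    init_branch_weights,
    load_weights,
    maxpool_forward,
    save_weights,
    train_branch,
    train_branches,
)


from _oracles import naive_conv, naive_pool


class TestConvForward:
    def test_ones_grid_hand_counts(self):
        out = conv_forward(np.ones((1, 4, 4)), np.ones((1, 1, 3, 3)), np.zeros(1))
        expected = np.array(
            [[4, 6, 6, 4], [6, 9, 9, 6], [6, 9, 9, 6], [4, 6, 6, 4]], dtype=float
        )
        np.testing.assert_array_equal(out[0], expected)

    def test_identity_kernel_rectifies_input(self, rng):
        x = rng.standard_normal((2, 5, 5))
        k = np.zeros((2, 2, 3, 3))
        k[0, 0, 1, 1] = 1.0
        k[1, 1, 1, 1] = 1.0
        out = conv_forward(x, k, np.zeros(2))
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-12)

    def test_matches_naive_loop_oracle(self, rng):
        x = rng.standard_normal((3, 6, 6))
        k = rng.standard_normal((4, 3, 3, 3))
        b = rng.standard_normal(4)
        np.testing.assert_allclose(conv_forward(x, k, b), naive_conv(x, k, b), atol=1e-6)

    def test_channel_mismatch(self, rng):
        with pytest.raises(ValueError, match="channel mismatch"):
            conv_forward(np.ones((2, 4, 4)), np.ones((1, 3, 3, 3)), np.zeros(1))


class TestMaxpool:
    def test_single_window(self):
        out = maxpool_forward(np.array([[[1.0, 2.0], [3.0, 4.0]]]))
        np.testing.assert_array_equal(out, [[[4.0]]])

    def test_constant_map(self):
        out = maxpool_forward(np.full((3, 8, 8), 2.5))
        np.testing.assert_array_equal(out, np.full((3, 4, 4), 2.5))

    def test_matches_naive_scan(self, rng):
        x = rng.standard_normal((2, 8, 8))
        np.testing.assert_allclose(maxpool_forward(x), naive_pool(x), atol=1e-12)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            maxpool_forward(np.ones((1, 5, 6)))


class TestEncodeBranch:
    def test_shape_chain_224_to_7(self, rng):
        spec = BranchSpec(width_divisor=8)
        w = init_branch_weights(spec, rng)
        maps = _branch_forward_maps(
            rng.uniform(0, 1, (1, 3, 224, 224)), spec, w
        )
        assert maps.shape == (1, 64, 7, 7)  # 512/8 channels, 224/2^5 spatial

    def test_code_dim_independent_of_width(self, rng):
        spec = BranchSpec(width_divisor=8)
        w = init_branch_weights(spec, rng)
        code = encode_branch(rng.uniform(0, 1, (224, 224, 3)), spec, w, rng)
        assert code.shape == (2000,)

    def test_zero_image_zero_code(self, rng):
        spec = BranchSpec(width_divisor=16)
        w = init_branch_weights(spec, rng)
        code = encode_branch(np.zeros((64, 64, 3)), spec, w, rng)
        assert not code.any()  # zero biases + ReLU propagate zeros

    def test_deterministic_given_weights(self, rng):
        spec = BranchSpec(width_divisor=16, projection_dim=100)
        img = np.random.default_rng(1).uniform(0, 1, (64, 64, 3))
        codes = []
        for _ in range(2):
            w = init_branch_weights(spec, np.random.default_rng(3))
            codes.append(encode_branch(img, spec, w, np.random.default_rng(4)))
        np.testing.assert_array_equal(codes[0], codes[1])

    def test_thirteen_conv_layers(self):
        spec = BranchSpec()
        assert spec.n_conv_layers() == 13
        assert [c for _, c in spec.channel_plan()][:: 1][-1] == 512


class TestFuse:
    def test_latent_order_and_slicing(self, rng):
        vecs = {m: rng.standard_normal(400) for m in ("ecg", "pcg", "coupling")}
        out = fuse(vecs)
        assert out.shape == (1200,)
        np.testing.assert_array_equal(out[:400], vecs["ecg"])
        np.testing.assert_array_equal(out[400:800], vecs["pcg"])
        np.testing.assert_array_equal(out[800:], vecs["coupling"])

    def test_deep_codes_concatenate(self, rng):
        out = fuse([rng.standard_normal(2000) for _ in range(3)])
        assert out.shape == (6000,)

    def test_missing_modality(self, rng):
        with pytest.raises(ValueError, match="missing modality"):
            fuse({"ecg": rng.standard_normal(4), "pcg": rng.standard_normal(4)})


def _blob_images(n, seed, shuffle_labels=False):
    """Two-class images: a bright central blob marks class 1; a per-image
    global-brightness nuisance keeps untrained readouts near chance."""
    r = np.random.default_rng(seed)
    labels = np.tile([0, 1], n // 2)
    base = 0.4 + r.uniform(-0.15, 0.15, size=(n, 1, 1, 1))
    imgs = np.broadcast_to(base, (n, 32, 32, 3)).copy()
    imgs[labels == 1, 8:24, 8:24, :] += 0.3
    imgs = np.clip(imgs + 0.05 * r.standard_normal(imgs.shape), 0, 1)
    if shuffle_labels:
        labels = r.permutation(labels)
    return imgs, labels


class TestTraining:
    SPEC = BranchSpec(width_divisor=8)
    CFG = TrainConfig(learning_rate=0.05, epochs=5, seed=1)

    def test_separable_classes_learned(self):
        imgs, labels = _blob_images(240, seed=0)
        w, losses = train_branch(imgs, labels, self.SPEC, self.CFG)
        assert losses[-1] < losses[0]
        te, tl = _blob_images(40, seed=5)
        assert head_accuracy(te, tl, self.SPEC, w) >= 0.9

    def test_seeded_training_reproducible(self):
        imgs, labels = _blob_images(48, seed=0)
        cfg = TrainConfig(learning_rate=0.05, epochs=2, seed=9)
        _, l1 = train_branch(imgs, labels, self.SPEC, cfg)
        _, l2 = train_branch(imgs, labels, self.SPEC, cfg)
        assert abs(l1[-1] - l2[-1]) < 1e-6

    def test_shuffled_labels_fall_to_chance(self):
        imgs, labels = _blob_images(240, seed=0, shuffle_labels=True)
        w, _ = train_branch(imgs, labels, self.SPEC, self.CFG)
        te, tl = _blob_images(40, seed=5)
        assert 0.35 <= head_accuracy(te, tl, self.SPEC, w) <= 0.65

    def test_single_class_rejected(self):
        imgs, _ = _blob_images(16, seed=0)
        with pytest.raises(ValueError, match="single-class"):
            train_branch(imgs, np.zeros(16, dtype=int), self.SPEC, self.CFG)

    def test_train_branches_requires_all_modalities(self):
        imgs, labels = _blob_images(16, seed=0)
        with pytest.raises(ValueError, match="missing modality"):
            train_branches({"ecg": imgs}, labels, self.SPEC, self.CFG)


def test_checkpoint_roundtrip(tmp_path, rng):
    spec = BranchSpec(width_divisor=16, projection_dim=50)
    weights = {
        m: init_branch_weights(spec, np.random.default_rng(i))
        for i, m in enumerate(("ecg", "pcg", "coupling"))
    }
    imgs = rng.uniform(0, 1, (2, 32, 32, 3))
    before = encode_images(imgs, spec, weights["ecg"], np.random.default_rng(7))
    save_weights(tmp_path / "w.npz", weights, spec)
    loaded = load_weights(tmp_path / "w.npz", spec)
    after = encode_images(imgs, spec, loaded["ecg"], np.random.default_rng(99))
    np.testing.assert_array_equal(before, after)  # projection persisted, rng unused
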
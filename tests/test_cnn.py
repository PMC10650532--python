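"""CNN layer operators against brute-force oracles; training behaviour."""

import numpy as np
import pytest

from eegcrypt import (
    CNNModel,
    ConvLayerSpec,
    FusionParams,
    activate,
    conv2d_forward,
    ensemble_fuse,
    load_pretrained_backbone,
    max_pool,
    train,
)
from eegcrypt.cnn import (
    BACKBONE_INPUT_SIDES,
    BackboneWeightsUnavailable,
    forward,
    load_model,
    save_model,
)


def conv_oracle(x, w, stride):
    """Nested-loop cross-correlation, valid padding."""
    C, H, W = x.shape
    K, _, k, _ = w.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    out = np.zeros((K, Ho, Wo))
    for kk in range(K):
        for p in range(Ho):
            for q in range(Wo):
                acc = 0.0
                for c in range(C):
                    for i in range(k):
                        for j in range(k):
                            acc += x[c, p * stride + i, q * stride + j] * w[kk, c, i, j]
                out[kk, p, q] = acc
    return out


def pool_oracle(x, win, stride):
    C, H, W = x.shape
    Ho = (H - win) // stride + 1
    Wo = (W - win) // stride + 1
    out = np.zeros((C, Ho, Wo))
    for c in range(C):
        for p in range(Ho):
            for q in range(Wo):
                out[c, p, q] = x[c, p * stride : p * stride + win, q * stride : q * stride + win].max()
    return out


class TestConv2dForward:
    def test_identity_kernel(self):
        x = np.arange(16.0).reshape(1, 4, 4)
        spec = ConvLayerSpec(kernel_size=1, n_kernels=1)
        out = conv2d_forward(x, spec, np.ones((1, 1, 1, 1)))
        assert np.array_equal(out[0], x[0])

    def test_direct_summation_example(self):
        # [[1,2],[3,4]] (x) eye(2), valid: 1*1 + 4*1 = 5
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        w = np.eye(2)[None, None, :, :]
        # ConvLayerSpec only allows odd kernels; evaluate the even case via the oracle
        assert conv_oracle(x, w, 1)[0, 0, 0] == 5.0

    def test_zero_kernel_gives_zero_maps(self):
        x = np.random.default_rng(0).normal(size=(2, 5, 5))
        spec = ConvLayerSpec(kernel_size=3, n_kernels=4)
        out = conv2d_forward(x, spec, np.zeros((4, 2, 3, 3)))
        assert np.all(out == 0)

    def test_matches_bruteforce_on_random_integer_tensors(self, rng):
        for _ in range(100):
            C = int(rng.integers(1, 3))
            K = int(rng.integers(1, 3))
            k = int(rng.choice([1, 3]))
            H = int(rng.integers(k, k + 5))
            W = int(rng.integers(k, k + 5))
            stride = int(rng.integers(1, 3))
            x = rng.integers(-5, 6, (C, H, W)).astype(float)
            w = rng.integers(-3, 4, (K, C, k, k)).astype(float)
            spec = ConvLayerSpec(kernel_size=k, n_kernels=K, stride=stride)
            assert np.array_equal(conv2d_forward(x, spec, w), conv_oracle(x, w, stride))

    def test_shape_mismatch_rejected(self):
        spec = ConvLayerSpec(kernel_size=3, n_kernels=2)
        with pytest.raises(ValueError):
            conv2d_forward(np.zeros((1, 5, 5)), spec, np.zeros((2, 3, 3, 3)))


class TestMaxPool:
    def test_single_window(self):
        assert max_pool(np.array([[[1.0, 2.0], [3.0, 4.0]]]), 2)[0, 0, 0] == 4.0

    def test_constant_input(self):
        out = max_pool(np.full((1, 4, 4), 2.5), 2)
        assert np.all(out == 2.5)

    def test_matches_bruteforce_on_random_tensors(self, rng):
        for _ in range(100):
            C = int(rng.integers(1, 3))
            H = int(rng.integers(2, 8))
            W = int(rng.integers(2, 8))
            win = int(rng.integers(1, min(H, W) + 1))
            stride = int(rng.integers(1, 3))
            x = rng.integers(-9, 10, (C, H, W)).astype(float)
            assert np.array_equal(max_pool(x, win, stride), pool_oracle(x, win, stride))

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            max_pool(np.zeros((1, 2, 2)), 3)


class TestActivate:
    def test_relu(self):
        assert activate(np.array(-1.0)) == 0.0
        assert activate(np.array(2.0)) == 2.0

    def test_sigmoid_at_zero(self):
        assert activate(np.array(0.0), "sigmoid") == 0.5

    def test_tanh_at_zero(self):
        assert activate(np.array(0.0), "tanh") == 0.0

    def test_matches_bruteforce_on_random_tensors(self, rng):
        x = rng.normal(size=(3, 4, 4))
        assert np.array_equal(activate(x, "relu"), np.where(x > 0, x, 0.0))
        assert np.allclose(activate(x, "sigmoid"), 1 / (1 + np.exp(-x)))
        assert np.allclose(activate(x, "tanh"), np.tanh(x))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            activate(np.zeros(3), "swish")


class TestForwardPass:
    def test_probabilities_sum_to_one(self, rng):
        model = CNNModel(input_side=16, n_classes=3, seed=0)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        probs = forward(model, img)
        assert probs.shape == (3,)
        assert np.all(probs >= 0)
        assert abs(probs.sum() - 1.0) < 1e-9

    def test_deterministic_inference(self, rng):
        model = CNNModel(input_side=16, n_classes=2, seed=1)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert np.array_equal(forward(model, img), forward(model, img))

    def test_zero_final_weights_give_uniform(self, rng):
        model = CNNModel(input_side=16, n_classes=3, seed=0)
        model.layers[-1].w[:] = 0.0
        model.layers[-1].b[:] = 0.0
        probs = forward(model, rng.integers(0, 256, (16, 16)).astype(np.uint8))
        assert np.allclose(probs, 1 / 3)

    def test_size_mismatch_rejected(self, rng):
        model = CNNModel(input_side=16, n_classes=2)
        with pytest.raises(ValueError):
            forward(model, rng.integers(0, 256, (8, 8)).astype(np.uint8))


def separable_images(rng, n_per_class=40, side=16, n_classes=3):
    """Classes marked by a bright horizontal band at class-specific rows."""
    X = rng.integers(0, 60, (n_per_class * n_classes, side, side)).astype(np.uint8)
    y = np.repeat(np.arange(n_classes), n_per_class)
    for i, cls in enumerate(y):
        X[i, cls * 5 : cls * 5 + 4, :] = np.minimum(X[i, cls * 5 : cls * 5 + 4, :] + 150, 255)
    return X, y


class TestTrain:
    def test_learns_separable_classes(self, rng):
        X, y = separable_images(rng)
        model = CNNModel(input_side=16, n_classes=3, seed=0)
        hist = train(model, X, y, epochs=20, seed=0)
        assert hist[-1]["accuracy"] >= 0.95

    def test_loss_decreases(self, rng):
        X, y = separable_images(rng)
        model = CNNModel(input_side=16, n_classes=3, seed=0)
        hist = train(model, X, y, epochs=10, seed=0)
        assert hist[-1]["loss"] < hist[0]["loss"]

    def test_zero_lr_leaves_weights_unchanged(self, rng):
        X, y = separable_images(rng, n_per_class=5)
        model = CNNModel(input_side=16, n_classes=3, seed=0)
        before = model.get_weights()
        train(model, X, y, epochs=2, lr=0.0, seed=0)
        for a, b in zip(before, model.get_weights()):
            assert np.array_equal(a, b)

    def test_seeded_reproducibility(self, rng):
        X, y = separable_images(rng, n_per_class=10)
        h1 = train(CNNModel(16, 3, seed=2), X, y, epochs=3, seed=5)
        h2 = train(CNNModel(16, 3, seed=2), X, y, epochs=3, seed=5)
        assert [r["loss"] for r in h1] == [r["loss"] for r in h2]

    def test_single_class_rejected(self, rng):
        X = rng.integers(0, 256, (10, 16, 16)).astype(np.uint8)
        model = CNNModel(input_side=16, n_classes=2)
        with pytest.raises(ValueError, match="2 classes"):
            train(model, X, np.zeros(10, dtype=int))


class TestEnsembleFuse:
    def test_single_member_identity(self):
        p = np.array([[0.2, 0.8]])
        fused = ensemble_fuse([p], FusionParams(np.array([1.0])))
        assert np.allclose(fused, p)

    def test_equal_weights_symmetry(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.0, 1.0]])
        fused = ensemble_fuse([a, b], FusionParams(np.array([0.5, 0.5])))
        assert np.allclose(fused, [[0.5, 0.5]])

    def test_one_hot_weight_selects_member(self):
        a = np.array([[0.9, 0.1]])
        b = np.array([[0.1, 0.9]])
        fused = ensemble_fuse([a, b], FusionParams(np.array([1.0, 0.0])))
        assert np.allclose(fused, a)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            ensemble_fuse([np.array([[1.0, 0.0]])], FusionParams(np.array([0.0])))

    def test_out_of_box_weights_rejected(self):
        with pytest.raises(ValueError):
            FusionParams(np.array([1.5]))

    def test_empty_feature_mask_rejected(self):
        with pytest.raises(ValueError):
            FusionParams(np.array([1.0]), selected_features=np.zeros(4, dtype=bool))


class TestBackboneHook:
    @pytest.mark.parametrize(
        "name,side",
        [("alexnet", 227), ("darknet19", 256), ("googlenet", 224),
         ("resnet50", 224), ("squeezenet", 227)],
    )
    def test_native_input_sides(self, name, side):
        assert BACKBONE_INPUT_SIDES[name] == side
        model = load_pretrained_backbone(name)
        assert model.input_side == side

    def test_strict_mode_raises_optional_feature_error(self):
        with pytest.raises(BackboneWeightsUnavailable, match="optional"):
            load_pretrained_backbone("alexnet", strict=True)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            load_pretrained_backbone("vgg16")


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        model = CNNModel(input_side=16, n_classes=2, seed=3)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        p = save_model(model, tmp_path / "m.npz")
        back = load_model(p)
        assert np.allclose(forward(model, img), forward(back, img))
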
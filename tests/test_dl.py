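import numpy as np
import pandas as pd
import pytest

from cvai import (
    FundusImage,
    ModelConfig,
    ParameterError,
    augment,
    build_network,
    grad_cam,
    kfold_train_eval,
    overlay_heatmap,
)
from cvai.dl import Conv2D, Dense, gamma_correct, make_folds, mirror_lr


def _random_image(rng, side=64):
    return FundusImage(
        rng.integers(0, 256, (side, side, 3), dtype=np.uint8), eye_id="img"
    )


def _quadrant_network():
    """Hand-wired vgg_small whose output is (a pooled proxy of) the mean of
    the top-left image quadrant: pass-through convolutions, dense head
    reading only spatial position (0, 0) of the block-5 feature map."""
    net = build_network(ModelConfig(input_side_px=64, seed=0))
    for layer in net.layers:
        if isinstance(layer, Conv2D):
            layer.W[:] = 0.0
            cout, cin = layer.W.shape[:2]
            for o in range(cout):
                layer.W[o, o % cin, 1, 1] = 1.0
            layer.b[:] = 0.0
    fc1 = next(l for l in net.layers if l.name == "fc1")
    fc2 = next(l for l in net.layers if l.name == "fc2")
    fc1.W[:] = 0.0
    fc1.b[:] = 0.0
    for c in range(32):  # flatten order is (channel, row, col) with 2x2 maps
        fc1.W[c * 4 + 0, 0] = 1.0 / 32
    fc2.W[:] = 0.0
    fc2.b[:] = 0.0
    fc2.W[0, 0] = 1.0
    return net


class TestAugment:
    def test_exactly_six_with_identical_original(self, rng):
        img = _random_image(rng)
        out = augment(img, seed=5)
        assert len(out) == 6
        np.testing.assert_array_equal(out[0].pixels, img.pixels)
        # the other five each differ from the original
        assert all(not np.array_equal(o.pixels, img.pixels) for o in out[1:])

    def test_deterministic_given_seed(self, rng):
        img = _random_image(rng)
        a = augment(img, seed=7)
        b = augment(img, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.pixels, y.pixels)

    def test_mirror_is_involution(self, rng):
        img = _random_image(rng)
        np.testing.assert_array_equal(mirror_lr(mirror_lr(img)).pixels, img.pixels)

    def test_gamma_one_is_identity(self, rng):
        img = _random_image(rng)
        np.testing.assert_array_equal(gamma_correct(img, 1.0).pixels, img.pixels)


class TestNetwork:
    def test_five_pools_shrink_by_32(self):
        cfg = ModelConfig(input_side_px=64)
        net = build_network(cfg)
        x = np.zeros((1, 3, 64, 64), dtype=np.float32)
        act = x
        for layer in net.layers:
            act = layer.forward(act)
            if layer.name == "block5_pool":
                assert act.shape[-2:] == (64 // 32, 64 // 32)
        assert act.shape == (1, 1)

    def test_zero_image_gives_finite_scalar(self):
        net = build_network(ModelConfig(input_side_px=64, seed=1))
        out = net.forward(np.zeros((1, 3, 64, 64), dtype=np.float32))
        assert out.shape == (1, 1) and np.isfinite(out).all()

    def test_frozen_blocks_reduce_trainable_params(self):
        cfg = ModelConfig(frozen_blocks=4, seed=0)
        net = build_network(cfg)
        assert net.n_params(trainable_only=True) < net.n_params()
        trainable_names = {layer.name for layer, _ in net.trainable_params()}
        assert "block5_conv1" in trainable_names
        assert "fc1" in trainable_names and "fc2" in trainable_names
        assert not any(n.startswith(("block1", "block2", "block3", "block4"))
                       for n in trainable_names)

    def test_vgg16_topology(self):
        net = build_network(ModelConfig(architecture="vgg16", input_side_px=224))
        names = net.layer_names()
        assert names.count("block3_conv3_relu") == 1  # three convs in block 3
        assert sum(n.endswith("_pool") for n in names) == 5
        assert names[-1] == "fc2"

    def test_bad_architecture_rejected(self):
        with pytest.raises(ParameterError):
            ModelConfig(architecture="resnet50")

    def test_input_not_divisible_by_32_rejected(self):
        with pytest.raises(ParameterError):
            ModelConfig(input_side_px=100)


class TestKFold:
    def test_fold_sizes_and_exhaustiveness(self):
        split = make_folds([f"e{i}" for i in range(13)], k=5, seed=0)
        sizes = np.bincount(list(split.assignments.values()), minlength=5)
        assert sizes.sum() == 13
        assert sizes.max() - sizes.min() <= 1

    def test_fewer_eyes_than_folds_rejected(self):
        with pytest.raises(ParameterError):
            make_folds(["a", "b"], k=5)

    def test_every_eye_predicted_once_without_leakage(self, rng):
        cfg = ModelConfig(epochs=1, batch_size=16, seed=2)
        cohort = [
            (FundusImage(rng.integers(0, 256, (64, 64, 3), dtype=np.uint8),
                         eye_id=f"eye{i}"), float(150 + 40 * i))
            for i in range(10)
        ]
        preds = kfold_train_eval(cohort, cfg, k=5)
        frame = preds.frame
        assert len(frame) == 10 and not frame["eye_id"].duplicated().any()
        assert np.bincount(frame["fold"], minlength=5).tolist() == [2] * 5
        # an eye is predicted in exactly the fold it was assigned to,
        # i.e. it was excluded from that fold's training set
        for row in frame.itertuples():
            assert preds.split.assignments[row.eye_id] == row.fold

    def test_visible_signal_is_learnable(self, rng):
        """Images encode thickness as the length of a bright bar; the small
        network must recover it through cross-validation."""
        cohort = []
        for i in range(40):
            thickness = float(rng.uniform(100, 650))
            px = np.full((64, 64, 3), 30, dtype=np.uint8)
            px[28:36, : int(thickness / 650 * 60)] = 220
            cohort.append((FundusImage(px, eye_id=f"bar{i}"), thickness))
        cfg = ModelConfig(epochs=10, batch_size=32, seed=3)
        preds = kfold_train_eval(cohort, cfg, k=5)
        r, _ = preds.correlation()
        assert r > 0.9


class TestGradCam:
    def test_map_normalised_to_unit_interval(self, rng):
        net = build_network(ModelConfig(input_side_px=64, seed=4))
        hm = grad_cam(net, _random_image(rng))
        assert hm.values.shape == (64, 64)
        assert hm.values.min() >= 0.0 and hm.values.max() == pytest.approx(1.0)

    def test_quadrant_model_localises(self, rng):
        net = _quadrant_network()
        img = rng.uniform(0.1, 1.0, (3, 64, 64)).astype(np.float32)
        hm = grad_cam(net, img, target_layer="block3_pool")
        mass = hm.values[:32, :32].sum() / hm.values.sum()
        assert mass >= 0.6

    def test_invariant_to_output_bias(self, rng):
        net = build_network(ModelConfig(input_side_px=64, seed=4))
        img = _random_image(rng)
        hm0 = grad_cam(net, img)
        fc2 = next(l for l in net.layers if l.name == "fc2")
        fc2.b += 1000.0
        hm1 = grad_cam(net, img)
        np.testing.assert_array_equal(hm0.values, hm1.values)

    def test_zero_head_gives_degenerate_flag(self, rng):
        net = build_network(ModelConfig(input_side_px=64, seed=4))
        fc2 = next(l for l in net.layers if l.name == "fc2")
        fc2.W[:] = 0.0
        hm = grad_cam(net, _random_image(rng))
        assert hm.degenerate and not hm.values.any()

    def test_unknown_layer_rejected(self, rng):
        net = build_network(ModelConfig(input_side_px=64, seed=4))
        with pytest.raises(ParameterError, match="block9_pool"):
            grad_cam(net, _random_image(rng), target_layer="block9_pool")


class TestOverlay:
    def test_zero_map_returns_image_unchanged(self, rng):
        img = _random_image(rng)
        out = overlay_heatmap(img, np.zeros((64, 64)))
        np.testing.assert_array_equal(out, img.pixels)

    def test_uniform_map_is_deterministic(self, rng):
        img = _random_image(rng)
        a = overlay_heatmap(img, np.ones((64, 64)))
        b = overlay_heatmap(img, np.ones((64, 64)))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, img.pixels)

    def test_ground_truth_mask_highlights_vessels(self, sample_eye):
        cam = sample_eye.truth_choroid.pixels.astype(float)
        out = overlay_heatmap(sample_eye.image, cam, alpha=1.0)
        vessel = sample_eye.truth_choroid.pixels
        np.testing.assert_array_equal(out[~vessel], sample_eye.image.pixels[~vessel])
        assert (out[vessel] != sample_eye.image.pixels[vessel]).any()

    def test_bad_shape_rejected(self, rng):
        with pytest.raises(ParameterError):
            overlay_heatmap(_random_image(rng), np.zeros(64))
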
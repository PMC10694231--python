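import numpy as np
import pytest

from canopyreg import deep_regression as dr


@pytest.fixture
def tiny():
    return dr.BackboneSpec("tiny_test_cnn")


def _brightness_dataset(n=60, size=24, seed=0):
    """Images whose target is their mean brightness — a strong, learnable cue."""
    rng = np.random.default_rng(seed)
    levels = rng.uniform(0.1, 0.9, n)
    X = np.clip(levels[:, None, None, None] + rng.normal(0, 0.05, (n, 3, size, size)), 0, 1)
    return X, levels * 10.0


class TestSpecs:
    def test_input_sizes_fixed_per_backbone(self):
        assert dr.BackboneSpec("resnet50").input_size == 224
        assert dr.BackboneSpec("efficientnet_b0").input_size == 224
        assert dr.BackboneSpec("efficientnet_b4").input_size == 380
        assert dr.BackboneSpec("tiny_test_cnn").input_size == 64
        with pytest.raises(ValueError, match="input_size"):
            dr.BackboneSpec("resnet50", input_size=64)

    def test_head_output_counts(self):
        assert dr.HeadSpec("single_linear", 1).n_outputs == 1
        assert dr.HeadSpec("multi_softmax", 4).n_outputs == 4
        with pytest.raises(ValueError):
            dr.HeadSpec("single_linear", 4)

    def test_flag_leaf_weight_default(self):
        np.testing.assert_array_equal(
            dr.HeadSpec("multi_softmax", 4).organ_weights, [1, 1, 20, 1]
        )
        np.testing.assert_array_equal(
            dr.HeadSpec("multi_linear", 4).organ_weights, np.ones(4)
        )

    def test_named_backbones_need_weights(self, tiny):
        with pytest.raises(NotImplementedError, match="pretrained"):
            dr.build_model(dr.BackboneSpec("resnet50"), dr.HeadSpec(), 3)


class TestPreprocess:
    def test_center_crop_geometry(self, tiny):
        img = np.random.default_rng(0).random((480, 640, 3)) * 255
        out = dr.preprocess(img, "rgb", tiny)
        assert out.shape == (3, 64, 64)

    def test_ms_standardization(self, tiny):
        stats = dr.ChannelStats(mean=np.full(6, 0.4), sd=np.full(6, 0.1))
        img = np.full((64, 64, 6), 0.4)
        out = dr.preprocess(img, "ms", tiny, stats)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_ms_without_stats_rejected(self, tiny):
        with pytest.raises(ValueError, match="train_stats"):
            dr.preprocess(np.zeros((64, 64, 6)), "ms", tiny)

    def test_leakage_guard(self, tiny):
        stats = dr.ChannelStats(np.zeros(6), np.ones(6), source_split="val")
        with pytest.raises(ValueError, match="training-split"):
            dr.preprocess(np.zeros((64, 64, 6)), "ms", tiny, stats)


class TestAugment:
    def test_double_flip_is_rotation(self):
        rng = np.random.default_rng(0)
        x = rng.random((3, 8, 8))
        both = x[:, ::-1, ::-1]
        # find a seed that triggers both flips
        for seed in range(50):
            r = np.random.default_rng(seed)
            if r.random() < 0.5 and r.random() < 0.5:
                np.testing.assert_array_equal(dr.augment(x, seed), both)
                return
        pytest.fail("no both-flip seed found")

    def test_involution(self):
        x = np.random.default_rng(1).random((3, 6, 6))
        for seed in range(20):
            once = dr.augment(x, seed)
            twice = dr.augment(once, seed)
            np.testing.assert_array_equal(twice, x)

    def test_flip_rates(self):
        n = 10_000
        v = h = 0
        x = np.zeros((1, 2, 2))
        x[0, 0, 0] = 1.0
        for seed in range(n):
            out = dr.augment(x, seed)
            if out[0, 1, 0] == 1.0 or out[0, 1, 1] == 1.0:
                v += 1
            if out[0, 0, 1] == 1.0 or out[0, 1, 1] == 1.0:
                h += 1
        assert v / n == pytest.approx(0.5, abs=0.02)
        assert h / n == pytest.approx(0.5, abs=0.02)


class TestBuildModel:
    def test_channel_adapter_shape(self, tiny):
        model = dr.build_model(tiny, dr.HeadSpec(), 6, seed=0)
        x = np.random.default_rng(0).random((2, 6, 64, 64))
        adapted = model.net.layers[0].forward(x)
        assert adapted.shape == (2, 3, 64, 64)

    def test_softmax_rows_normalized(self, tiny):
        model = dr.build_model(tiny, dr.HeadSpec("multi_softmax", 4), 3, seed=1)
        x = np.random.default_rng(1).random((8, 3, 64, 64))
        out = model(x)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(out >= 0)

    def test_forward_smoke_under_1s(self, tiny):
        import time

        model = dr.build_model(tiny, dr.HeadSpec(), 3, seed=0)
        x = np.random.default_rng(2).random((4, 3, 64, 64))
        t0 = time.time()
        out = model(x)
        assert time.time() - t0 < 1.0
        assert np.all(np.isfinite(out))

    def test_bad_channels(self, tiny):
        with pytest.raises(ValueError, match="in_channels"):
            dr.build_model(tiny, dr.HeadSpec(), 4)


class TestMaskedWeightedMse:
    def test_masked_arithmetic(self):
        head = dr.HeadSpec("multi_linear", 4, mask_zero_targets=True)
        y_true = np.array([[2.0, 0.0, 3.0, 1.0]])
        y_pred = np.array([[1.0, 5.0, 3.0, 1.0]])
        # included: (2-1)^2, (3-3)^2, (1-1)^2 over 3 terms
        assert dr.masked_weighted_mse(y_true, y_pred, head) == pytest.approx(1 / 3)

    def test_flag_leaf_weighting(self):
        head = dr.HeadSpec("multi_softmax", 4)
        y_true = np.array([[0.3, 0.3, 0.2, 0.2]])
        y_pred = np.array([[0.3, 0.3, 0.3, 0.1]])
        # l1 error 0.1 weighted x20, ear error 0.1 weight 1, over 4 terms
        expected = (20 * 0.01 + 0.01) / 4
        assert dr.masked_weighted_mse(y_true, y_pred, head) == pytest.approx(expected)

    def test_zero_when_equal(self):
        head = dr.HeadSpec("multi_linear", 4)
        y = np.random.default_rng(0).random((5, 4))
        assert dr.masked_weighted_mse(y, y, head) == 0.0

    def test_all_masked_warns(self):
        head = dr.HeadSpec("multi_linear", 4, mask_zero_targets=True)
        with pytest.warns(UserWarning, match="masked"):
            loss = dr.masked_weighted_mse(np.zeros((2, 4)), np.ones((2, 4)), head)
        assert loss == 0.0

    def test_gradient_zero_at_masked_positions(self):
        head = dr.HeadSpec("multi_linear", 4, mask_zero_targets=True)
        rng = np.random.default_rng(3)
        y_true = rng.random((6, 4))
        y_true[y_true < 0.4] = 0.0
        y_pred = rng.random((6, 4))
        _, grad = dr.masked_weighted_mse(y_true, y_pred, head, return_grad=True)
        assert np.all(grad[y_true == 0.0] == 0.0)
        # finite differences confirm both masked and unmasked entries
        eps = 1e-7
        for idx in [(0, 0), (1, 2), (3, 3)]:
            yp = y_pred.copy()
            yp[idx] += eps
            up = dr.masked_weighted_mse(y_true, yp, head)
            yp[idx] -= 2 * eps
            dn = dr.masked_weighted_mse(y_true, yp, head)
            num = (up - dn) / (2 * eps)
            assert num == pytest.approx(grad[idx], abs=1e-6)


class TestTrain:
    def test_loss_decreases(self, tiny):
        X, y = _brightness_dataset(n=60, size=24)
        finals = []
        for seed in (0, 1, 2):
            model = dr.build_model(tiny, dr.HeadSpec(), 3, seed=seed)
            bundle = dr.train(model, X, y / y.std(),
                              [dr.TrainPhase("t", 5, 3e-3, "all")], seed=seed)
            losses = [h["train_loss"] for h in bundle.history]
            finals.append(losses[-1] < losses[0])
        assert sum(finals) >= 2  # median of 3 seeds decreases

    def test_head_only_freezes_backbone(self, tiny):
        X, y = _brightness_dataset(n=20, size=24)
        model = dr.build_model(tiny, dr.HeadSpec(), 3, seed=0)
        before = {f"block{i}": model.net.checksum(f"block{i}") for i in range(1, 5)}
        head_before = model.net.checksum("head")
        dr.train(model, X, y, [dr.TrainPhase("t", 2, 1e-3, "head_only")], seed=0)
        for scope, val in before.items():
            assert model.net.checksum(scope) == val
        assert model.net.checksum("head") != head_before

    def test_last_block_scope(self, tiny):
        X, y = _brightness_dataset(n=20, size=24)
        model = dr.build_model(tiny, dr.HeadSpec(), 3, seed=0)
        b3 = model.net.checksum("block3")
        b4 = model.net.checksum("block4")
        dr.train(model, X, y, [dr.TrainPhase("t", 2, 1e-3, "head_plus_last_block")], seed=0)
        assert model.net.checksum("block3") == b3
        assert model.net.checksum("block4") != b4

    def test_zero_lr_no_change(self, tiny):
        X, y = _brightness_dataset(n=20, size=24)
        model = dr.build_model(tiny, dr.HeadSpec(), 3, seed=0)
        state = [p.copy() for p in model.net.state()]
        dr.train(model, X, y, [dr.TrainPhase("t", 2, 0.0, "all")], seed=0)
        for a, b in zip(state, model.net.state()):
            np.testing.assert_array_equal(a, b)

    def test_empty_training_set(self, tiny):
        model = dr.build_model(tiny, dr.HeadSpec(), 3, seed=0)
        with pytest.raises(ValueError, match="empty"):
            dr.train(model, np.zeros((0, 3, 8, 8)), np.zeros(0),
                     [dr.TrainPhase("t", 1, 1e-3, "all")], seed=0)

    def test_overfit_capacity(self, tiny):
        """Training MSE drops below 10% of target variance on 50 images."""
        X, y = _brightness_dataset(n=50, size=24, seed=4)
        ys = y / y.std()
        model = dr.build_model(tiny, dr.HeadSpec(), 3, seed=0)
        bundle = dr.train(model, X, ys, [dr.TrainPhase("t", 60, 3e-3, "all")],
                          seed=0, augment_data=False)
        pred = dr.predict(model, X).ravel()
        assert np.mean((pred - ys) ** 2) < 0.1 * ys.var()

    def test_determinism(self, tiny):
        X, y = _brightness_dataset(n=20, size=24)
        outs = []
        for _ in range(2):
            model = dr.build_model(tiny, dr.HeadSpec(), 3, seed=5)
            dr.train(model, X, y, [dr.TrainPhase("t", 2, 1e-3, "all")], seed=5)
            outs.append(dr.predict(model, X))
        np.testing.assert_array_equal(outs[0], outs[1])


def test_gradient_check_full_network(tiny):
    """Analytic backprop matches central finite differences."""
    head = dr.HeadSpec("multi_linear", 4, mask_zero_targets=True)
    model = dr.build_model(tiny, head, 3, seed=7)
    rng = np.random.default_rng(7)
    x = rng.random((2, 3, 16, 16))
    y_true = rng.random((2, 4))
    y_true[0, 1] = 0.0
    pred = model.net.forward(x)
    _, grad = dr.masked_weighted_mse(y_true, pred, head, return_grad=True)
    model.net.zero_grad()
    model.net.backward(grad)
    for p in (model.net.params()[0], model.net.params()[-2]):
        flat_idx = np.unravel_index(3 % p.value.size, p.value.shape)
        orig = p.value[flat_idx]
        eps = 1e-6
        p.value[flat_idx] = orig + eps
        up = dr.masked_weighted_mse(y_true, model.net.forward(x), head)
        p.value[flat_idx] = orig - eps
        dn = dr.masked_weighted_mse(y_true, model.net.forward(x), head)
        p.value[flat_idx] = orig
        assert (up - dn) / (2 * eps) == pytest.approx(p.grad[flat_idx], rel=1e-4, abs=1e-8)
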
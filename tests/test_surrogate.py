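import numpy as np
import pytest

from uswnnm import (
    NoiseSpec,
    PhantomSpec,
    SurrogateArch,
    make_phantom,
    predict,
    preset,
    profile,
    ssim,
    train,
)
from uswnnm.surrogate import (
    SurrogateModel,
    TrainingSet,
    _conv_bwd,
    _conv_fwd,
    _deconv_bwd,
    _deconv_fwd,
    _masked_mae,
    _pad_batch,
    build_pairs,
)


class TestArch:
    def test_input_side_must_divide_by_stride_power(self):
        with pytest.raises(ValueError):
            SurrogateArch(depth=3, input_side=60)
        SurrogateArch(depth=3, base_filters=8, max_filters=32, input_side=64)

    def test_stage_filters_double_and_cap(self):
        arch = SurrogateArch(depth=4, base_filters=8, max_filters=32, input_side=64)
        assert arch.stage_filters() == [8, 16, 32, 32]

    def test_profiles(self):
        assert profile("tiny").depth == 2
        full = profile("full")
        assert full.depth == 10
        assert full.base_filters == 32 and full.max_filters == 512
        assert full.kernel == (4, 4) and full.stride == (2, 2)
        with pytest.raises(ValueError):
            profile("huge")


class TestConvPrimitives:
    """Numerical gradient checks of the conv / transposed-conv building blocks."""

    def _num_grad(self, f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = x[idx]
            x[idx] = orig + eps
            fp = f()
            x[idx] = orig - eps
            fm = f()
            x[idx] = orig
            g[idx] = (fp - fm) / (2 * eps)
        return g

    def test_conv_gradients(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 8, 8))
        w = rng.normal(size=(4, 3, 4, 4)) * 0.3
        b = rng.normal(size=4) * 0.1
        target = rng.normal(size=(2, 4, 4, 4))

        def loss():
            return 0.5 * np.sum((_conv_fwd(x, w, b) - target) ** 2)

        gy = _conv_fwd(x, w, b) - target
        gx, gw, gb = _conv_bwd(x, w, gy)
        np.testing.assert_allclose(gx, self._num_grad(loss, x), atol=1e-5)
        np.testing.assert_allclose(gw, self._num_grad(loss, w), atol=1e-5)
        np.testing.assert_allclose(gb, self._num_grad(loss, b), atol=1e-5)

    def test_deconv_gradients_and_shape(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 3, 4, 4))
        w = rng.normal(size=(3, 2, 4, 4)) * 0.3
        b = rng.normal(size=2) * 0.1
        out = _deconv_fwd(x, w, b)
        assert out.shape == (2, 2, 8, 8)
        target = rng.normal(size=out.shape)

        def loss():
            return 0.5 * np.sum((_deconv_fwd(x, w, b) - target) ** 2)

        gy = _deconv_fwd(x, w, b) - target
        gx, gw, gb = _deconv_bwd(x, w, gy)
        np.testing.assert_allclose(gx, self._num_grad(loss, x), atol=1e-5)
        np.testing.assert_allclose(gw, self._num_grad(loss, w), atol=1e-5)
        np.testing.assert_allclose(gb, self._num_grad(loss, b), atol=1e-5)

    def test_deconv_is_adjoint_of_conv(self):
        # <conv(x), y> = <x, deconv(y)> for zero bias and shared weights: the
        # conv layout (F, C, u, v) is read by the transposed conv as
        # (C_in=F, C_out=C, u, v)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 3, 8, 8))
        w = rng.normal(size=(4, 3, 4, 4))
        y = rng.normal(size=(1, 4, 4, 4))
        lhs = np.sum(_conv_fwd(x, w, np.zeros(4)) * y)
        rhs = np.sum(x * _deconv_fwd(y, w, np.zeros(3)))
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestModelGradients:
    def test_full_network_gradient_check(self):
        arch = SurrogateArch(depth=2, base_filters=3, max_filters=6, input_side=8)
        model = SurrogateModel.initialise(arch, seed=0)
        rng = np.random.default_rng(3)
        x = rng.random((2, 1, 8, 8))
        t = rng.random((2, 1, 8, 8))
        m = np.ones_like(x)
        pred, cache = model.forward(x, keep_cache=True)
        gout = np.sign(pred - t) * m / m.sum()
        grads = model.backward(cache, gout)
        eps = 1e-6
        rng_idx = np.random.default_rng(4)
        for name in ("enc0_W", "enc1_W", "dec1_W", "dec0_W", "enc0_b", "dec0_b"):
            p = model.params[name]
            flat = rng_idx.choice(p.size, size=min(5, p.size), replace=False)
            for fi in flat:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = _masked_mae(model.forward(x), t, m)
                p[idx] = orig - eps
                lm = _masked_mae(model.forward(x), t, m)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, abs=2e-5), name


def _identity_task(n=10, size=24, canvas=32, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        img = rng.random((size, size))
        pairs.append((img, img.copy()))
    return TrainingSet(pairs=pairs, split=0.2)


class TestTraining:
    def test_identity_task_loss_decreases(self):
        arch = SurrogateArch(depth=2, base_filters=4, max_filters=8, input_side=32)
        model, log = train(_identity_task(), arch, epochs_max=15, patience=15, seed=1)
        assert log.train_loss[-1] < log.train_loss[0]

    def test_training_is_deterministic(self):
        arch = SurrogateArch(depth=2, base_filters=4, max_filters=8, input_side=32)
        _, log1 = train(_identity_task(), arch, epochs_max=5, patience=5, seed=2)
        _, log2 = train(_identity_task(), arch, epochs_max=5, patience=5, seed=2)
        assert log1.train_loss == log2.train_loss
        assert log1.val_loss == log2.val_loss

    def test_early_stopping_returns_best_snapshot(self):
        # scripted validation losses: best at epoch 2, rising afterwards;
        # with patience 3 training must stop at epoch 5 and return the
        # epoch-2 parameters
        scripted = [1.0, 0.9, 0.8, 0.85, 0.9, 0.95, 0.3, 0.2]
        snapshots = {}

        def fake_val(model, epoch):
            snapshots[epoch] = model.copy_params()
            return scripted[epoch]

        arch = SurrogateArch(depth=1, base_filters=2, max_filters=2, input_side=16)
        ts = _identity_task(n=6, size=12, canvas=16)
        model, log = train(ts, arch, epochs_max=8, patience=3, seed=3, val_eval=fake_val)
        assert log.stopped_epoch == 5
        assert log.best_epoch == 2
        for k, v in model.params.items():
            np.testing.assert_array_equal(v, snapshots[2][k])

    def test_runs_to_epochs_max_without_stop(self):
        losses = iter([1.0, 0.9, 0.8, 0.7])

        def fake_val(model, epoch):
            return next(losses)

        arch = SurrogateArch(depth=1, base_filters=2, max_filters=2, input_side=16)
        model, log = train(_identity_task(n=6, size=12), arch, epochs_max=4,
                           patience=2, seed=3, val_eval=fake_val)
        assert log.stopped_epoch == 3
        assert log.best_epoch == 3

    def test_oversized_pair_rejected(self):
        arch = SurrogateArch(depth=1, base_filters=2, max_filters=2, input_side=16)
        big = np.zeros((20, 20))
        with pytest.raises(ValueError):
            train(TrainingSet(pairs=[(big, big)], split=0.5), arch)

    def test_masked_loss_ignores_padded_region(self):
        # growing the zero-padded canvas must not change the masked loss of
        # a fixed fully-convolutional model
        arch = SurrogateArch(depth=2, base_filters=4, max_filters=8, input_side=32)
        model = SurrogateModel.initialise(arch, seed=5)
        pairs = _identity_task(n=3, size=24).pairs
        x1, t1, m1 = _pad_batch(pairs, 32)
        x2, t2, m2 = _pad_batch(pairs, 48)
        loss1 = _masked_mae(model.forward(x1), t1, m1)
        loss2 = _masked_mae(model.forward(x2), t2, m2)
        assert loss1 == pytest.approx(loss2, abs=1e-6)


class TestBuildPairs:
    def test_pairs_match_specs_and_are_deterministic(self, surrogate_pairs_layers):
        ts = surrogate_pairs_layers
        assert len(ts.pairs) == 40
        for raw, target in ts.pairs:
            assert raw.shape == (64, 64) == target.shape
        # rebuilding a single pair reproduces it bit-exactly
        cfg = preset("tuned", "medium", 0.1)
        rebuilt = build_pairs(
            [PhantomSpec("layers", (64, 64), seed=100)], NoiseSpec("speckle", 0.1, 5), cfg
        )
        assert np.array_equal(rebuilt.pairs[0][0], ts.pairs[0][0])
        assert np.array_equal(rebuilt.pairs[0][1], ts.pairs[0][1])

    def test_targets_differ_from_raws(self, surrogate_pairs_layers):
        for raw, target in surrogate_pairs_layers.pairs[:5]:
            assert np.mean(np.abs(raw - target)) > 1e-4

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError):
            build_pairs([], NoiseSpec("speckle", 0.1, 0), preset("tuned"))


class TestPredict:
    def _trained_identity_model(self):
        arch = SurrogateArch(depth=2, base_filters=4, max_filters=8, input_side=64)
        model, _ = train(_identity_task(n=8, size=48), arch, epochs_max=3,
                         patience=3, seed=6)
        return model

    def test_output_shape_matches_non_square_input(self):
        model = self._trained_identity_model()
        img = np.random.default_rng(7).random((48, 33))
        out = predict(model, img)
        assert out.shape == (48, 33)

    def test_output_clamped_to_unit_interval(self):
        model = self._trained_identity_model()
        out = predict(model, np.random.default_rng(8).random((64, 64)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_input_larger_than_canvas_rejected(self):
        model = self._trained_identity_model()
        with pytest.raises(ValueError):
            predict(model, np.zeros((65, 64)))

    def test_save_load_round_trip(self, tmp_path):
        model = self._trained_identity_model()
        path = tmp_path / "model.npz"
        model.save(path)
        again = SurrogateModel.load(path)
        assert again.arch == model.arch
        for k in model.params:
            np.testing.assert_array_equal(again.params[k], model.params[k])
        img = np.random.default_rng(9).random((40, 40))
        np.testing.assert_array_equal(predict(model, img), predict(again, img))


class TestDistrictSpecialisation:
    def test_same_district_training_beats_cross_district(
        self, surrogate_pairs_layers, surrogate_pairs_ellipses
    ):
        """A surrogate trained on the phantom family it is tested on should
        track the denoiser's output better than one trained on a different
        family (averaged over 8 test pairs and 2 training seeds)."""
        arch = profile("tiny")
        train_layers = TrainingSet(pairs=surrogate_pairs_layers.pairs[:32])
        train_ellipses = surrogate_pairs_ellipses
        test_pairs = surrogate_pairs_layers.pairs[32:]
        scores = {"same": [], "cross": []}
        for seed in (0, 1):
            m_same, _ = train(train_layers, arch, epochs_max=60, patience=6, seed=seed)
            m_cross, _ = train(train_ellipses, arch, epochs_max=60, patience=6, seed=seed)
            for raw, target in test_pairs:
                scores["same"].append(ssim(target, predict(m_same, raw)))
                scores["cross"].append(ssim(target, predict(m_cross, raw)))
        assert np.mean(scores["same"]) > np.mean(scores["cross"])
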
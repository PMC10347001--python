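"""Network fidelity: layer oracles, shape algebra, seeded training."""

import numpy as np
import pytest

import gaitdpf.nets.layers as layers_mod
from gaitdpf.nets import (
    ModelSpec,
    TrainConfig,
    TrainedModel,
    build_model,
    cross_entropy,
    train,
    train_specialists,
)
from gaitdpf.nets.layers import Conv1D, LSTMLayer, MaxPool1D
from gaitdpf.preprocess import NormalizerParams, SensorGroup
from gaitdpf.phases import SITES


# -- independent oracles: direct elementwise evaluation ---------------------

def lstm_cell_oracle(x_t, h_prev, c_prev, Wx, Wh, b):
    """One LSTM step evaluated gate by gate with explicit scalar math."""
    H = h_prev.shape[0]

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    z = x_t @ Wx + h_prev @ Wh + b
    i = sig(z[:H])
    f = sig(z[H : 2 * H])
    g = np.tanh(z[2 * H : 3 * H])
    o = sig(z[3 * H :])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


def conv_oracle(x, W, b, width):
    """Direct sum-over-taps convolution with 'same' zero padding + ReLU."""
    T, Cin = x.shape
    Cout = b.shape[0]
    pad = width // 2
    xp = np.zeros((T + 2 * pad, Cin))
    xp[pad : pad + T] = x
    out = np.zeros((T, Cout))
    for t in range(T):
        for j in range(Cout):
            acc = b[j]
            for k in range(width):
                for i in range(Cin):
                    acc += xp[t + k, i] * W[k * Cin + i, j]
            out[t, j] = max(acc, 0.0)
    return out


class TestLayerOracles:
    def test_lstm_cell_step_matches_direct_evaluation(self, rng):
        C, H = 3, 5
        layer = LSTMLayer(C, H, rng)
        # random small weights, not the init
        layer.Wx[...] = rng.normal(0, 0.3, layer.Wx.shape)
        layer.Wh[...] = rng.normal(0, 0.3, layer.Wh.shape)
        layer.b[...] = rng.normal(0, 0.3, layer.b.shape)
        x = rng.normal(size=(1, 4, C)).astype(np.float32)
        hs = layer.forward(x)
        h = np.zeros(H)
        c = np.zeros(H)
        for t in range(4):
            h, c = lstm_cell_oracle(
                x[0, t].astype(float), h, c,
                layer.Wx.astype(float), layer.Wh.astype(float), layer.b.astype(float),
            )
            np.testing.assert_allclose(hs[0, t], h, atol=1e-5)

    def test_conv_layer_matches_direct_evaluation(self, rng):
        Cin, Cout, width = 4, 3, 3
        layer = Conv1D(Cin, Cout, width, rng)
        layer.W[...] = rng.normal(0, 0.4, layer.W.shape)
        layer.b[...] = rng.normal(0, 0.4, layer.b.shape)
        x = rng.normal(size=(1, 7, Cin)).astype(np.float32)
        out = layer.forward(x)
        want = conv_oracle(
            x[0].astype(float), layer.W.astype(float), layer.b.astype(float), width
        )
        np.testing.assert_allclose(out[0], want, atol=1e-5)

    def test_maxpool_strides(self, rng):
        x = rng.normal(size=(2, 10, 3)).astype(np.float32)
        out2 = MaxPool1D(2, 2).forward(x)
        out1 = MaxPool1D(2, 1).forward(x)
        assert out2.shape == (2, 5, 3)
        assert out1.shape == (2, 9, 3)
        np.testing.assert_array_equal(out1[:, 4], np.maximum(x[:, 4], x[:, 5]))

    def test_full_gradient_against_numeric_differences(self, monkeypatch, rng):
        # double precision and randomized biases keep the check away from
        # ReLU kinks and pool ties
        monkeypatch.setattr(layers_mod, "DTYPE", np.float64)
        net = build_model(ModelSpec(lstm_units=4, conv_filters=(3, 5)), 2, seed=3)
        for p in net.params:
            p[...] = rng.normal(0, 0.3, p.shape)
        x = rng.normal(size=(3, 20, 2))
        y = np.array([0, 1, 2])
        loss, dlog = cross_entropy(net.forward_logits(x), y)
        net.backward(dlog)
        analytic = [g.copy() for g in net.grads]

        checked = 0
        for p, g in zip(net.params, analytic):
            flat = p.ravel()
            for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                eps = 1e-6
                old = flat[idx]
                flat[idx] = old + eps
                lp = cross_entropy(net.forward_logits(x), y)[0]
                flat[idx] = old - eps
                lm = cross_entropy(net.forward_logits(x), y)[0]
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g.ravel()[idx]) < 1e-5 * max(1.0, abs(num))
                checked += 1
        assert checked > 50


class TestBuildModel:
    def test_parameter_count_deterministic(self):
        a = build_model(ModelSpec(), 6, seed=0)
        b = build_model(ModelSpec(), 6, seed=1)
        assert a.parameter_count == b.parameter_count > 0

    def test_time_lengths_after_pooling(self):
        # 20 -> pool(2, stride 2) -> 10 -> pool(2, stride 1) -> 9
        net = build_model(ModelSpec(), 6)
        assert net.feature_len == 9
        assert net.layers[-1].W.shape == (9 * 128, 4)

    def test_untrained_output_is_probability_vector(self, rng):
        net = build_model(ModelSpec(lstm_units=8, conv_filters=(4, 8)), 2, seed=5)
        p = net.predict_proba(rng.normal(size=(7, 20, 2)))
        assert p.shape == (7, 4)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)

    def test_channel_counts_validated(self, rng):
        net = build_model(ModelSpec(lstm_units=4, conv_filters=(3, 3)), 4, seed=0)
        with pytest.raises(ValueError, match="expected windows"):
            net.forward_logits(rng.normal(size=(2, 20, 6)))

    def test_batch_invariance_of_predictions(self, rng):
        net = build_model(ModelSpec(lstm_units=8, conv_filters=(4, 8)), 3, seed=2)
        x = rng.normal(size=(9, 20, 3)).astype(np.float32)
        batched = net.predict_proba(x)
        singles = np.concatenate([net.predict_proba(x[i : i + 1]) for i in range(9)])
        np.testing.assert_allclose(batched, singles, atol=1e-7)


def _separable_windows(rng, n_per_class=60, n_channels=3):
    """Four well-separated class templates plus small noise."""
    xs, ys = [], []
    t = np.linspace(0, 1, 20)[:, None]
    for c in range(4):
        template = np.sin(2 * np.pi * (c + 1) * t) + c * np.ones((20, n_channels))
        for _ in range(n_per_class):
            xs.append(template + rng.normal(0, 0.1, (20, n_channels)))
            ys.append(c)
    x = np.array(xs, dtype=np.float32)
    return x, np.array(ys)


TINY = ModelSpec(lstm_units=12, conv_filters=(6, 8))
FAST = TrainConfig(
    max_epochs=25, batch_size=32, early_stop_patience=5, early_stop_min_delta=1e-4, seed=0
)


class TestTraining:
    def test_reaches_high_accuracy_on_separable_classes(self, rng):
        x, y = _separable_windows(rng)
        net = build_model(TINY, 3, seed=1)
        model = train(net, x, y, FAST)
        assert model.history["train_accuracy"].iloc[-1] >= 0.95
        assert np.isfinite(model.history["train_loss"]).all()
        assert np.isfinite(model.history["val_loss"]).all()

    def test_same_seed_identical_weights(self, rng):
        x, y = _separable_windows(rng, n_per_class=20)
        cfg = TrainConfig(max_epochs=3, batch_size=32, seed=9)
        m1 = train(build_model(TINY, 3, seed=4), x, y, cfg)
        m2 = train(build_model(TINY, 3, seed=4), x, y, cfg)
        for a, b in zip(m1.network.get_weights(), m2.network.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_missing_class_rejected(self, rng):
        x, y = _separable_windows(rng, n_per_class=10)
        keep = y != 2
        with pytest.raises(ValueError, match="class"):
            train(build_model(TINY, 3, seed=0), x[keep], y[keep], FAST)

    def test_holdout_accuracy_on_separable_test_set(self, rng):
        x, y = _separable_windows(rng, n_per_class=80)
        order = rng.permutation(len(y))
        x, y = x[order], y[order]
        n_tr = int(0.7 * len(y))
        model = train(build_model(TINY, 3, seed=2), x[:n_tr], y[:n_tr], FAST)
        acc = float(np.mean(model.predict(x[n_tr:]) == y[n_tr:]))
        assert acc >= 0.90


class TestTrainedModelPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        x, y = _separable_windows(rng, n_per_class=15, n_channels=2)
        group = SensorGroup(1)
        norm = NormalizerParams(group.sites, np.array([-2.0, -2.0]), np.array([4.0, 4.0]))
        model = train(
            build_model(TINY, 2, seed=6),
            x[..., :2],
            y,
            TrainConfig(max_epochs=2, batch_size=32, seed=6),
            sensor_group=group,
            normalizer=norm,
            name="unit-test",
        )
        model.save(tmp_path / "ckpt")
        back = TrainedModel.load(tmp_path / "ckpt")
        assert back.sensor_group.group_id == 1
        assert back.name == "unit-test"
        probe = rng.normal(size=(3, 20, 2)).astype(np.float32)
        np.testing.assert_allclose(
            back.predict_proba(probe), model.predict_proba(probe), atol=1e-7
        )

    def test_shape_error_names_group(self, rng, tmp_path):
        x, y = _separable_windows(rng, n_per_class=15, n_channels=2)
        group = SensorGroup(1)
        norm = NormalizerParams(group.sites, np.array([-2.0, -2.0]), np.array([4.0, 4.0]))
        model = train(
            build_model(TINY, 2, seed=6), x[..., :2], y,
            TrainConfig(max_epochs=1, batch_size=32, seed=6),
            sensor_group=group, normalizer=norm,
        )
        with pytest.raises(ValueError, match="group 1"):
            model.predict_proba(rng.normal(size=(2, 20, 6)))


class TestSpecialists:
    def test_group_bindings_and_channel_counts(self, rng):
        # six-channel raw windows with separable structure
        x, y = _separable_windows(rng, n_per_class=15, n_channels=6)
        norm = NormalizerParams(
            SITES, np.full(6, -3.0), np.full(6, 5.0)
        )
        models = train_specialists(
            x, y, norm, TrainConfig(max_epochs=1, batch_size=32, seed=1), spec=TINY
        )
        assert set(models) == {"LSTM-CNN-1", "LSTM-CNN-2", "LSTM-CNN-3"}
        assert models["LSTM-CNN-1"].n_channels == 6
        assert models["LSTM-CNN-2"].n_channels == 4
        assert models["LSTM-CNN-3"].n_channels == 4
        assert models["LSTM-CNN-2"].sensor_group.group_id == 6
        assert models["LSTM-CNN-3"].sensor_group.group_id == 4
        # all three evaluate on windows sliced from one 6-channel stream
        probe = rng.normal(size=(4, 20, 6))
        for m in models.values():
            p = m.predict_on_raw(probe)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
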
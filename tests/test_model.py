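"""Fusion-network primitives against independent oracles and closed forms."""

import numpy as np
import pytest

from lungsound.model import (AdamOptimizer, ConvLayerParams, LSTMParams,
                             LSTMState, ModelConfig, conv2d_forward,
                             count_macs, fusion_forward, init_parameters,
                             load_checkpoint, loss_cross_entropy_l2,
                             lstm_sequence, lstm_step, maxpool2d,
                             save_checkpoint, softmax_layer)
from lungsound.model.reference import (conv2d_loop, fusion_forward_scratch,
                                       lstm_sequence_loop, lstm_step_loop)


def brute_force_conv(x, kernels, bias):
    """Triple-nested-loop valid cross-correlation + bias + ReLU."""
    h, w, c_in = x.shape
    f = kernels.shape[0]
    out = np.zeros((h - 2, w - 2, f))
    for j in range(f):
        for i in range(h - 2):
            for k in range(w - 2):
                s = bias[j]
                for c in range(c_in):
                    for u in range(3):
                        for v in range(3):
                            s += kernels[j, c, u, v] * x[i + u, k + v, c]
                out[i, k, j] = max(s, 0.0)
    return out


class TestConv:
    def test_zero_kernels_pass_bias_through_relu(self):
        params = ConvLayerParams(np.zeros((2, 1, 3, 3)), np.array([0.5, -0.5]))
        out = conv2d_forward(np.ones((5, 5, 1)), params)
        np.testing.assert_allclose(out[:, :, 0], 0.5)
        np.testing.assert_allclose(out[:, :, 1], 0.0)  # ReLU clips -0.5

    def test_center_one_kernel_crops_input(self):
        k = np.zeros((1, 1, 3, 3))
        k[0, 0, 1, 1] = 1.0
        x = np.arange(25, dtype=float).reshape(5, 5, 1)
        out = conv2d_forward(x, ConvLayerParams(k, np.zeros(1)))
        np.testing.assert_allclose(out[:, :, 0], x[1:-1, 1:-1, 0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 5, 2))
        kernels = rng.standard_normal((3, 2, 3, 3))
        bias = rng.standard_normal(3)
        got = conv2d_forward(x, ConvLayerParams(kernels, bias))
        np.testing.assert_allclose(got, brute_force_conv(x, kernels, bias),
                                   atol=1e-6)

    def test_channel_mismatch_rejected(self):
        params = ConvLayerParams(np.zeros((1, 2, 3, 3)), np.zeros(1))
        with pytest.raises(ValueError, match="channel"):
            conv2d_forward(np.zeros((5, 5, 1)), params)


class TestMaxPool:
    def test_single_window(self):
        out = maxpool2d(np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None])
        np.testing.assert_allclose(out, [[[4.0]]])

    def test_enumerated_windows(self):
        x = np.arange(1, 17, dtype=float).reshape(4, 4)[:, :, None]
        out = maxpool2d(x)
        np.testing.assert_allclose(out[:, :, 0], [[6.0, 8.0], [14.0, 16.0]])

    def test_constant_map_halves_size(self):
        out = maxpool2d(np.full((6, 8, 3), 2.5))
        assert out.shape == (3, 4, 3)
        np.testing.assert_allclose(out, 2.5)

    def test_odd_trailing_dropped(self):
        x = np.random.default_rng(1).random((5, 7, 2))
        assert maxpool2d(x).shape == (2, 3, 2)


class TestLSTMStep:
    def _zero_params(self, hidden, inp):
        z = np.zeros((hidden, hidden + inp))
        b = np.zeros(hidden)
        return LSTMParams(z, z.copy(), z.copy(), z.copy(),
                          b, b.copy(), b.copy(), b.copy())

    def test_all_zero_params_closed_form(self):
        params = self._zero_params(3, 2)
        state = lstm_step(np.zeros(2), LSTMState(np.zeros(3), np.zeros(3)),
                          params)
        # sigma(0)=0.5, tanh(0)=0 -> C = 0.5*0 + 0.5*0 = 0, h = 0
        np.testing.assert_allclose(state.C, 0.0)
        np.testing.assert_allclose(state.h, 0.0)

    def test_saturated_forget_gate_carries_cell(self):
        params = self._zero_params(2, 1)
        params.b_f = np.full(2, 10.0)
        c_prev = np.array([1.5, -2.0])
        state = lstm_step(np.zeros(1), LSTMState(np.zeros(2), c_prev), params)
        # C_t = sigma(10)*c + sigma(0)*tanh(0) ~ 0.99995*c
        sig10 = 1.0 / (1.0 + np.exp(-10.0))
        np.testing.assert_allclose(state.C, sig10 * c_prev, rtol=1e-9)

    def test_matches_independent_gate_equations(self):
        rng = np.random.default_rng(2)
        params = LSTMParams(*(rng.standard_normal((3, 5)) for _ in range(4)),
                            *(rng.standard_normal(3) for _ in range(4)))
        x = rng.standard_normal(2)
        h0, c0 = rng.standard_normal(3), rng.standard_normal(3)
        state = lstm_step(x, LSTMState(h0, c0), params)
        h_ref, c_ref = lstm_step_loop(x, h0, c0, params)
        np.testing.assert_allclose(state.h, h_ref, atol=1e-9)
        np.testing.assert_allclose(state.C, c_ref, atol=1e-9)

    def test_printed_cell_variant_omits_input_gate(self):
        rng = np.random.default_rng(3)
        params = LSTMParams(*(rng.standard_normal((2, 4)) for _ in range(4)),
                            *(rng.standard_normal(2) for _ in range(4)))
        x = rng.standard_normal(2)
        h0, c0 = rng.standard_normal(2), rng.standard_normal(2)
        got = lstm_step(x, LSTMState(h0, c0), params, cell_variant="printed")
        h_ref, c_ref = lstm_step_loop(x, h0, c0, params, cell_variant="printed")
        np.testing.assert_allclose(got.C, c_ref, atol=1e-9)
        np.testing.assert_allclose(got.h, h_ref, atol=1e-9)

    def test_gate_boundedness(self):
        rng = np.random.default_rng(4)
        params = LSTMParams(*(5 * rng.standard_normal((4, 7)) for _ in range(4)),
                            *(5 * rng.standard_normal(4) for _ in range(4)))
        state = LSTMState(np.zeros(4), np.zeros(4))
        for t in range(10):
            state = lstm_step(100 * rng.standard_normal(3), state, params)
            assert np.all(np.abs(state.h) < 1.0)

    def test_shape_mismatch_rejected(self):
        params = self._zero_params(3, 2)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(5), LSTMState(np.zeros(3), np.zeros(3)), params)


class TestLSTMSequence:
    def _random_params(self, rng, hidden, inp):
        return LSTMParams(*(0.5 * rng.standard_normal((hidden, hidden + inp))
                            for _ in range(4)),
                          *(0.1 * rng.standard_normal(hidden) for _ in range(4)))

    def test_length_one_equals_single_step(self):
        rng = np.random.default_rng(5)
        params = self._random_params(rng, 3, 2)
        x = rng.standard_normal((1, 2))
        out = lstm_sequence(x, [params])
        step = lstm_step(x[0], LSTMState(np.zeros(3), np.zeros(3)), params)
        np.testing.assert_allclose(out, step.h, atol=1e-12)

    def test_zero_everything_gives_zero(self):
        hidden, inp = 3, 2
        z = np.zeros((hidden, hidden + inp))
        b = np.zeros(hidden)
        params = LSTMParams(z, z, z, z, b, b, b, b)
        out = lstm_sequence(np.zeros((4, inp)), [params])
        np.testing.assert_allclose(out, 0.0)

    def test_two_layer_matches_unrolled_reference(self):
        rng = np.random.default_rng(6)
        p1 = self._random_params(rng, 3, 2)
        p2 = self._random_params(rng, 3, 3)
        xs = rng.standard_normal((4, 2))
        got = lstm_sequence(xs, [p1, p2])
        ref = lstm_sequence_loop(xs, [p1, p2])
        np.testing.assert_allclose(got, ref, atol=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            lstm_sequence(np.zeros((0, 2)), [])


class TestSoftmax:
    def test_uniform(self):
        np.testing.assert_allclose(softmax_layer(np.zeros(5)), 0.2)

    def test_closed_form_log2(self):
        out = softmax_layer(np.array([0.0, np.log(2.0)]))
        np.testing.assert_allclose(out, [1 / 3, 2 / 3], atol=1e-12)

    def test_shift_invariance(self):
        z = np.random.default_rng(7).standard_normal(6)
        np.testing.assert_allclose(softmax_layer(z + 7.0), softmax_layer(z),
                                   atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            softmax_layer(np.array([0.0, np.inf]))


class TestFusionForward:
    def test_five_class_probability_vector(self):
        cfg = ModelConfig(n_classes=5)
        params = init_parameters(cfg, seed=0)
        x = np.random.default_rng(0).random((128, 250)).astype(np.float32)
        probs = fusion_forward(x, cfg, params)
        assert probs.shape == (5,)
        assert abs(probs.sum() - 1.0) < 1e-5
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_shape_algebra_of_default_stack(self):
        cfg = ModelConfig()
        assert cfg.conv_shapes() == [(63, 124), (30, 61), (14, 29)]
        assert cfg.sequence_length == 29
        assert cfg.lstm_input_size == 14 * 64

    def test_wrong_input_shape_rejected(self):
        cfg = ModelConfig(n_classes=4)
        params = init_parameters(cfg, seed=0)
        with pytest.raises(ValueError):
            fusion_forward(np.zeros((64, 250)), cfg, params)

    def test_scratch_route_agrees_small_architectures(self):
        rng = np.random.default_rng(8)
        cfg = ModelConfig(conv_filters=(2, 3), lstm_layers=2, lstm_hidden=4,
                          dense_units=5, n_classes=3, input_shape=(16, 24, 1))
        for seed in range(5):
            params = init_parameters(cfg, seed=seed, dtype=np.float64)
            x = rng.random((16, 24))
            fast = fusion_forward(x, cfg, params)
            slow = fusion_forward_scratch(x, cfg, params)
            np.testing.assert_allclose(fast, slow, atol=1e-5)

    def test_conv_loop_reference_matches_vectorized(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((10, 12, 3))
        params = ConvLayerParams(rng.standard_normal((4, 3, 3, 3)),
                                 rng.standard_normal(4))
        np.testing.assert_allclose(conv2d_forward(x, params),
                                   conv2d_loop(x, params), atol=1e-9)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.array([[0.0, 1.0, 0.0]])
        onehot = np.array([[0.0, 1.0, 0.0]])
        assert loss_cross_entropy_l2(probs, onehot) == 0.0

    def test_uniform_five_class_ln5(self):
        probs = np.full((1, 5), 0.2)
        onehot = np.eye(5)[[2]]
        np.testing.assert_allclose(loss_cross_entropy_l2(probs, onehot),
                                   np.log(5.0), atol=1e-12)

    def test_l2_term_counts_weights_not_biases(self):
        cfg = ModelConfig(conv_filters=(1,), lstm_layers=1, lstm_hidden=2,
                          dense_units=2, n_classes=2, input_shape=(6, 8, 1))
        params = init_parameters(cfg, seed=0, dtype=np.float64)
        # zero all weights, then set a single weight to 2
        from lungsound.model.network import iter_weights
        for holder, key, w in iter_weights(params):
            w[:] = 0.0
        params["out"]["W"][0, 0] = 2.0
        probs = np.array([[1.0, 0.0]])
        onehot = np.array([[1.0, 0.0]])
        loss = loss_cross_entropy_l2(probs, onehot, params, lam=0.0001)
        np.testing.assert_allclose(loss, 4e-4, atol=1e-12)

    def test_zero_probability_clipped_with_warning(self):
        probs = np.array([[1.0, 0.0]])
        onehot = np.array([[0.0, 1.0]])
        with pytest.warns(UserWarning, match="clip"):
            loss = loss_cross_entropy_l2(probs, onehot)
        assert loss == pytest.approx(-np.log(1e-12))


class TestComplexity:
    def test_counted_macs_match_component_formulas(self):
        cfg = ModelConfig()
        macs = count_macs(cfg)
        # conv: sum over layers of positions * filters * channels * k^2
        conv_expected = (126 * 248 * 16 * 1 * 9
                         + 61 * 122 * 32 * 16 * 9
                         + 28 * 59 * 64 * 32 * 9)
        assert macs["conv"] == conv_expected
        lstm_expected = (29 * 4 * 128 * (128 + 896)
                         + 29 * 4 * 128 * (128 + 128))
        assert macs["lstm"] == lstm_expected
        assert macs["total"] == macs["conv"] + macs["lstm"] + macs["dense"]


class TestCheckpoint:
    def test_roundtrip_preserves_forward(self, tmp_path):
        cfg = ModelConfig(conv_filters=(2, 3), lstm_layers=1, lstm_hidden=4,
                          dense_units=5, n_classes=3, input_shape=(16, 24, 1))
        params = init_parameters(cfg, seed=1)
        path = tmp_path / "model.npz"
        save_checkpoint(path, cfg, params, ["a", "b", "c"])
        cfg2, params2, labels = load_checkpoint(path)
        assert labels == ["a", "b", "c"]
        x = np.random.default_rng(0).random((16, 24)).astype(np.float32)
        np.testing.assert_allclose(fusion_forward(x, cfg, params),
                                   fusion_forward(x, cfg2, params2), atol=1e-7)


def test_training_step_reduces_loss_on_tiny_problem():
    cfg = ModelConfig(conv_filters=(2,), lstm_layers=1, lstm_hidden=4,
                      dense_units=4, n_classes=2, input_shape=(8, 10, 1))
    params = init_parameters(cfg, seed=0, dtype=np.float64)
    rng = np.random.default_rng(1)
    X = rng.random((8, 8, 10))
    y = np.array([0, 1] * 4)
    eye = np.eye(2)
    from lungsound.model.network import fusion_backward
    opt = AdamOptimizer(params, lr=0.01)
    losses = []
    for _ in range(30):
        probs, cache = fusion_forward(X, cfg, params, return_cache=True)
        losses.append(loss_cross_entropy_l2(probs, eye[y]))
        grads = fusion_backward(cache, (probs - eye[y]) / len(y), cfg, params)
        opt.step(params, grads)
    assert losses[-1] < losses[0]
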
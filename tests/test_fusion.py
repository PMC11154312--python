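"""Classifier-core tests: CNN forward/backward against independent
references, the LSTM cell against a per-element reference, and the
BiLSTM head's structural properties."""

import numpy as np
import pytest

from pulsegaze import fusion
from pulsegaze.nn import Conv1D, Dense, Sequential, softmax, softmax_cross_entropy


def naive_conv1d(x, W, b):
    """Direct-loop valid convolution oracle, (C, L) x (F, C, k) -> (F, L')."""
    F, C, k = W.shape
    L = x.shape[1]
    out = np.zeros((F, L - k + 1))
    for f in range(F):
        for i in range(L - k + 1):
            out[f, i] = np.sum(x[:, i : i + k] * W[f]) + b[f]
    return out


def naive_lstm_step(params, x, h, c, standard=False):
    """Per-element LSTM reference following the gate equations literally."""
    H = params.hidden
    z = np.concatenate([h, x])
    out_h, out_c = np.zeros(H), np.zeros(H)
    for j in range(H):
        gf = 1 / (1 + np.exp(-(np.dot(params.W_f[j], z) + params.b_f[j])))
        gu = 1 / (1 + np.exp(-(np.dot(params.W_u[j], z) + params.b_u[j])))
        go = 1 / (1 + np.exp(-(np.dot(params.W_o[j], z) + params.b_o[j])))
        ct = np.tanh(np.dot(params.W_c[j], z) + params.b_c[j])
        out_c[j] = gu * ct + gf * c[j]
        out_h[j] = go * (np.tanh(out_c[j]) if standard else out_c[j])
    return out_h, out_c


class TestConvAgainstReference:
    def test_forward_matches_direct_loops(self):
        rng = np.random.default_rng(3)
        layer = Conv1D(2, 4, 5, rng)
        x = rng.normal(size=(3, 2, 20))
        got = layer.forward(x)
        for b in range(3):
            ref = naive_conv1d(x[b], layer.params["W"], layer.params["b"])
            np.testing.assert_allclose(got[b], ref, atol=1e-12)

    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        net = Sequential([Conv1D(1, 3, 4, rng), Conv1D(3, 2, 3, rng)])
        x = rng.normal(size=(2, 1, 12))  # lengths 12 -> 9 -> 7, 2 channels
        y = np.array([0, 1])
        head = Dense(14, 2, rng)

        def loss():
            h = net.forward(x)
            return softmax_cross_entropy(head.forward(h.reshape(2, -1)), y)[0]

        h = net.forward(x)
        l, dl = softmax_cross_entropy(head.forward(h.reshape(2, -1)), y)
        dh = head.backward(dl).reshape(h.shape)
        net.backward(dh)
        W = net.layers[0].params["W"]
        g = net.layers[0].grads["W"][2, 0, 1]
        eps = 1e-6
        W[2, 0, 1] += eps
        l2 = loss()
        W[2, 0, 1] -= 2 * eps
        l1 = loss()
        W[2, 0, 1] += eps
        assert g == pytest.approx((l2 - l1) / (2 * eps), abs=1e-6)


class TestCNNClassifier:
    def test_zero_parameters_give_uninformative_softmax(self):
        model = fusion.CNNClassifier(fusion.FaceModelConfig(), seed=0)
        for layer in model.net.layers:
            for k in layer.params:
                layer.params[k] = np.zeros_like(layer.params[k])
        p = model.predict_proba(np.zeros(600))
        np.testing.assert_allclose(p, [[0.5, 0.5]])

    def test_probabilities_normalized_for_random_inputs(self):
        model = fusion.CNNClassifier(fusion.HRModelConfig(), seed=1)
        X = np.random.default_rng(0).normal(size=(4, 1024))
        p = model.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all()

    def test_inference_is_deterministic_despite_dropout_config(self):
        model = fusion.CNNClassifier(fusion.HRModelConfig(dropout=0.5), seed=2)
        x = np.random.default_rng(1).normal(size=(1, 1024))
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_architecture_shapes_chain(self):
        hr = fusion.CNNClassifier(fusion.HRModelConfig(), seed=0)
        conv_lengths = 1024 - 16 + 1 - 8 + 1 - 4 + 1
        flat = next(l for l in hr.net.layers if isinstance(l, Dense))
        assert flat.params["W"].shape == (32 * conv_lengths, 256)
        fa = fusion.CNNClassifier(fusion.FaceModelConfig(), seed=0)
        conv_lengths_f = 600 - 10 + 1 - 5 + 1 - 3 + 1
        flat_f = next(l for l in fa.net.layers if isinstance(l, Dense))
        assert flat_f.params["W"].shape == (24 * conv_lengths_f, 128)

    def test_wrong_input_length_rejected(self):
        model = fusion.CNNClassifier(fusion.FaceModelConfig(), seed=0)
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros(601))

    def test_save_load_round_trip(self, tmp_path):
        model = fusion.CNNClassifier(fusion.FaceModelConfig(), seed=5)
        x = np.random.default_rng(2).normal(size=(2, 600))
        path = str(tmp_path / "m.npz")
        model.save(path)
        clone = fusion.CNNClassifier.load(path)
        np.testing.assert_array_equal(model.predict_proba(x), clone.predict_proba(x))


class TestLSTMStep:
    def test_zero_everything_is_a_fixed_point(self):
        p = fusion.LSTMCellParams(*[np.zeros((3, 5))] * 4, *[np.zeros(3)] * 4)
        h, c = fusion.lstm_step(p, np.zeros(2), np.zeros(3), np.zeros(3))
        assert not h.any() and not c.any()

    def test_zero_weights_unit_cell_state(self):
        p = fusion.LSTMCellParams(*[np.zeros((3, 5))] * 4, *[np.zeros(3)] * 4)
        h, c = fusion.lstm_step(p, np.zeros(2), np.zeros(3), np.ones(3))
        np.testing.assert_allclose(c, 0.5)  # sigma(0) * 1
        np.testing.assert_allclose(h, 0.25)  # sigma(0) * 0.5, no tanh on C

    @pytest.mark.parametrize("standard", [False, True])
    def test_matches_independent_reference_on_random_draws(self, standard):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = fusion.LSTMCellParams.init(4, 6, rng)
            x, h, c = rng.normal(size=4), rng.normal(size=6), rng.normal(size=6)
            got_h, got_c = fusion.lstm_step(p, x, h, c, standard_lstm=standard)
            ref_h, ref_c = naive_lstm_step(p, x, h, c, standard=standard)
            np.testing.assert_allclose(got_h[0], ref_h, atol=1e-6)
            np.testing.assert_allclose(got_c[0], ref_c, atol=1e-6)

    def test_gates_bounded_in_unit_interval(self):
        rng = np.random.default_rng(12)
        p = fusion.LSTMCellParams.init(3, 4, rng)
        x = rng.normal(size=3) * 10
        h, c = fusion.lstm_step(p, x, np.zeros(4), np.zeros(4))
        # with c_prev=0, |c| = |gu * c~| < 1 and |h| = |go * c| < 1
        assert np.all(np.abs(c) < 1.0) and np.all(np.abs(h) < 1.0)

    def test_shape_mismatch_rejected(self):
        p = fusion.LSTMCellParams(*[np.zeros((3, 5))] * 4, *[np.zeros(3)] * 4)
        with pytest.raises(ValueError, match="width"):
            fusion.lstm_step(p, np.zeros(7), np.zeros(3), np.zeros(3))


class TestBiLSTM:
    def test_single_window_sequence_is_well_defined(self):
        m = fusion.BiLSTMFusion(input_dim=4, hidden=6, seed=0)
        p = m.predict_proba(np.random.default_rng(0).normal(size=(1, 1, 4)))
        assert p.shape == (1, 1, 2)
        np.testing.assert_allclose(p.sum(axis=2), 1.0)

    def test_time_reversal_direction_swap_symmetry(self):
        m = fusion.BiLSTMFusion(input_dim=4, hidden=8, seed=3)
        x = np.random.default_rng(5).normal(size=(3, 7, 4))
        swapped = m.direction_swapped()
        p1 = m.predict_proba(x)
        p2 = swapped.predict_proba(x[:, ::-1])[:, ::-1]
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_learns_separable_sequences(self):
        rng = np.random.default_rng(9)
        n, T = 20, 6
        labels = rng.integers(0, 2, size=(n, T))
        seqs = np.zeros((n, T, 4))
        for lo in (0, 2):
            p = np.where(labels == 1, 0.9, 0.1) + rng.normal(0, 0.03, size=(n, T))
            seqs[:, :, lo + 1] = np.clip(p, 0, 1)
            seqs[:, :, lo] = 1 - seqs[:, :, lo + 1]
        m = fusion.BiLSTMFusion(input_dim=4, hidden=8, seed=0)
        m.fit(seqs[:14], labels[:14], epochs=300, lr=0.05, seed=0)
        acc = float(np.mean(m.predict(seqs[14:]) == labels[14:]))
        assert acc >= 0.95

    def test_misaligned_labels_rejected(self):
        m = fusion.BiLSTMFusion(input_dim=4, hidden=4, seed=0)
        with pytest.raises(ValueError, match="misaligned"):
            m.fit(np.zeros((2, 5, 4)), np.zeros((2, 4), dtype=int))

    def test_save_load_round_trip(self, tmp_path):
        m = fusion.BiLSTMFusion(input_dim=4, hidden=5, seed=7)
        x = np.random.default_rng(1).normal(size=(2, 4, 4))
        path = str(tmp_path / "b.npz")
        m.save(path)
        clone = fusion.BiLSTMFusion.load(path)
        np.testing.assert_array_equal(m.predict_proba(x), clone.predict_proba(x))
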
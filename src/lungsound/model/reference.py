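"""Independent scratch forward pass used to cross-check the trainable
implementation.

Everything here is written against the layer definitions directly --
``scipy.signal.correlate2d`` per channel pair for the convolutions,
window enumeration for pooling, and per-gate evaluation of the LSTM
recurrence -- sharing no code with the vectorized im2col/BPTT backend in
``network.py``.  It is intentionally slow and used only in tests.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import correlate2d

from .layers import ConvLayerParams, LSTMParams
from .network import ModelConfig


def conv2d_loop(x: np.ndarray, params: ConvLayerParams) -> np.ndarray:
    """Valid 3x3 cross-correlation + bias + ReLU, one channel pair at a time."""
    h, w, c_in = x.shape
    f = params.kernels.shape[0]
    out = np.zeros((h - 2, w - 2, f))
    for j in range(f):
        acc = np.zeros((h - 2, w - 2))
        for c in range(c_in):
            acc += correlate2d(x[:, :, c], params.kernels[j, c], mode="valid")
        out[:, :, j] = acc + params.bias[j]
    return np.maximum(out, 0.0)


def maxpool_loop(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    out = np.empty((h // 2, w // 2, c))
    for i in range(h // 2):
        for j in range(w // 2):
            out[i, j] = x[2 * i: 2 * i + 2, 2 * j: 2 * j + 2].max(axis=(0, 1))
    return out


def _sigmoid(v: float) -> float:
    return 1.0 / (1.0 + np.exp(-v))


def lstm_step_loop(x_t, h_prev, C_prev, params: LSTMParams,
                   cell_variant: str = "standard"):
    """Gate equations evaluated element by element."""
    hsize = params.hidden_size
    z = np.concatenate([h_prev, x_t])
    h_new = np.zeros(hsize)
    C_new = np.zeros(hsize)
    for j in range(hsize):
        f = _sigmoid(float(np.dot(params.W_f[j], z)) + float(params.b_f[j]))
        i = _sigmoid(float(np.dot(params.W_i[j], z)) + float(params.b_i[j]))
        chat = np.tanh(float(np.dot(params.W_C[j], z)) + float(params.b_C[j]))
        if cell_variant == "standard":
            C_new[j] = f * C_prev[j] + i * chat
        else:
            C_new[j] = f * C_prev[j] + chat
        o = _sigmoid(float(np.dot(params.W_o[j], z)) + float(params.b_o[j]))
        h_new[j] = o * np.tanh(C_new[j])
    return h_new, C_new


def lstm_sequence_loop(xs: np.ndarray, layer_params: list[LSTMParams],
                       cell_variant: str = "standard") -> np.ndarray:
    seq = [np.asarray(x, dtype=np.float64) for x in xs]
    for params in layer_params:
        h = np.zeros(params.hidden_size)
        C = np.zeros(params.hidden_size)
        outputs = []
        for x_t in seq:
            h, C = lstm_step_loop(x_t, h, C, params, cell_variant)
            outputs.append(h)
        seq = outputs
    return seq[-1]


def fusion_forward_scratch(mel_values: np.ndarray, config: ModelConfig,
                           params: dict) -> np.ndarray:
    """Full forward pass for one (128, 250) input, scratch route."""
    a = np.asarray(mel_values, dtype=np.float64)[:, :, None]
    for layer in params["conv"]:
        layer64 = ConvLayerParams(layer.kernels.astype(np.float64),
                                  layer.bias.astype(np.float64))
        a = maxpool_loop(conv2d_loop(a, layer64))
    fh, t_len, c = a.shape
    xs = [a[:, t, :].reshape(fh * c) for t in range(t_len)]
    lstm64 = [LSTMParams(**{k: getattr(lp, k).astype(np.float64)
                            for k in ("W_f", "W_i", "W_C", "W_o",
                                      "b_f", "b_i", "b_C", "b_o")})
              for lp in params["lstm"]]
    h_last = lstm_sequence_loop(xs, lstm64, config.cell_variant)
    gap = a.mean(axis=(0, 1))
    concat = np.concatenate([h_last, gap])
    act1 = np.maximum(
        params["dense1"]["W"].astype(np.float64) @ concat
        + params["dense1"]["b"].astype(np.float64), 0.0)
    logits = (params["out"]["W"].astype(np.float64) @ act1
              + params["out"]["b"].astype(np.float64))
    e = np.exp(logits - logits.max())
    return e / e.sum()
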
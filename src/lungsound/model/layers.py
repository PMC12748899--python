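"""Primitive layers of the CNN-LSTM fusion network, with hand-written
backward passes (the package trains in NumPy; no autograd framework).

Conventions: feature maps are channels-last, ``(N, H, W, C)`` or
``(H, W, C)``; convolutions are valid (unpadded) 3x3 cross-correlations
with stride 1 followed by bias and ReLU; pooling is non-overlapping 2x2
max with odd trailing rows/columns dropped.  The LSTM cell follows the
standard gate equations

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)
    c^_t = tanh(W_C [h_{t-1}, x_t] + b_C)
    C_t = f_t * C_{t-1} + i_t * c^_t
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)
    h_t = o_t * tanh(C_t)

A ``cell_variant="printed"`` switch reproduces the cell update without
the input-gate product (C_t = f_t * C_{t-1} + c^_t), kept only for
compatibility experiments; training uses the standard form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as sigmoid

__all__ = [
    "ConvLayerParams", "LSTMParams", "LSTMState",
    "conv2d_forward", "maxpool2d", "lstm_step", "lstm_sequence",
    "softmax_layer",
]


@dataclass
class ConvLayerParams:
    kernels: np.ndarray   # (out_channels, in_channels, 3, 3)
    bias: np.ndarray      # (out_channels,)

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels)
        self.bias = np.asarray(self.bias)
        if self.kernels.ndim != 4 or self.kernels.shape[2:] != (3, 3):
            raise ValueError("kernels must have shape (out, in, 3, 3)")
        if not (np.all(np.isfinite(self.kernels)) and np.all(np.isfinite(self.bias))):
            raise ValueError("parameters must be finite")


@dataclass
class LSTMParams:
    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        shape = np.shape(self.W_f)
        for name in ("W_i", "W_C", "W_o"):
            if np.shape(getattr(self, name)) != shape:
                raise ValueError("all gate matrices must share one shape")

    @property
    def hidden_size(self) -> int:
        return np.shape(self.W_f)[0]

    @property
    def input_size(self) -> int:
        return np.shape(self.W_f)[1] - self.hidden_size


@dataclass
class LSTMState:
    h: np.ndarray
    C: np.ndarray


# ---------------------------------------------------------------- conv ----
# The 3x3 valid convolution is evaluated as one GEMM over an explicitly
# buffered patch matrix: patches are gathered tap-by-tap into a
# contiguous (N*OH*OW, 9*C) buffer so the GEMM sees a wide inner
# dimension (reshaping a sliding-window view directly is far slower).

def _gather_patches(x: np.ndarray, oh: int, ow: int) -> np.ndarray:
    n, _, _, c = x.shape
    cols = np.empty((n, oh, ow, 9, c), dtype=x.dtype)
    for u in range(3):
        for v in range(3):
            cols[:, :, :, u * 3 + v, :] = x[:, u: u + oh, v: v + ow, :]
    return cols.reshape(n * oh * ow, 9 * c)


def _kernel_matrix(kernels: np.ndarray, dtype) -> np.ndarray:
    """(F, C, 3, 3) -> (9*C, F) matching the patch layout of _gather_patches."""
    return np.ascontiguousarray(
        kernels.transpose(2, 3, 1, 0).reshape(-1, kernels.shape[0]).astype(
            dtype, copy=False))


def conv2d_forward(x: np.ndarray, params: ConvLayerParams,
                   return_preactivation: bool = False):
    """Valid 3x3 cross-correlation, stride 1, + bias, + ReLU."""
    x = np.asarray(x)
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.ndim != 4:
        raise ValueError("input must be (H, W, C) or (N, H, W, C)")
    f, c_in = params.kernels.shape[:2]
    if x.shape[3] != c_in:
        raise ValueError(
            f"channel mismatch: input has {x.shape[3]}, kernels expect {c_in}")
    if x.shape[1] < 3 or x.shape[2] < 3:
        raise ValueError("spatial dimensions must be >= 3 for a valid 3x3 conv")
    n, h, w, _ = x.shape
    oh, ow = h - 2, w - 2
    cols = _gather_patches(x, oh, ow)
    pre = (cols @ _kernel_matrix(params.kernels, x.dtype)).reshape(n, oh, ow, f)
    pre += params.bias.astype(x.dtype, copy=False)
    out = np.maximum(pre, 0)
    if single:
        out, pre = out[0], pre[0]
    if return_preactivation:
        return out, (pre, cols)
    return out


def conv2d_backward(x: np.ndarray, pre: np.ndarray, dout: np.ndarray,
                    params: ConvLayerParams, need_dx: bool = True,
                    cols: np.ndarray | None = None):
    """Gradients for conv2d_forward.  ``dout`` is w.r.t. the ReLU output."""
    f, c_in = params.kernels.shape[:2]
    dpre = dout * (pre > 0)
    n, oh, ow = dpre.shape[:3]
    dmat = dpre.reshape(-1, f)
    if cols is None:
        cols = _gather_patches(x, oh, ow)
    dwmat = cols.T @ dmat                       # (9*C, F)
    dW = dwmat.reshape(3, 3, c_in, f).transpose(3, 2, 0, 1)
    db = dpre.sum(axis=(0, 1, 2))
    dx = None
    if need_dx:
        dcols = (dmat @ _kernel_matrix(params.kernels, dpre.dtype).T)
        dcols = dcols.reshape(n, oh, ow, 9, c_in)
        dx = np.zeros_like(x)
        for u in range(3):
            for v in range(3):
                dx[:, u: u + oh, v: v + ow, :] += dcols[:, :, :, u * 3 + v, :]
    return dx, dW, db


# ------------------------------------------------------------- pooling ----

def maxpool2d(x: np.ndarray, return_cache: bool = False):
    """Non-overlapping 2x2 max pooling; odd trailing row/column dropped."""
    x = np.asarray(x)
    single = x.ndim == 3
    if single:
        x = x[None]
    n, h, w, c = x.shape
    if h < 2 or w < 2:
        raise ValueError("spatial dimensions must be >= 2")
    oh, ow = h // 2, w // 2
    views = [x[:, u: 2 * oh: 2, v: 2 * ow: 2, :] for u in (0, 1) for v in (0, 1)]
    out = np.maximum(np.maximum(views[0], views[1]),
                     np.maximum(views[2], views[3]))
    if return_cache:
        # first-match masks route each gradient to exactly one tied entry
        masks = []
        found = np.zeros(out.shape, dtype=bool)
        for view in views:
            m = (view == out) & ~found
            found |= m
            masks.append(m)
        cache = (x.shape, masks)
    if single:
        out = out[0]
    return (out, cache) if return_cache else out


def maxpool2d_backward(dout: np.ndarray, cache) -> np.ndarray:
    (n, h, w, c), masks = cache
    oh, ow = h // 2, w // 2
    dx = np.zeros((n, h, w, c), dtype=dout.dtype)
    k = 0
    for u in (0, 1):
        for v in (0, 1):
            dx[:, u: 2 * oh: 2, v: 2 * ow: 2, :] += dout * masks[k]
            k += 1
    return dx


# ---------------------------------------------------------------- LSTM ----

def lstm_step(x_t: np.ndarray, prev: LSTMState, params: LSTMParams,
              cell_variant: str = "standard",
              return_cache: bool = False):
    """One LSTM cell update; accepts vectors or (N, dim) batches."""
    x_t = np.asarray(x_t)
    h_prev = np.asarray(prev.h)
    C_prev = np.asarray(prev.C)
    if x_t.shape[-1] != params.input_size or h_prev.shape[-1] != params.hidden_size:
        raise ValueError("input/state dimensions do not match gate matrices")
    z = np.concatenate([h_prev, x_t], axis=-1)
    f = sigmoid(z @ params.W_f.T + params.b_f)
    i = sigmoid(z @ params.W_i.T + params.b_i)
    chat = np.tanh(z @ params.W_C.T + params.b_C)
    if cell_variant == "standard":
        C = f * C_prev + i * chat
    elif cell_variant == "printed":
        C = f * C_prev + chat
    else:
        raise ValueError(f"unknown cell_variant {cell_variant!r}")
    o = sigmoid(z @ params.W_o.T + params.b_o)
    tanh_C = np.tanh(C)
    h = o * tanh_C
    state = LSTMState(h=h, C=C)
    if return_cache:
        return state, (z, f, i, chat, C_prev, o, tanh_C)
    return state


def lstm_layer_forward(xs: np.ndarray, params: LSTMParams,
                       cell_variant: str = "standard"):
    """Run one layer over a (T, N, D) sequence from zero state.

    Returns the (T, N, H) hidden sequence and per-step caches.
    """
    t_len, n = xs.shape[0], xs.shape[1]
    h = np.zeros((n, params.hidden_size), dtype=xs.dtype)
    C = np.zeros_like(h)
    state = LSTMState(h, C)
    hs = np.empty((t_len, n, params.hidden_size), dtype=xs.dtype)
    caches = []
    for t in range(t_len):
        state, cache = lstm_step(xs[t], state, params, cell_variant,
                                 return_cache=True)
        hs[t] = state.h
        caches.append(cache)
    return hs, caches


def lstm_layer_backward(dhs: np.ndarray, caches, params: LSTMParams):
    """BPTT for one layer.  ``dhs`` is (T, N, H) external hidden grads.

    Returns dxs (T, N, D) and a dict of parameter gradients.
    """
    t_len, n, hsize = dhs.shape
    dsize = params.input_size
    grads = {k: np.zeros_like(getattr(params, k))
             for k in ("W_f", "W_i", "W_C", "W_o", "b_f", "b_i", "b_C", "b_o")}
    dxs = np.empty((t_len, n, dsize), dtype=dhs.dtype)
    dh_next = np.zeros((n, hsize), dtype=dhs.dtype)
    dC_next = np.zeros_like(dh_next)
    for t in range(t_len - 1, -1, -1):
        z, f, i, chat, C_prev, o, tanh_C = caches[t]
        dh = dhs[t] + dh_next
        do = dh * tanh_C
        dC = dC_next + dh * o * (1 - tanh_C**2)
        df = dC * C_prev
        di = dC * chat
        dchat = dC * i
        dC_next = dC * f
        dzf = df * f * (1 - f)
        dzi = di * i * (1 - i)
        dzc = dchat * (1 - chat**2)
        dzo = do * o * (1 - o)
        grads["W_f"] += dzf.T @ z
        grads["W_i"] += dzi.T @ z
        grads["W_C"] += dzc.T @ z
        grads["W_o"] += dzo.T @ z
        grads["b_f"] += dzf.sum(axis=0)
        grads["b_i"] += dzi.sum(axis=0)
        grads["b_C"] += dzc.sum(axis=0)
        grads["b_o"] += dzo.sum(axis=0)
        dz = dzf @ params.W_f + dzi @ params.W_i + dzc @ params.W_C + dzo @ params.W_o
        dh_next = dz[:, :hsize]
        dxs[t] = dz[:, hsize:]
    return dxs, grads


def lstm_sequence(inputs: np.ndarray, layer_params: list[LSTMParams],
                  cell_variant: str = "standard") -> np.ndarray:
    """Stacked LSTM over a (T, D) or (T, N, D) sequence, zero initial states;
    returns the top layer's final hidden state."""
    xs = np.asarray(inputs)
    if xs.shape[0] == 0:
        raise ValueError("empty sequence")
    single = xs.ndim == 2
    if single:
        xs = xs[:, None, :]
    for params in layer_params:
        xs, _ = lstm_layer_forward(xs, params, cell_variant)
    out = xs[-1]
    return out[0] if single else out


# ------------------------------------------------------------- softmax ----

def softmax_layer(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = np.asarray(z, dtype=np.result_type(z, np.float32))
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)
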
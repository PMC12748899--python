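"""CNN-LSTM fusion network: assembly, forward/backward, loss, optimizer.

Architecture (defaults): three valid 3x3 conv layers ([16, 32, 64]
filters, ReLU) each followed by 2x2 max pooling, mapping a (128, 250, 1)
mel-spectrogram to (14, 29, 64); the pooled map is read as a length-29
temporal sequence of 14*64 frequency-channel vectors and fed to two
stacked 128-unit LSTM layers; the final hidden state is concatenated
with the global-average-pooled conv map, passed through a 64-unit ReLU
dense layer and a softmax output.  Objective: cross-entropy plus an L2
penalty lambda * ||W||^2 over weight matrices (biases excluded).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .layers import (ConvLayerParams, LSTMParams, conv2d_backward,
                     conv2d_forward, lstm_layer_backward, lstm_layer_forward,
                     maxpool2d, maxpool2d_backward, softmax_layer)

__all__ = ["ModelConfig", "init_parameters", "fusion_forward", "fusion_backward",
           "loss_cross_entropy_l2", "AdamOptimizer", "count_macs",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    conv_filters: tuple[int, ...] = (16, 32, 64)
    lstm_layers: int = 2
    lstm_hidden: int = 128
    dense_units: int = 64
    n_classes: int = 5
    input_shape: tuple[int, int, int] = (128, 250, 1)
    cell_variant: str = "standard"

    @property
    def n_conv(self) -> int:
        return len(self.conv_filters)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_conv < 1:
            raise ValueError("need at least one conv layer")

    def conv_shapes(self) -> list[tuple[int, int]]:
        """Spatial shapes after each conv (valid 3x3) and pool (2x2 floor)."""
        h, w, _ = self.input_shape
        shapes = []
        for _ in self.conv_filters:
            h, w = h - 2, w - 2          # valid conv
            h, w = h // 2, w // 2        # max pool
            shapes.append((h, w))
        return shapes

    @property
    def sequence_length(self) -> int:
        return self.conv_shapes()[-1][1]

    @property
    def lstm_input_size(self) -> int:
        h, _ = self.conv_shapes()[-1]
        return h * self.conv_filters[-1]

    @property
    def concat_size(self) -> int:
        return self.lstm_hidden + self.conv_filters[-1]


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_parameters(config: ModelConfig, seed: int = 0,
                    dtype=np.float32) -> dict:
    """Seeded uniform Glorot-style initialization."""
    rng = np.random.default_rng(seed)
    params: dict = {"conv": [], "lstm": []}
    c_in = config.input_shape[2]
    for f in config.conv_filters:
        fan_in, fan_out = c_in * 9, f * 9
        params["conv"].append(ConvLayerParams(
            kernels=_glorot(rng, (f, c_in, 3, 3), fan_in, fan_out, dtype),
            bias=np.zeros(f, dtype=dtype)))
        c_in = f
    in_size = config.lstm_input_size
    for _ in range(config.lstm_layers):
        h = config.lstm_hidden
        gate = {}
        for g in ("f", "i", "C", "o"):
            gate[f"W_{g}"] = _glorot(rng, (h, h + in_size), h + in_size, h, dtype)
            gate[f"b_{g}"] = np.zeros(h, dtype=dtype)
        # positive forget bias: standard trick for gradient flow early on
        gate["b_f"] = np.ones(h, dtype=dtype)
        params["lstm"].append(LSTMParams(**gate))
        in_size = h
    params["dense1"] = {
        "W": _glorot(rng, (config.dense_units, config.concat_size),
                     config.concat_size, config.dense_units, dtype),
        "b": np.zeros(config.dense_units, dtype=dtype)}
    params["out"] = {
        "W": _glorot(rng, (config.n_classes, config.dense_units),
                     config.dense_units, config.n_classes, dtype),
        "b": np.zeros(config.n_classes, dtype=dtype)}
    return params


def fusion_forward(x: np.ndarray, config: ModelConfig, params: dict,
                   return_cache: bool = False):
    """Class probabilities for mel inputs.

    ``x`` is (128, 250), (128, 250, 1), or a batch (N, 128, 250[, 1]).
    """
    x = np.asarray(x)
    h, w, c = config.input_shape
    single = False
    if x.ndim == 2:                       # (H, W)
        single = True
        x = x[None, :, :, None]
    elif x.ndim == 3:
        if x.shape == (h, w, c):          # (H, W, C) single input
            single = True
            x = x[None]
        else:                             # (N, H, W) channelless batch
            x = x[..., None]
    if x.shape[1:3] != config.input_shape[:2]:
        raise ValueError(f"expected input spatial shape {config.input_shape[:2]}, "
                         f"got {x.shape[1:3]}")
    if x.ndim != 4:
        raise ValueError("bad input rank")

    cache = {"x": x, "conv": []}
    a = x
    for layer in params["conv"]:
        out, (pre, cols) = conv2d_forward(a, layer, return_preactivation=True)
        pooled, pool_cache = maxpool2d(out, return_cache=True)
        cache["conv"].append({"in": a, "pre": pre, "cols": cols,
                              "pool": pool_cache})
        a = pooled
    # (N, H, T, C) -> time-major sequence of frequency-channel vectors
    n, fh, t_len, c = a.shape
    seq = a.transpose(2, 0, 1, 3).reshape(t_len, n, fh * c)
    cache["pooled_shape"] = a.shape
    cache["lstm"] = []
    hs = seq
    for lp in params["lstm"]:
        hs, layer_cache = lstm_layer_forward(hs, lp, config.cell_variant)
        cache["lstm"].append(layer_cache)
    h_last = hs[-1]
    gap = a.mean(axis=(1, 2))
    concat = np.concatenate([h_last, gap], axis=1)
    pre1 = concat @ params["dense1"]["W"].T + params["dense1"]["b"]
    act1 = np.maximum(pre1, 0)
    logits = act1 @ params["out"]["W"].T + params["out"]["b"]
    probs = softmax_layer(logits)
    cache.update(h_last=h_last, gap=gap, concat=concat, pre1=pre1, act1=act1,
                 logits=logits, probs=probs)
    if single:
        probs = probs[0]
    return (probs, cache) if return_cache else probs


def fusion_backward(cache: dict, dlogits: np.ndarray, config: ModelConfig,
                    params: dict, need_conv_grad: bool = False):
    """Backward pass from logit gradients.

    Returns parameter gradients; with ``need_conv_grad`` also the gradient
    w.r.t. the last conv layer's ReLU output (used by Grad-CAM).
    """
    grads: dict = {"conv": [], "lstm": [], "dense1": {}, "out": {}}
    act1 = cache["act1"]
    grads["out"]["W"] = dlogits.T @ act1
    grads["out"]["b"] = dlogits.sum(axis=0)
    dact1 = dlogits @ params["out"]["W"]
    dpre1 = dact1 * (cache["pre1"] > 0)
    grads["dense1"]["W"] = dpre1.T @ cache["concat"]
    grads["dense1"]["b"] = dpre1.sum(axis=0)
    dconcat = dpre1 @ params["dense1"]["W"]
    hsize = config.lstm_hidden
    dh_last = dconcat[:, :hsize]
    dgap = dconcat[:, hsize:]

    n, fh, t_len, c = cache["pooled_shape"]
    dhs = np.zeros((t_len, n, hsize), dtype=dh_last.dtype)
    dhs[-1] = dh_last
    lstm_grads = []
    dxs = dhs
    for lp, layer_cache in zip(reversed(params["lstm"]), reversed(cache["lstm"])):
        dxs, g = lstm_layer_backward(dxs, layer_cache, lp)
        lstm_grads.append(g)
    grads["lstm"] = list(reversed(lstm_grads))

    da = dxs.reshape(t_len, n, fh, c).transpose(1, 2, 0, 3)
    da = da + (dgap[:, None, None, :] / (fh * t_len))

    dconv_last = None
    for k in range(config.n_conv - 1, -1, -1):
        layer_cache = cache["conv"][k]
        dout = maxpool2d_backward(da, layer_cache["pool"])
        if need_conv_grad and k == config.n_conv - 1:
            dconv_last = dout
        da, dW, db = conv2d_backward(layer_cache["in"], layer_cache["pre"],
                                     dout, params["conv"][k], need_dx=k > 0,
                                     cols=layer_cache["cols"])
        grads["conv"].append({"kernels": dW, "bias": db})
    grads["conv"] = list(reversed(grads["conv"]))
    return (grads, dconv_last) if need_conv_grad else grads


def iter_weights(params: dict):
    """Yield (container, key, array) for every weight matrix (biases excluded)."""
    for layer in params["conv"]:
        yield layer, "kernels", layer.kernels
    for lp in params["lstm"]:
        for g in ("W_f", "W_i", "W_C", "W_o"):
            yield lp, g, getattr(lp, g)
    for name in ("dense1", "out"):
        yield params[name], "W", params[name]["W"]


def l2_penalty(params: dict) -> float:
    return float(sum(np.sum(w.astype(np.float64) ** 2)
                     for _, _, w in iter_weights(params)))


def loss_cross_entropy_l2(probs: np.ndarray, onehot: np.ndarray,
                          params: dict | None = None, lam: float = 0.0) -> float:
    """Mean -log p(true class) + lam * sum of squared weights."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    onehot = np.atleast_2d(np.asarray(onehot, dtype=np.float64))
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p_true = (probs * onehot).sum(axis=1)
    if np.any(p_true <= 0):
        warnings.warn("zero probability at true class; clipping at 1e-12",
                      stacklevel=2)
        p_true = np.clip(p_true, 1e-12, None)
    ce = float(-np.mean(np.log(p_true)))
    if lam > 0 and params is not None:
        ce += lam * l2_penalty(params)
    return ce


def _iter_all(params: dict):
    for layer in params["conv"]:
        yield layer, "kernels"
        yield layer, "bias"
    for lp in params["lstm"]:
        for g in ("W_f", "W_i", "W_C", "W_o", "b_f", "b_i", "b_C", "b_o"):
            yield lp, g
    for name in ("dense1", "out"):
        yield params[name], "W"
        yield params[name], "b"


def _get(container, key):
    return container[key] if isinstance(container, dict) else getattr(container, key)


def _set(container, key, value):
    if isinstance(container, dict):
        container[key] = value
    else:
        setattr(container, key, value)


def _grad_lookup(grads: dict, params: dict):
    """Pair every parameter slot with its gradient array."""
    pairs = []
    for (pc, key), (gc, _) in zip(_iter_all(params), _iter_all(grads)):
        pairs.append((pc, key, _get(gc, key)))
    return pairs


def clip_gradients(grads: dict, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.  LSTM backpropagation through time can
    produce occasional exploding gradients; clipping is the standard
    safeguard.
    """
    total = 0.0
    for gc, key in _iter_all(grads):
        g = _get(gc, key)
        total += float(np.sum(g.astype(np.float64) ** 2))
    norm = float(np.sqrt(total))
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / norm
        for gc, key in _iter_all(grads):
            _set(gc, key, _get(gc, key) * scale)
    return norm


class AdamOptimizer:
    """Adam with decoupled-from-nothing classic L2: grad += 2*lam*W."""

    def __init__(self, params: dict, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, lam: float = 0.0):
        self.lr, self.beta1, self.beta2, self.eps, self.lam = lr, beta1, beta2, eps, lam
        self.t = 0
        self.m = {}
        self.v = {}
        for idx, (pc, key) in enumerate(_iter_all(params)):
            arr = _get(pc, key)
            self.m[idx] = np.zeros_like(arr)
            self.v[idx] = np.zeros_like(arr)

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        weight_slots = {id(w) for _, _, w in iter_weights(params)}
        for idx, ((pc, key), (gc, _)) in enumerate(
                zip(_iter_all(params), _iter_all(grads))):
            p = _get(pc, key)
            g = _get(gc, key).astype(p.dtype, copy=False)
            if self.lam > 0 and id(p) in weight_slots:
                g = g + 2.0 * self.lam * p
            self.m[idx] = self.beta1 * self.m[idx] + (1 - self.beta1) * g
            self.v[idx] = self.beta2 * self.v[idx] + (1 - self.beta2) * g * g
            mhat = self.m[idx] / (1 - self.beta1**self.t)
            vhat = self.v[idx] / (1 - self.beta2**self.t)
            _set(pc, key, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def clone_params(params: dict) -> dict:
    out: dict = {"conv": [], "lstm": []}
    for layer in params["conv"]:
        out["conv"].append(ConvLayerParams(layer.kernels.copy(), layer.bias.copy()))
    for lp in params["lstm"]:
        out["lstm"].append(LSTMParams(
            **{k: getattr(lp, k).copy()
               for k in ("W_f", "W_i", "W_C", "W_o", "b_f", "b_i", "b_C", "b_o")}))
    for name in ("dense1", "out"):
        out[name] = {k: v.copy() for k, v in params[name].items()}
    return out


def count_macs(config: ModelConfig) -> dict:
    """Exact multiply-add counts per component for one forward pass.

    Conv layers follow n * k^2 * f per output position (n filters, k
    kernel size, f = input-map positions x input channels); the LSTM term
    is t * 4 * h * (h + d) per layer, the t*h^2-dominated recurrence cost.
    """
    h, w, c_in = config.input_shape
    conv_macs = 0
    for f in config.conv_filters:
        oh, ow = h - 2, w - 2
        conv_macs += oh * ow * f * c_in * 9
        h, w, c_in = oh // 2, ow // 2, f
    t_len = config.sequence_length
    d = config.lstm_input_size
    lstm_macs = 0
    for _ in range(config.lstm_layers):
        lstm_macs += t_len * 4 * config.lstm_hidden * (config.lstm_hidden + d)
        d = config.lstm_hidden
    dense_macs = (config.dense_units * config.concat_size
                  + config.n_classes * config.dense_units)
    return {"conv": conv_macs, "lstm": lstm_macs, "dense": dense_macs,
            "total": conv_macs + lstm_macs + dense_macs}


# -------------------------------------------------------- persistence ----

def save_checkpoint(path, config: ModelConfig, params: dict,
                    class_labels: list[str] | None = None) -> None:
    """Portable checkpoint: JSON header + named arrays (npz)."""
    path = Path(path)
    arrays = {}
    for idx, (pc, key) in enumerate(_iter_all(params)):
        arrays[f"p{idx:03d}_{key}"] = _get(pc, key)
    header = {
        "config": {"conv_filters": list(config.conv_filters),
                   "lstm_layers": config.lstm_layers,
                   "lstm_hidden": config.lstm_hidden,
                   "dense_units": config.dense_units,
                   "n_classes": config.n_classes,
                   "input_shape": list(config.input_shape),
                   "cell_variant": config.cell_variant},
        "class_labels": class_labels or [],
    }
    np.savez(path, header=json.dumps(header), **arrays)


def load_checkpoint(path):
    data = np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz")
                   else path, allow_pickle=False)
    header = json.loads(str(data["header"]))
    cfg = header["config"]
    config = ModelConfig(conv_filters=tuple(cfg["conv_filters"]),
                         lstm_layers=cfg["lstm_layers"],
                         lstm_hidden=cfg["lstm_hidden"],
                         dense_units=cfg["dense_units"],
                         n_classes=cfg["n_classes"],
                         input_shape=tuple(cfg["input_shape"]),
                         cell_variant=cfg["cell_variant"])
    params = init_parameters(config, seed=0)
    for idx, (pc, key) in enumerate(_iter_all(params)):
        _set(pc, key, data[f"p{idx:03d}_{key}"])
    return config, params, header["class_labels"]
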
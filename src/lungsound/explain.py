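"""Grad-CAM attribution over mel-spectrogram inputs.

Channel weights are spatial averages of the gradient of the pre-softmax
class score with respect to the last convolutional layer's ReLU
activations; the weighted activation sum is rectified, bilinearly
upsampled to the input's 128 x 250 grid, and min-max normalized (a map
that is non-positive everywhere normalizes to all zeros).  Because the
score is taken before the softmax, the map is invariant to adding a
constant to all logits by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .features import MelSpectrogram
from .model.network import ModelConfig, fusion_backward, fusion_forward

__all__ = ["GradCamMap", "grad_cam", "band_mass", "overlay_export"]


@dataclass
class GradCamMap:
    values: np.ndarray        # (128, 250) in [0, 1]
    target_class: int
    layer: int                # conv layer index the map was taken from

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("Grad-CAM map must be normalized to [0, 1]")


def _bilinear_resize(arr: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    h, w = arr.shape
    interp = RegularGridInterpolator(
        (np.arange(h), np.arange(w)), arr, method="linear",
        bounds_error=False, fill_value=None)
    # map output pixel centers onto the source grid
    rows = np.linspace(0, h - 1, out_shape[0])
    cols = np.linspace(0, w - 1, out_shape[1])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(out_shape)


def grad_cam(params: dict, config: ModelConfig, spec: MelSpectrogram,
             target_class: int, layer: int | None = None) -> GradCamMap:
    """Class-specific attribution map for one mel-spectrogram input."""
    if not 0 <= target_class < config.n_classes:
        raise ValueError("target class out of range")
    if layer is None:
        layer = config.n_conv - 1
    if layer != config.n_conv - 1:
        raise ValueError("attribution is implemented for the last conv layer")
    x = np.asarray(spec.values, dtype=np.float32)[None, :, :, None]
    _, cache = fusion_forward(x, config, params, return_cache=True)
    # gradient of the pre-softmax score for the target class
    dlogits = np.zeros((1, config.n_classes), dtype=np.float32)
    dlogits[0, target_class] = 1.0
    _, dconv = fusion_backward(cache, dlogits, config, params,
                               need_conv_grad=True)
    # activations of the last conv layer (ReLU output, pre-pool)
    pre = cache["conv"][layer]["pre"][0]
    act = np.maximum(pre, 0.0).astype(np.float64)
    grad = dconv[0].astype(np.float64)
    weights = grad.mean(axis=(0, 1))
    cam = np.maximum((act * weights).sum(axis=2), 0.0)
    cam = _bilinear_resize(cam, spec.values.shape)
    cam = np.maximum(cam, 0.0)
    hi, lo = cam.max(), cam.min()
    cam = np.zeros_like(cam) if hi <= lo or hi == 0 else (cam - lo) / (hi - lo)
    return GradCamMap(values=cam, target_class=target_class, layer=layer)


def band_mass(cam: GradCamMap, mel_center_freqs: np.ndarray,
              band: tuple[float, float]) -> float:
    """Fraction of total heatmap mass in mel rows whose centers lie in ``band``."""
    total = cam.values.sum()
    if total == 0:
        return 0.0
    rows = (mel_center_freqs >= band[0]) & (mel_center_freqs <= band[1])
    return float(cam.values[rows].sum() / total)


def overlay_export(spec: MelSpectrogram, cam: GradCamMap, path,
                   frame_duration: float = 2.5) -> Path:
    """PNG of the spectrogram (grayscale) with the heatmap alpha-blended."""
    if cam.values.shape != spec.values.shape:
        raise ValueError("heatmap and spectrogram shapes must match")
    path = Path(path)
    extent = [0.0, frame_duration,
              float(spec.mel_center_freqs[0]), float(spec.mel_center_freqs[-1])]
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.imshow(spec.values, cmap="gray", aspect="auto", origin="lower",
              extent=extent)
    ax.imshow(cam.values, cmap="jet", alpha=0.4 * (cam.values > 0) + 0.05,
              aspect="auto", origin="lower", extent=extent)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mel center frequency (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
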
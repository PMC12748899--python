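"""Waveform-level data augmentation and class-balancing expansion.

Three label-preserving transforms: phase-vocoder time stretching
(0.9-1.1x), pitch shifting (+-2 semitones, resample + stretch), and
additive white Gaussian noise at 10% of the signal RMS (20 dB SNR).
``expand_class`` grows a class to ceil(multiplier * n) recordings by
cycling transforms deterministically; originals are kept untouched and
augmented copies are flagged.  Default multipliers reproduce the corpus
composition table: pneumonia 1.5x, asthma/COPD/COVID-19 3x, healthy 1x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .synth import AnnotatedRecording

__all__ = ["AugmentPolicy", "pitch_shift", "time_stretch", "inject_noise",
           "expand_class"]

DEFAULT_MULTIPLIERS = {
    "healthy": 1.0,
    "pneumonia": 1.5,
    "asthma": 3.0,
    "COPD": 3.0,
    "COVID-19": 3.0,
    "bronchiectasis": 3.0,
}


@dataclass(frozen=True)
class AugmentPolicy:
    pitch_semitones: float = 2.0          # drawn uniformly from +-this
    stretch_range: tuple[float, float] = (0.9, 1.1)
    noise_fraction: float = 0.10          # noise RMS / signal RMS
    per_class_multiplier: dict = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.per_class_multiplier.values()):
            raise ValueError("multipliers must be >= 1")
        lo, hi = self.stretch_range
        if not (0 < lo <= hi < 2):
            raise ValueError("stretch range must lie within (0, 2)")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")


_N_FFT = 1024
_HOP = 256


def _stft(x: np.ndarray) -> np.ndarray:
    window = np.hanning(_N_FFT)
    n_frames = 1 + int(np.ceil(max(x.size - _N_FFT, 0) / _HOP))
    padded = np.zeros((n_frames - 1) * _HOP + _N_FFT)
    padded[: x.size] = x
    idx = np.arange(_N_FFT)[None, :] + _HOP * np.arange(n_frames)[:, None]
    return np.fft.rfft(padded[idx] * window, axis=1)


def _istft(frames: np.ndarray, out_len: int) -> np.ndarray:
    window = np.hanning(_N_FFT)
    n_frames = frames.shape[0]
    y = np.zeros((n_frames - 1) * _HOP + _N_FFT)
    norm = np.zeros_like(y)
    chunks = np.fft.irfft(frames, n=_N_FFT, axis=1)
    for k in range(n_frames):
        start = k * _HOP
        y[start: start + _N_FFT] += chunks[k] * window
        norm[start: start + _N_FFT] += window**2
    y /= np.maximum(norm, 1e-8)
    return y[:out_len]


def time_stretch(x: np.ndarray, rate: float) -> np.ndarray:
    """Phase-vocoder time stretch: output duration = input / rate."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    x = np.asarray(x, dtype=np.float64)
    if rate == 1.0:
        return x.copy()
    spec = _stft(x)
    n_in = spec.shape[0]
    steps = np.arange(0, n_in - 1, rate)
    omega = 2 * np.pi * _HOP * np.arange(spec.shape[1]) / _N_FFT

    out = np.zeros((steps.size, spec.shape[1]), dtype=complex)
    phase = np.angle(spec[0])
    for k, step in enumerate(steps):
        i = int(step)
        frac = step - i
        s0, s1 = spec[i], spec[min(i + 1, n_in - 1)]
        mag = (1 - frac) * np.abs(s0) + frac * np.abs(s1)
        out[k] = mag * np.exp(1j * phase)
        dphi = np.angle(s1) - np.angle(s0) - omega
        dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
        phase = phase + omega + dphi
    return _istft(out, int(round(x.size / rate)))


def pitch_shift(x: np.ndarray, sample_rate: int, semitones: float) -> np.ndarray:
    """Shift pitch by 2^(semitones/12); output length equals input length."""
    if abs(semitones) > 12:
        raise ValueError("|semitones| must be <= 12")
    x = np.asarray(x, dtype=np.float64)
    if semitones == 0:
        return x.copy()
    factor = 2.0 ** (semitones / 12.0)
    # speed up/down by `factor` (pitch and duration change together) ...
    ratio = Fraction(1.0 / factor).limit_denominator(1000)
    sped = sps.resample_poly(x, ratio.numerator, ratio.denominator)
    # ... then stretch duration back, keeping the shifted pitch
    out = time_stretch(sped, rate=sped.size / x.size)
    if out.size < x.size:
        out = np.pad(out, (0, x.size - out.size))
    return out[: x.size]


def inject_noise(x: np.ndarray, noise_fraction: float, seed) -> np.ndarray:
    """Add white Gaussian noise with RMS = noise_fraction * signal RMS."""
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    if noise_fraction == 0:
        return x.copy()
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0:
        raise ValueError("zero-RMS signal cannot define a noise level")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return x + noise_fraction * rms * rng.standard_normal(x.size)


_TRANSFORM_CYCLE = ("pitch", "stretch", "noise", "pitch+noise")


def _apply_transform(rec: AnnotatedRecording, name: str, policy: AugmentPolicy,
                     rng: np.random.Generator) -> AnnotatedRecording:
    x = rec.samples
    if "pitch" in name:
        semis = rng.uniform(-policy.pitch_semitones, policy.pitch_semitones)
        x = pitch_shift(x, rec.sample_rate, semis)
    if "stretch" in name:
        x = time_stretch(x, rng.uniform(*policy.stretch_range))
    if "noise" in name:
        x = inject_noise(x, policy.noise_fraction, rng)
    return AnnotatedRecording(
        samples=x, sample_rate=rec.sample_rate, class_label=rec.class_label,
        crackle_flag=rec.crackle_flag, wheeze_flag=rec.wheeze_flag,
        subject_id=rec.subject_id, dataset_tag=rec.dataset_tag,
        augmented=1, cycles=list(rec.cycles),
    )


def expand_class(examples: list[AnnotatedRecording],
                 policy: AugmentPolicy) -> list[AnnotatedRecording]:
    """Grow one class to ceil(multiplier * n); originals first, unmodified."""
    if not examples:
        raise ValueError("cannot expand an empty class")
    label = examples[0].class_label
    if any(r.class_label != label for r in examples):
        raise ValueError("expand_class expects a single-class list")
    m = policy.per_class_multiplier.get(label, 1.0)
    if m < 1:
        raise ValueError("multiplier must be >= 1")
    target = math.ceil(m * len(examples))
    rng = np.random.default_rng(policy.seed)
    out = list(examples)
    i = 0
    while len(out) < target:
        src = examples[i % len(examples)]
        name = _TRANSFORM_CYCLE[i % len(_TRANSFORM_CYCLE)]
        out.append(_apply_transform(src, name, policy, rng))
        i += 1
    return out
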
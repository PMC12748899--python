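"""Time-frequency representations and the disease-specific band weighting.

The primary input representation is a 128-band mel-spectrogram computed
from 25 ms Hann windows with a 10 ms hop.  Windows are left-aligned at
t = k*hop so a 2.5 s frame yields exactly 250 columns (the tail window is
zero-padded).  Power is converted to dB with an 80 dB floor relative to
the frame maximum and min-max scaled to [0, 1].

The weighted mapping emphasises the adventitious-sound bands: mel rows
above 1 kHz are scaled by 1.5 when the frame carries a crackle annotation
(pneumonia-type), and rows with centers in 200-800 Hz by 1.3 when it
carries a wheeze annotation (asthma/COPD-type).  Weighting is applied to
the feature matrix, not the loss, and may push values above 1; it is
deliberately not re-normalized so the two band weightings commute and are
exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft

__all__ = [
    "MelSpectrogram",
    "WeightProfile",
    "AuxFeatureSet",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "mel_center_frequencies",
    "mel_spectrogram",
    "apply_weight_map",
    "mfcc",
    "stft_spectrogram",
    "zero_crossing_rate",
    "chroma",
]

N_MELS = 128
WINDOW_S = 0.025
HOP_S = 0.010
N_FFT = 1024  # zero-padded FFT length for the 25 ms window
DB_FLOOR = -80.0


@dataclass
class MelSpectrogram:
    values: np.ndarray                 # (n_mels, n_cols), [0, 1] before weighting
    mel_center_freqs: np.ndarray       # Hz, strictly increasing
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mel_center_freqs = np.asarray(self.mel_center_freqs, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("mel spectrogram must be finite")
        if self.values.shape[0] != self.mel_center_freqs.size:
            raise ValueError("row count must equal number of mel filters")


@dataclass(frozen=True)
class WeightProfile:
    crackle_weight: float = 1.5
    crackle_cutoff: float = 1000.0          # Hz; rows strictly above get weighted
    wheeze_weight: float = 1.3
    wheeze_band: tuple[float, float] = (200.0, 800.0)

    def __post_init__(self) -> None:
        if self.crackle_weight < 1 or self.wheeze_weight < 1:
            raise ValueError("weights must be >= 1")
        if not self.wheeze_band[0] < self.wheeze_band[1]:
            raise ValueError("wheeze band must be (low, high) with low < high")


@dataclass
class AuxFeatureSet:
    mfcc: np.ndarray      # (13, n_cols)
    stft_db: np.ndarray   # (n_fft/2+1, n_cols)
    zcr: np.ndarray       # (n_cols,)
    chroma: np.ndarray    # (12, n_cols)


def hz_to_mel(f):
    """HTK mel scale."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_center_frequencies(n_mels: int, sample_rate: int) -> np.ndarray:
    edges = mel_to_hz(np.linspace(0.0, hz_to_mel(sample_rate / 2.0), n_mels + 2))
    return edges[1:-1]


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Triangular filters on the HTK mel scale, 0 Hz to Nyquist.

    Filters are area-normalized (each scaled by 2 / bandwidth, the Slaney
    convention): without this, wider high-frequency filters integrate more
    bins and a spectrally flat input ramps up with frequency.
    """
    edges = mel_to_hz(np.linspace(0.0, hz_to_mel(sample_rate / 2.0), n_mels + 2))
    fft_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (fft_freqs - lo) / (ctr - lo)
        down = (hi - fft_freqs) / (hi - ctr)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None) * (2.0 / (hi - lo))
    return fb


def _frame_signal(samples: np.ndarray, sample_rate: int) -> np.ndarray:
    """Left-aligned 25 ms windows every 10 ms; returns (n_cols, win) matrix."""
    win = int(round(WINDOW_S * sample_rate))
    hop = int(round(HOP_S * sample_rate))
    n_cols = int(np.ceil(samples.size / hop))
    needed = (n_cols - 1) * hop + win
    padded = np.zeros(needed)
    padded[: samples.size] = samples
    idx = np.arange(win)[None, :] + hop * np.arange(n_cols)[:, None]
    return padded[idx]


def _power_stft(samples: np.ndarray, sample_rate: int) -> np.ndarray:
    frames = _frame_signal(samples, sample_rate)
    window = np.hanning(frames.shape[1])
    spec = rfft(frames * window, n=N_FFT, axis=1)
    return (np.abs(spec) ** 2).T  # (n_fft/2+1, n_cols)


def _expected_cols(n_samples: int, sample_rate: int) -> int:
    return int(np.ceil(n_samples / int(round(HOP_S * sample_rate))))


def _check_frame(frame, expected_s: float = 2.5):
    n_expected = int(round(expected_s * frame.sample_rate))
    if frame.samples.size != n_expected:
        raise ValueError(
            f"frame must be exactly {expected_s} s "
            f"({n_expected} samples at {frame.sample_rate} Hz), "
            f"got {frame.samples.size}"
        )


def mel_spectrogram(frame, n_mels: int = N_MELS) -> MelSpectrogram:
    """128 x 250 scaled mel-spectrogram of a 2.5 s segment frame."""
    _check_frame(frame)
    sr = frame.sample_rate
    power = _power_stft(frame.samples, sr)
    mel_power = mel_filterbank(n_mels, N_FFT, sr) @ power
    ref = mel_power.max()
    if ref <= 0:
        values = np.zeros_like(mel_power)
    else:
        db = 10.0 * np.log10(np.maximum(mel_power / ref, 10.0 ** (DB_FLOOR / 10.0)))
        lo, hi = db.min(), db.max()
        values = np.zeros_like(db) if hi == lo else (db - lo) / (hi - lo)
    return MelSpectrogram(values, mel_center_frequencies(n_mels, sr),
                          frame_id=f"{frame.recording_id}@{frame.offset:.3f}")


def apply_weight_map(spec: MelSpectrogram, crackle_flag: int, wheeze_flag: int,
                     profile: WeightProfile = WeightProfile()) -> MelSpectrogram:
    """Scale annotated adventitious bands; rows are selected by center frequency."""
    values = spec.values.copy()
    freqs = spec.mel_center_freqs
    if crackle_flag:
        values[freqs > profile.crackle_cutoff] *= profile.crackle_weight
    if wheeze_flag:
        lo, hi = profile.wheeze_band
        values[(freqs >= lo) & (freqs <= hi)] *= profile.wheeze_weight
    np.clip(values, 0.0, None, out=values)
    return MelSpectrogram(values, freqs.copy(), frame_id=spec.frame_id)


def mfcc(frame, n_coeff: int = 13, n_mels: int = N_MELS) -> np.ndarray:
    """DCT-II (orthonormal) of the log-mel energies; (n_coeff, 250)."""
    _check_frame(frame)
    sr = frame.sample_rate
    mel_power = mel_filterbank(n_mels, N_FFT, sr) @ _power_stft(frame.samples, sr)
    log_mel = 10.0 * np.log10(np.maximum(mel_power, 1e-10))
    return dct(log_mel, type=2, axis=0, norm="ortho")[:n_coeff]


def stft_spectrogram(frame) -> np.ndarray:
    """dB power spectrogram, (n_fft/2+1, 250)."""
    _check_frame(frame)
    power = _power_stft(frame.samples, frame.sample_rate)
    return 10.0 * np.log10(np.maximum(power, 1e-10))


def zero_crossing_rate(frame) -> np.ndarray:
    """Per 25 ms window: fraction of adjacent sample pairs changing sign."""
    _check_frame(frame)
    frames = _frame_signal(frame.samples, frame.sample_rate)
    signs = np.signbit(frames)
    return np.mean(signs[:, 1:] != signs[:, :-1], axis=1)


_PITCH_CLASSES = ("C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B")


def chroma(frame) -> np.ndarray:
    """12 pitch-class energy profile per column (A440 reference, C = class 0)."""
    _check_frame(frame)
    sr = frame.sample_rate
    power = _power_stft(frame.samples, sr)
    fft_freqs = np.arange(N_FFT // 2 + 1) * sr / N_FFT
    out = np.zeros((12, power.shape[1]))
    valid = fft_freqs > 0
    pc = np.mod(np.round(12.0 * np.log2(fft_freqs[valid] / 440.0)).astype(int) + 9, 12)
    for c in range(12):
        out[c] = power[valid][pc == c].sum(axis=0)
    return out


def aux_features(frame) -> AuxFeatureSet:
    return AuxFeatureSet(mfcc=mfcc(frame), stft_db=stft_spectrogram(frame),
                         zcr=zero_crossing_rate(frame), chroma=chroma(frame))
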
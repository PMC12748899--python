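"""Signal conditioning for auscultation recordings.

Pipeline order is fixed: resample -> high-pass filter -> silence trim ->
z-score normalization -> fixed-length segmentation.  The high-pass is a
4th-order Butterworth applied forward-backward (zero phase), the standard
choice for removing rumble/heart-sound leakage below 100 Hz.  Frames are
2.5 s with 50% overlap; a recording shorter than one frame yields a single
zero-padded frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "PreprocessConfig",
    "SegmentFrame",
    "resample",
    "highpass_filter",
    "trim_silence",
    "zscore_normalize",
    "segment_frames",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    target_sample_rate: int = 8000
    highpass_cutoff: float = 100.0
    frame_length: float = 2.5       # seconds
    overlap_fraction: float = 0.5
    silence_threshold_db: float = -40.0
    normalize_per_frame: bool = False  # z-score each frame instead of the recording

    def __post_init__(self) -> None:
        if not 0 < self.highpass_cutoff < self.target_sample_rate / 2:
            raise ValueError("cutoff must lie in (0, Nyquist)")
        if self.frame_length <= 0:
            raise ValueError("frame_length must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.silence_threshold_db >= 0:
            raise ValueError("silence threshold is relative dB and must be < 0")


@dataclass(frozen=True)
class SegmentFrame:
    samples: np.ndarray
    sample_rate: int
    recording_id: str
    offset: float  # seconds from recording start

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def resample(samples: np.ndarray, source_rate: int, target_rate: int) -> np.ndarray:
    """Band-limited (polyphase) resampling; duration preserved within one sample."""
    if source_rate <= 0 or target_rate <= 0:
        raise ValueError("sample rates must be positive")
    if source_rate == target_rate:
        return np.asarray(samples, dtype=np.float64).copy()
    ratio = Fraction(target_rate, source_rate).limit_denominator(10000)
    return signal.resample_poly(np.asarray(samples, dtype=np.float64),
                                ratio.numerator, ratio.denominator)


def highpass_filter(samples: np.ndarray, cutoff: float, sample_rate: int) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass."""
    nyquist = sample_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    samples = np.asarray(samples, dtype=np.float64)
    sos = signal.butter(4, cutoff, "highpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, samples)


def _window_rms(samples: np.ndarray, win: int) -> np.ndarray:
    n_win = int(np.ceil(samples.size / win))
    padded = np.zeros(n_win * win)
    padded[: samples.size] = samples
    return np.sqrt(np.mean(padded.reshape(n_win, win) ** 2, axis=1))


def trim_silence(samples: np.ndarray, sample_rate: int,
                 threshold_db: float = -40.0, window_s: float = 0.05) -> np.ndarray:
    """Drop leading/trailing 50 ms windows below ``threshold_db`` rel. peak RMS."""
    if threshold_db >= 0:
        raise ValueError("threshold_db must be negative (relative dB)")
    samples = np.asarray(samples, dtype=np.float64)
    win = max(int(round(window_s * sample_rate)), 1)
    rms = _window_rms(samples, win)
    peak = rms.max() if rms.size else 0.0
    if peak <= 0:
        raise ValueError("entirely silent input")
    keep = rms >= peak * 10.0 ** (threshold_db / 20.0)
    if not keep.any():
        raise ValueError("entirely silent input")
    first, last = np.flatnonzero(keep)[[0, -1]]
    return samples[first * win: min((last + 1) * win, samples.size)].copy()


def zscore_normalize(samples: np.ndarray) -> np.ndarray:
    """(L - mu) / sigma with the population standard deviation."""
    samples = np.asarray(samples, dtype=np.float64)
    sigma = samples.std()  # population (ddof=0)
    if sigma == 0:
        raise ValueError("constant signal: standard deviation is zero")
    return (samples - samples.mean()) / sigma


def segment_frames(samples: np.ndarray, sample_rate: int,
                   frame_length: float = 2.5, overlap_fraction: float = 0.5,
                   recording_id: str = "") -> list[SegmentFrame]:
    """Fixed-length frames; hop = frame_length * (1 - overlap)."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("empty signal")
    n_frame = int(round(frame_length * sample_rate))
    hop = frame_length * (1.0 - overlap_fraction)
    n_hop = int(round(hop * sample_rate))
    duration = samples.size / sample_rate

    if samples.size < n_frame:
        warnings.warn("signal shorter than one frame; zero-padding", stacklevel=2)
        padded = np.zeros(n_frame)
        padded[: samples.size] = samples
        return [SegmentFrame(padded, sample_rate, recording_id, 0.0)]

    n_frames = int(np.floor((duration - frame_length) / hop)) + 1
    frames = []
    for k in range(n_frames):
        start = k * n_hop
        frames.append(
            SegmentFrame(samples[start: start + n_frame].copy(), sample_rate,
                         recording_id, start / sample_rate)
        )
    return frames


def preprocess_recording(samples: np.ndarray, source_rate: int,
                         config: PreprocessConfig = PreprocessConfig(),
                         recording_id: str = "") -> list[SegmentFrame]:
    """Full pipeline: resample -> high-pass -> trim -> z-score -> segment.

    Normalization is per recording by default; ``normalize_per_frame``
    instead z-scores each frame after segmentation (constant frames are
    left as-is there, rather than raising as the recording-level path
    does).
    """
    x = resample(samples, source_rate, config.target_sample_rate)
    x = highpass_filter(x, config.highpass_cutoff, config.target_sample_rate)
    x = trim_silence(x, config.target_sample_rate, config.silence_threshold_db)
    if not config.normalize_per_frame:
        x = zscore_normalize(x)
    frames = segment_frames(x, config.target_sample_rate, config.frame_length,
                            config.overlap_fraction, recording_id)
    if config.normalize_per_frame:
        frames = [
            SegmentFrame(zscore_normalize(f.samples) if f.samples.std() > 0
                         else f.samples, f.sample_rate, f.recording_id, f.offset)
            for f in frames
        ]
    return frames
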
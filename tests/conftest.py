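import numpy as np
import pytest

from lungsound.preprocess import SegmentFrame

SR = 8000
FRAME_N = 20000  # 2.5 s at 8 kHz


def tone(freq: float, duration: float = 2.5, sr: int = SR, phase: float = 0.0):
    t = np.arange(int(round(duration * sr))) / sr
    return np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture
def make_frame():
    def _make(samples, sr: int = SR, rec_id: str = "test", offset: float = 0.0):
        return SegmentFrame(np.asarray(samples, dtype=np.float64), sr, rec_id, offset)
    return _make


@pytest.fixture
def tone_frame(make_frame):
    def _make(freq: float, sr: int = SR):
        return make_frame(tone(freq, 2.5, sr), sr)
    return _make


def band_energy_fraction(x: np.ndarray, sr: int, lo: float, hi: float = np.inf):
    """FFT band-energy oracle."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / sr)
    sel = (freqs >= lo) & (freqs <= hi)
    return spec[sel].sum() / spec.sum()


def dominant_frequency(x: np.ndarray, sr: int):
    """FFT argmax oracle."""
    spec = np.abs(np.fft.rfft(x))
    spec[0] = 0.0
    return np.fft.rfftfreq(x.size, 1.0 / sr)[spec.argmax()]


@pytest.fixture(scope="session")
def trained_synthetic_run():
    """Seeded corpus-to-metrics experiment shared by the end-to-end tests.

    Full per-class composition (300/200/150/100), subject-wise folds,
    train-fold augmentation, and the default fusion architecture; short
    recordings and a reduced epoch cap keep the run desk-scale.
    """
    from lungsound.experiment import run_synthetic_experiment

    return run_synthetic_experiment(seed=1, max_epochs=15)
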
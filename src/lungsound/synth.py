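"""Seeded, class-conditional synthetic auscultation recordings.

Emulates the structure of public lung-sound corpora: per-class WAV
recordings with per-cycle crackle/wheeze annotations and a CSV manifest,
so the whole classification pipeline is testable without downloading
real data.  The acoustic models are deliberately simple but carry the
band signatures the downstream weighting scheme assumes:

* crackle  -- short transient (5-40 ms), dominant energy above 1 kHz
              (damped sinusoid at 1.2-2.5 kHz over a broadband click);
* wheeze   -- sustained tone (>= 250 ms) with fundamental in 200-800 Hz,
              amplitude tied to the respiratory envelope;
* cough    -- 200-500 ms broadband burst with a sharp attack;
* breath   -- white noise low-passed at 1 kHz, shaped by a raised-sine
              respiratory envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "SyntheticClassSpec",
    "SubjectProfile",
    "SyntheticDatasetConfig",
    "AnnotatedRecording",
    "CycleAnnotation",
    "DEFAULT_CLASS_SPECS",
    "TABLE_ICBHI_COUNTS",
    "TABLE_COSWARA_COUNTS",
    "synth_event",
    "generate_recording",
    "generate_recordings",
    "generate_dataset",
]

CLASS_LABELS = ("healthy", "pneumonia", "asthma", "COPD", "bronchiectasis", "COVID-19")

#: Per-class original recording counts of the ICBHI-like corpus.
TABLE_ICBHI_COUNTS = {"healthy": 300, "pneumonia": 200, "asthma": 150, "COPD": 100}
#: Per-class original recording counts of the Coswara-like corpus.
TABLE_COSWARA_COUNTS = {"healthy": 200, "pneumonia": 150, "asthma": 100, "COVID-19": 100}


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Event statistics that define one disease class.

    crackle_rate    -- crackle transients per respiratory cycle (>= 0)
    wheeze_fraction -- proportion of each cycle occupied by wheeze, in [0, 1]
    cough_rate      -- cough bursts per recording (>= 0)
    breath_noise_level -- target RMS of the envelope-shaped breath noise
    crackle_band / wheeze_band -- Hz ranges the event frequencies are drawn from
    """

    class_label: str
    crackle_rate: float = 0.0
    wheeze_fraction: float = 0.0
    cough_rate: float = 0.0
    breath_noise_level: float = 0.05
    crackle_band: tuple[float, float] = (1200.0, 2500.0)
    wheeze_band: tuple[float, float] = (200.0, 800.0)

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.crackle_rate < 0 or self.cough_rate < 0:
            raise ValueError("event rates must be >= 0")
        if not 0.0 <= self.wheeze_fraction <= 1.0:
            raise ValueError("wheeze_fraction must lie in [0, 1]")
        if self.breath_noise_level <= 0:
            raise ValueError("breath_noise_level must be > 0")
        if self.class_label == "healthy" and (
            self.crackle_rate or self.wheeze_fraction or self.cough_rate
        ):
            raise ValueError("healthy spec must have no adventitious events")
        if self.class_label == "pneumonia" and self.crackle_rate <= 0:
            raise ValueError("pneumonia spec requires crackle_rate > 0")
        if self.class_label in ("asthma", "COPD") and self.wheeze_fraction <= 0:
            raise ValueError(f"{self.class_label} spec requires wheeze_fraction > 0")


#: Study-condition defaults.  Pneumonia-like recordings carry crackle
#: transients, asthma/COPD sustained wheezes (separable by pitch range and
#: duty cycle), bronchiectasis a crackle+wheeze mixture, COVID-19 coughs.
DEFAULT_CLASS_SPECS: dict[str, SyntheticClassSpec] = {
    "healthy": SyntheticClassSpec("healthy"),
    "pneumonia": SyntheticClassSpec("pneumonia", crackle_rate=2.5),
    "asthma": SyntheticClassSpec(
        "asthma", wheeze_fraction=0.5, wheeze_band=(420.0, 800.0)
    ),
    "COPD": SyntheticClassSpec(
        "COPD", wheeze_fraction=0.3, wheeze_band=(200.0, 380.0)
    ),
    "bronchiectasis": SyntheticClassSpec(
        "bronchiectasis", crackle_rate=2.0, wheeze_fraction=0.25
    ),
    "COVID-19": SyntheticClassSpec("COVID-19", cough_rate=3.0),
}


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    breathing_rate: float = 16.0  # respiratory cycles per minute, [12, 24]
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 12.0 <= self.breathing_rate <= 24.0:
            raise ValueError("breathing_rate must lie in [12, 24] cycles/min")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    counts: dict[str, int] = field(default_factory=lambda: dict(TABLE_ICBHI_COUNTS))
    duration: float = 10.0
    sample_rate: int = 8000
    seed: int = 0
    dataset_tag: str = "icbhi-like"

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("per-class counts must be >= 0")
        if self.duration < 2.5:
            raise ValueError("duration must be >= the 2.5 s frame length")
        if self.sample_rate < 4000:
            raise ValueError("sample rate must be >= 4000 Hz")


@dataclass(frozen=True)
class CycleAnnotation:
    """One respiratory-cycle segment of an annotation sidecar."""

    start_s: float
    end_s: float
    crackle: int
    wheeze: int


@dataclass
class AnnotatedRecording:
    samples: np.ndarray
    sample_rate: int
    class_label: str
    crackle_flag: int
    wheeze_flag: int
    subject_id: str
    dataset_tag: str = ""
    augmented: int = 0
    cycles: list[CycleAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def synth_event(kind: str, sample_rate: int, seed, *, band=None,
                duration=None) -> np.ndarray:
    """Synthesize a single adventitious event waveform.

    ``band`` optionally overrides the frequency range the event's
    characteristic frequency is drawn from (crackle center frequency or
    wheeze fundamental); ``duration`` (s) overrides the random draw.
    """
    if sample_rate < 4000:
        raise ValueError("sample_rate must be >= 4000 Hz")
    rng = _rng(seed)
    nyq = sample_rate / 2.0

    if kind == "crackle":
        lo, hi = band or (1200.0, 2500.0)
        hi = min(hi, 0.9 * nyq)
        dur = duration if duration is not None else rng.uniform(0.008, 0.04)
        n = max(int(round(dur * sample_rate)), 8)
        t = np.arange(n) / sample_rate
        f0 = rng.uniform(lo, hi)
        tau = dur / 3.0
        body = np.exp(-t / tau) * np.sin(2 * np.pi * f0 * t)
        # 5 ms broadband click at onset, kept small so >1 kHz energy dominates
        n_click = min(int(0.005 * sample_rate), n)
        click = np.zeros(n)
        click[:n_click] = 0.25 * rng.standard_normal(n_click) * np.exp(
            -np.arange(n_click) / (0.3 * n_click + 1)
        )
        return body + click

    if kind == "wheeze":
        lo, hi = band or (200.0, 800.0)
        dur = duration if duration is not None else rng.uniform(0.3, 0.8)
        n = int(round(dur * sample_rate))
        t = np.arange(n) / sample_rate
        f0 = rng.uniform(lo, hi)
        # near-constant-frequency tone; slight vibrato keeps it from being
        # a bare FFT line while the fundamental stays inside the band
        vibrato = 4.0 * np.sin(2 * np.pi * rng.uniform(3.0, 6.0) * t)
        phase = 2 * np.pi * np.cumsum(f0 + vibrato) / sample_rate
        return np.hanning(n) * np.sin(phase)

    if kind == "cough":
        dur = duration if duration is not None else rng.uniform(0.2, 0.5)
        n = int(round(dur * sample_rate))
        noise = rng.standard_normal(n)
        # sharp attack, exponential decay
        attack = min(int(0.01 * sample_rate), n)
        env = np.exp(-np.arange(n) / (0.25 * n))
        env[:attack] *= np.linspace(0.0, 1.0, attack)
        sos = signal.butter(2, min(50.0, 0.4 * nyq), "highpass", fs=sample_rate, output="sos")
        return signal.sosfilt(sos, noise) * env

    raise ValueError(f"unsupported event kind {kind!r}")


def _breath_noise(n: int, sample_rate: int, envelope: np.ndarray, level: float,
                  rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(n)
    cutoff = min(1000.0, 0.45 * sample_rate)
    sos = signal.butter(4, cutoff, "lowpass", fs=sample_rate, output="sos")
    shaped = signal.sosfilt(sos, noise) * envelope
    rms = float(np.sqrt(np.mean(shaped**2)))
    return shaped * (level / rms) if rms > 0 else shaped


def _add_at(x: np.ndarray, start: int, event: np.ndarray) -> None:
    start = max(0, min(start, x.size - 1))
    end = min(start + event.size, x.size)
    x[start:end] += event[: end - start]


def generate_recording(
    spec: SyntheticClassSpec,
    profile: SubjectProfile,
    duration: float,
    sample_rate: int,
    seed,
    dataset_tag: str = "",
) -> AnnotatedRecording:
    """Render one annotated recording for a class spec and subject."""
    if duration < 2.5:
        raise ValueError("duration must be >= the 2.5 s frame length")
    rng = _rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    period = 60.0 / profile.breathing_rate
    phase0 = rng.uniform(0.0, 1.0)
    phase = (t / period + phase0) % 1.0
    # raised-sine respiratory envelope with a small baseline
    envelope = 0.1 + 0.9 * np.sin(np.pi * phase) ** 2

    x = _breath_noise(n, sample_rate, envelope, spec.breath_noise_level, rng)

    n_cycles = duration / period
    cycle_starts = (np.arange(math.ceil(n_cycles + 1)) - phase0) * period
    cycle_starts = cycle_starts[(cycle_starts + period > 0) & (cycle_starts < duration)]
    cycle_has_crackle = {i: 0 for i in range(len(cycle_starts))}
    cycle_has_wheeze = {i: 0 for i in range(len(cycle_starts))}

    def cycle_index(time_s: float) -> int:
        idx = int(np.searchsorted(cycle_starts, time_s, side="right")) - 1
        return int(np.clip(idx, 0, len(cycle_starts) - 1))

    if spec.crackle_rate > 0:
        n_crackles = math.ceil(spec.crackle_rate * n_cycles)
        # crackles are brief; they must stand well above the local noise
        # floor to be audible (and detectable) at all
        amp = 8.0 * spec.breath_noise_level
        for _ in range(n_crackles):
            ev = synth_event("crackle", sample_rate, rng, band=spec.crackle_band)
            # place crackles inside inspiration (high-envelope region)
            pos = rng.uniform(0.0, duration - ev.size / sample_rate)
            for _try in range(8):
                cand = rng.uniform(0.0, duration - ev.size / sample_rate)
                if envelope[int(cand * sample_rate)] > 0.5:
                    pos = cand
                    break
            _add_at(x, int(pos * sample_rate), amp * ev)
            cycle_has_crackle[cycle_index(pos)] = 1

    if spec.wheeze_fraction > 0:
        amp = 2.0 * spec.breath_noise_level
        for i, start in enumerate(cycle_starts):
            w_dur = max(0.25, spec.wheeze_fraction * period)
            ev = synth_event("wheeze", sample_rate, rng, band=spec.wheeze_band,
                             duration=w_dur)
            # center the wheeze on the envelope peak of this cycle
            center = start + 0.5 * period
            pos = max(0.0, min(center - w_dur / 2, duration - ev.size / sample_rate))
            _add_at(x, int(pos * sample_rate), amp * ev)
            cycle_has_wheeze[i] = 1

    if spec.cough_rate > 0:
        n_coughs = math.ceil(spec.cough_rate)
        amp = 4.0 * spec.breath_noise_level
        for _ in range(n_coughs):
            ev = synth_event("cough", sample_rate, rng)
            pos = rng.uniform(0.0, max(duration - ev.size / sample_rate, 0.0))
            _add_at(x, int(pos * sample_rate), amp * ev)

    x *= profile.amplitude_scale

    cycles = []
    for i, start in enumerate(cycle_starts):
        s = max(0.0, float(start))
        e = min(duration, float(start + period))
        cycles.append(CycleAnnotation(s, e, cycle_has_crackle[i], cycle_has_wheeze[i]))

    return AnnotatedRecording(
        samples=x,
        sample_rate=sample_rate,
        class_label=spec.class_label,
        crackle_flag=int(spec.crackle_rate > 0),
        wheeze_flag=int(spec.wheeze_fraction > 0),
        subject_id=profile.subject_id,
        dataset_tag=dataset_tag,
        cycles=cycles,
    )


def _assign_subjects(label: str, count: int, tag: str,
                     rng: np.random.Generator) -> list[SubjectProfile]:
    """One subject contributes 1-5 recordings; every recording has a subject."""
    profiles: list[SubjectProfile] = []
    s = 0
    while len(profiles) < count:
        s += 1
        per_subject = int(rng.integers(1, 6))
        profile = SubjectProfile(
            subject_id=f"{tag}-{label}-s{s:04d}",
            breathing_rate=float(rng.uniform(12.0, 24.0)),
            amplitude_scale=float(rng.uniform(0.8, 1.25)),
        )
        profiles.extend([profile] * per_subject)
    return profiles[:count]


def generate_recordings(
    config: SyntheticDatasetConfig,
    class_specs: dict[str, SyntheticClassSpec] | None = None,
) -> list[AnnotatedRecording]:
    """Generate the configured corpus in memory (deterministic per seed)."""
    specs = dict(DEFAULT_CLASS_SPECS)
    if class_specs:
        specs.update(class_specs)
    rng = np.random.default_rng(config.seed)
    recordings: list[AnnotatedRecording] = []
    for label in sorted(config.counts):
        count = config.counts[label]
        if count == 0:
            continue
        if label not in specs:
            raise ValueError(f"no class spec for label {label!r}")
        profiles = _assign_subjects(label, count, config.dataset_tag, rng)
        for profile in profiles:
            recordings.append(
                generate_recording(
                    specs[label], profile, config.duration, config.sample_rate,
                    rng, dataset_tag=config.dataset_tag,
                )
            )
    return recordings


def write_wav(path: Path, samples: np.ndarray, sample_rate: int) -> None:
    """Mono 16-bit PCM output."""
    clipped = np.clip(samples, -1.0, 1.0)
    wavfile.write(path, sample_rate, np.round(clipped * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    else:
        data = data.astype(np.float64)
    if data.ndim > 1:
        data = data.mean(axis=1)
    return data, int(sr)


def generate_dataset(
    config: SyntheticDatasetConfig,
    out_dir,
    class_specs: dict[str, SyntheticClassSpec] | None = None,
) -> pd.DataFrame:
    """Write WAVs, per-recording annotation sidecars, and a manifest CSV.

    Returns the manifest with columns
    ``path,label,subject_id,dataset_tag,crackle,wheeze``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings = generate_recordings(config, class_specs)
    rows = []
    for i, rec in enumerate(recordings):
        name = f"{config.dataset_tag}_{rec.class_label}_{i:05d}"
        wav_path = out_dir / f"{name}.wav"
        write_wav(wav_path, rec.samples, rec.sample_rate)
        ann_path = out_dir / f"{name}.txt"
        with open(ann_path, "w") as fh:
            for c in rec.cycles:
                fh.write(f"{c.start_s:.3f}\t{c.end_s:.3f}\t{c.crackle}\t{c.wheeze}\n")
        rows.append(
            {
                "path": str(wav_path),
                "label": rec.class_label,
                "subject_id": rec.subject_id,
                "dataset_tag": rec.dataset_tag,
                "crackle": rec.crackle_flag,
                "wheeze": rec.wheeze_flag,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["path", "label", "subject_id", "dataset_tag", "crackle", "wheeze"]
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
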
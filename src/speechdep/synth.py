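"""Synthetic interview corpus with a controllable class-dependent voice signature.

Each speaker is a harmonic "voice" (fundamental near 120 Hz, amplitudes
falling off as 1/h) whose pitch wanders slowly under a random modulation,
mixed with low-band shaped noise and a high-band (2-7 kHz) noise component.
The depressed class speaks more monotonously: its pitch-modulation depth and
its high-band energy are both scaled by (1 - 0.8*effect).  With effect=0 the
two classes share an identical generative law; with effect=1 the high-band
energy ratio separates crops almost perfectly.  The signature lives in slow
temporal modulation and spectral tilt — visible in a log-spectrogram and
untouched by per-spectrogram min-max normalization, which would erase any
plain gain difference.

Per-speaker randomness derives from the global seed through a counter-based
seed sequence ([seed, label, index]), so a corpus is reproducible and stable
under roster growth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .corpus import (
    CANONICAL_RATE,
    AudioRecording,
    SegmentAnnotation,
    SpeakerRecord,
    ValidationError,
    save_roster,
    save_segments,
    write_wav,
)

MIN_DURATION_S = 4.0  # every recording must admit at least one crop

# generative constants (class-independent baselines)
_F0_HZ = 120.0
_N_HARMONICS = 10
_MOD_DEPTH = 0.08  # fractional pitch excursion, non-depressed
_MOD_RATE_HZ = 4.0  # control-point rate of the slow pitch modulation
_LOW_NOISE_GAIN = 0.30  # low-band noise RMS relative to voiced RMS
_HIGH_NOISE_GAIN = 0.35  # high-band noise RMS relative to voiced RMS
_CLASS_SCALE = 0.8  # label-1 scaling is (1 - effect * _CLASS_SCALE)


@dataclass
class SynthConfig:
    """Corpus-level generation parameters.

    ``n_per_class`` are (non-depressed, depressed) speaker counts and default
    to the 100:42 imbalance of the corpus being emulated; ``duration_law`` is
    the (mean, sd) in seconds of a truncated normal (>= 4 s) matching that
    corpus's recording-length statistics.  ``n_test_per_class`` of each class
    are assigned to the test split (the rest are train).
    """

    n_per_class: tuple[int, int] = (100, 42)
    n_test_per_class: tuple[int, int] = (0, 0)
    duration_law: tuple[float, float] = (547.29, 237.58)
    effect: float = 1.0
    phq8_law: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {0: (0, 9), 1: (10, 24)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_class, int):
            self.n_per_class = (self.n_per_class, self.n_per_class)
        if isinstance(self.n_test_per_class, int):
            self.n_test_per_class = (self.n_test_per_class, self.n_test_per_class)
        if not 0.0 <= self.effect <= 1.0:
            raise ValidationError("effect must lie in [0, 1]")
        if min(self.n_per_class) < 1:
            raise ValidationError("need at least one speaker per class")
        for lab in (0, 1):
            if self.n_test_per_class[lab] >= self.n_per_class[lab]:
                raise ValidationError("test speakers must leave at least one train speaker")


def class_scale(label: int, effect: float) -> float:
    """Modulation-depth / high-band scaling applied to the depressed class."""
    return 1.0 - effect * _CLASS_SCALE if label == 1 else 1.0


def _slow_modulation(rng: np.random.Generator, n: int, rate: int) -> np.ndarray:
    """Unit-variance slow random curve (control points every 1/_MOD_RATE_HZ s)."""
    n_ctrl = max(4, int(np.ceil(n / rate * _MOD_RATE_HZ)) + 2)
    ctrl = rng.standard_normal(n_ctrl)
    t = np.arange(n) / rate * _MOD_RATE_HZ
    curve = np.interp(t, np.arange(n_ctrl), ctrl)
    sd = curve.std()
    return curve / sd if sd > 0 else curve


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt((x**2).mean()))


def generate_speaker_audio(
    label: int,
    duration_s: float,
    effect: float,
    seed,
    speaker_id: str = "synthetic",
    rate: int = CANONICAL_RATE,
) -> AudioRecording:
    """Deterministic voice-like waveform carrying the class signature.

    ``seed`` may be an int or a numpy SeedSequence.  Raises if the duration
    cannot hold a single 4-s crop.
    """
    if duration_s < MIN_DURATION_S:
        raise ValidationError(f"duration {duration_s} s < minimum {MIN_DURATION_S} s")
    if not 0.0 <= effect <= 1.0:
        raise ValidationError("effect must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    scale = class_scale(label, effect)

    depth = _MOD_DEPTH * scale
    f0 = _F0_HZ * (1.0 + depth * _slow_modulation(rng, n, rate))
    phase = 2.0 * np.pi * np.cumsum(f0) / rate
    voiced = np.zeros(n)
    for h in range(1, _N_HARMONICS + 1):
        voiced += np.sin(h * phase + rng.uniform(0, 2 * np.pi)) / h
    voiced /= _rms(voiced)

    sos_lo = butter(4, 1000.0, btype="low", fs=rate, output="sos")
    sos_hi = butter(4, [2000.0, 7000.0], btype="band", fs=rate, output="sos")
    noise_lo = sosfiltfilt(sos_lo, rng.standard_normal(n))
    noise_hi = sosfiltfilt(sos_hi, rng.standard_normal(n))
    noise_lo *= _LOW_NOISE_GAIN / _rms(noise_lo)
    noise_hi *= _HIGH_NOISE_GAIN * scale / _rms(noise_hi)

    x = voiced + noise_lo + noise_hi
    x *= 0.5 / np.abs(x).max()
    return AudioRecording(speaker_id, x.astype(np.float64), rate)


def _draw_duration(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0:
        return max(float(mean), MIN_DURATION_S)
    # rejection-sampled truncated normal, lower bound = one crop length
    for _ in range(10_000):
        d = rng.normal(mean, sd)
        if d >= MIN_DURATION_S:
            return float(d)
    return MIN_DURATION_S


def synthesize_roster(
    config: SynthConfig,
) -> tuple[list[SpeakerRecord], dict[str, AudioRecording]]:
    """Generate the corpus in memory: roster records plus recordings.

    Speaker i of class lab gets seed sequence [seed, lab, i]; its duration and
    PHQ-8 score come from the same per-speaker stream, so existing speakers
    are unchanged when the roster grows.
    """
    records: list[SpeakerRecord] = []
    recordings: dict[str, AudioRecording] = {}
    for lab in (0, 1):
        n_total = config.n_per_class[lab]
        n_test = config.n_test_per_class[lab]
        lo, hi = config.phq8_law[lab]
        for i in range(n_total):
            ss = np.random.SeedSequence([config.seed, lab, i])
            rng = np.random.default_rng(ss)
            duration = _draw_duration(rng, *config.duration_law)
            phq8 = int(rng.integers(lo, hi + 1))
            sid = f"spk{lab}{i:03d}"
            split = "test" if i >= n_total - n_test else "train"
            records.append(SpeakerRecord(sid, phq8, lab, split))
            recordings[sid] = generate_speaker_audio(
                lab, duration, config.effect, ss.spawn(1)[0], speaker_id=sid
            )
    return records, recordings


def generate_corpus(config: SynthConfig, out_dir: str | Path) -> Path:
    """Write the synthetic corpus to disk: WAVs, labels.csv, segments.csv, manifest.

    Segment annotations are trivial (one all-participant span per speaker);
    the manifest records the full configuration for provenance.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "wav").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create corpus directory {out}: {exc}") from exc
    records, recordings = synthesize_roster(config)
    annotations = []
    for rec in records:
        audio = recordings[rec.speaker_id]
        write_wav(out / "wav" / f"{rec.speaker_id}.wav", audio.samples, audio.rate)
        annotations.append(
            SegmentAnnotation(rec.speaker_id, [(0.0, audio.duration, "participant")])
        )
    save_roster(records, out / "labels.csv")
    save_segments(annotations, out / "segments.csv")
    manifest = asdict(config)
    manifest["phq8_law"] = {str(k): list(v) for k, v in config.phq8_law.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
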
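"""Corpus I/O: speaker rosters, WAV audio and participant-segment annotations.

The screening task starts from one interview recording per speaker plus a
label table carrying the PHQ-8 questionnaire score (0-24).  A score of 10 or
more marks the speaker as depressed.  Recordings may contain a second
(interviewer) voice; a segment-annotation table — the output of a diarization
step run elsewhere — says which time spans belong to the participant, and
only those spans are kept.  All audio is canonicalized to 16 kHz mono.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

CANONICAL_RATE = 16_000
PHQ8_THRESHOLD = 10
PHQ8_MAX = 24


class FormatError(ValueError):
    """A table or file does not have the expected layout."""


class ValidationError(ValueError):
    """A value violates a domain contract (range, uniqueness, consistency)."""


class EmptyRecordingError(ValueError):
    """No participant audio remains after segment filtering."""


def binarize_phq8(score: int) -> int:
    """Map a PHQ-8 score to the binary depression label (1 iff score >= 10)."""
    score = int(score)
    if not 0 <= score <= PHQ8_MAX:
        raise ValidationError(f"PHQ-8 score {score} outside [0, {PHQ8_MAX}]")
    return 1 if score >= PHQ8_THRESHOLD else 0


@dataclass(frozen=True)
class SpeakerRecord:
    """One speaker: identity, PHQ-8 score, derived binary label, split."""

    speaker_id: str
    phq8: int
    label: int
    split: str = "train"

    def __post_init__(self) -> None:
        if self.split not in ("train", "test"):
            raise ValidationError(f"split must be 'train' or 'test', got {self.split!r}")
        if self.label != binarize_phq8(self.phq8):
            raise ValidationError(
                f"label {self.label} inconsistent with phq8={self.phq8} for "
                f"speaker {self.speaker_id!r}"
            )


@dataclass
class AudioRecording:
    """Mono waveform for one speaker at the canonical 16 kHz rate."""

    speaker_id: str
    samples: np.ndarray
    rate: int = CANONICAL_RATE

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.rate


@dataclass
class SegmentAnnotation:
    """Who-spoke-when spans for one recording (diarization stand-in)."""

    speaker_id: str
    segments: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, stop, who in self.segments:
            if not 0 <= start < stop:
                raise ValidationError(
                    f"segment ({start}, {stop}) invalid for {self.speaker_id!r}"
                )
            if who not in ("participant", "interviewer"):
                raise ValidationError(f"unknown segment role {who!r}")
        spans = sorted((s, e) for s, e, _ in self.segments)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"overlapping segments in annotation for {self.speaker_id!r}"
                )

    def participant_spans(self) -> list[tuple[float, float]]:
        return sorted((s, e) for s, e, who in self.segments if who == "participant")


# ---------------------------------------------------------------------------
# Roster I/O


def load_roster(path: str | Path, exclude: Iterable[str] = ()) -> list[SpeakerRecord]:
    """Read a label CSV (speaker_id, phq8[, split]) into speaker records.

    ``exclude`` drops listed speaker ids (e.g. known low-quality recordings).
    Rows get label 1 iff phq8 >= 10; a missing split column means all train.
    """
    df = pd.read_csv(path, dtype={"speaker_id": str})
    required = {"speaker_id", "phq8"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"label table missing column(s): {sorted(missing)}")
    excluded = set(exclude)
    records: list[SpeakerRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        sid = str(row["speaker_id"])
        if sid in excluded:
            continue
        if sid in seen:
            raise ValidationError(f"duplicate speaker_id {sid!r} (row {idx})")
        seen.add(sid)
        try:
            phq8 = int(row["phq8"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-integer phq8 in row {idx}: {row['phq8']!r}") from exc
        if not 0 <= phq8 <= PHQ8_MAX:
            raise ValidationError(f"phq8 {phq8} out of range in row {idx} ({sid!r})")
        split = str(row["split"]) if "split" in df.columns else "train"
        records.append(SpeakerRecord(sid, phq8, binarize_phq8(phq8), split))
    return records


def save_roster(records: Sequence[SpeakerRecord], path: str | Path) -> None:
    """Write speaker records as a label CSV (round-trips with load_roster)."""
    pd.DataFrame(
        {
            "speaker_id": [r.speaker_id for r in records],
            "phq8": [r.phq8 for r in records],
            "split": [r.split for r in records],
        }
    ).to_csv(path, index=False)


def load_segments(path: str | Path) -> dict[str, SegmentAnnotation]:
    """Read a segment CSV (speaker_id, start_s, stop_s, who) grouped per speaker."""
    df = pd.read_csv(path, dtype={"speaker_id": str})
    required = {"speaker_id", "start_s", "stop_s", "who"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"segment table missing column(s): {sorted(missing)}")
    out: dict[str, SegmentAnnotation] = {}
    for sid, grp in df.groupby("speaker_id", sort=False):
        segs = [
            (float(r.start_s), float(r.stop_s), str(r.who)) for r in grp.itertuples()
        ]
        out[str(sid)] = SegmentAnnotation(str(sid), segs)
    return out


def save_segments(annotations: Sequence[SegmentAnnotation], path: str | Path) -> None:
    rows = [
        {"speaker_id": a.speaker_id, "start_s": s, "stop_s": e, "who": who}
        for a in annotations
        for (s, e, who) in a.segments
    ]
    pd.DataFrame(rows, columns=["speaker_id", "start_s", "stop_s", "who"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Audio I/O


def _to_float_mono(data: np.ndarray) -> np.ndarray:
    if data.ndim == 2:  # average channels to mono
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    return data.astype(np.float64)


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file as float mono in [-1, 1] plus its sample rate."""
    try:
        rate, data = wavfile.read(str(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read WAV file {path}: {exc}") from exc
    return _to_float_mono(np.asarray(data)), int(rate)


def write_wav(path: str | Path, samples: np.ndarray, rate: int = CANONICAL_RATE) -> None:
    """Write float samples in [-1, 1] as 16-bit PCM."""
    clipped = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    wavfile.write(str(path), rate, (clipped * 32767.0).astype(np.int16))


def resample_to_canonical(samples: np.ndarray, rate: int) -> np.ndarray:
    """Polyphase-resample a waveform to 16 kHz (identity when already there)."""
    if rate == CANONICAL_RATE:
        return np.asarray(samples, dtype=np.float64)
    g = math.gcd(CANONICAL_RATE, rate)
    return resample_poly(np.asarray(samples, dtype=np.float64), CANONICAL_RATE // g, rate // g)


def trim_silence(
    samples: np.ndarray,
    rate: int,
    frame_ms: float = 25.0,
    threshold_frac: float = 0.005,
) -> np.ndarray:
    """Drop low-energy frames (RMS below threshold_frac of the peak frame RMS).

    Fallback used only when no segment annotation is available; surviving
    frames are concatenated in order.
    """
    frame = max(1, int(round(frame_ms * rate / 1000.0)))
    n_frames = len(samples) // frame
    if n_frames == 0:
        return np.asarray(samples, dtype=np.float64)
    frames = np.asarray(samples[: n_frames * frame], dtype=np.float64).reshape(n_frames, frame)
    rms = np.sqrt((frames**2).mean(axis=1))
    keep = rms >= threshold_frac * rms.max()
    kept = frames[keep].reshape(-1)
    tail = np.asarray(samples[n_frames * frame :], dtype=np.float64)
    return np.concatenate([kept, tail]) if tail.size else kept


def load_participant_audio(
    path: str | Path,
    annotation: SegmentAnnotation | None = None,
    speaker_id: str | None = None,
    silence_trim: bool = False,
) -> AudioRecording:
    """Load a WAV, keep participant segments, canonicalize to 16 kHz.

    With an annotation, participant spans are cut out (at the original rate)
    and concatenated in time order.  Without one the whole file is kept,
    optionally passed through energy-based silence trimming.
    """
    sid = speaker_id or (annotation.speaker_id if annotation else Path(path).stem)
    if annotation is not None and speaker_id is not None and annotation.speaker_id != speaker_id:
        raise ValidationError(
            f"annotation speaker {annotation.speaker_id!r} != requested {speaker_id!r}"
        )
    samples, rate = read_wav(path)
    if annotation is not None:
        spans = annotation.participant_spans()
        pieces = []
        for start, stop in spans:
            i0 = int(round(start * rate))
            i1 = min(int(round(stop * rate)), len(samples))
            if i1 > i0:
                pieces.append(samples[i0:i1])
        if not pieces:
            raise EmptyRecordingError(f"no participant audio for {sid!r}")
        samples = np.concatenate(pieces)
    elif silence_trim:
        samples = trim_silence(samples, rate)
    if samples.size == 0:
        raise EmptyRecordingError(f"no audio content in {path}")
    return AudioRecording(sid, resample_to_canonical(samples, rate), CANONICAL_RATE)
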
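"""Log-spectrogram extraction with the fixed geometry the classifier expects.

A 4-s crop at 16 kHz, analyzed every 32 ms over 64 ms Hamming windows with a
1024-point FFT, becomes a 513 x 125 matrix of log STFT magnitudes.  The frame
count follows T0 = floor(n_samples / hop): frames are centered (the signal is
padded by half a window on each side) and the trailing boundary frame is
dropped, so a 64000-sample crop yields exactly 125 frames.  Each spectrogram
is min-max normalized to [0, 1] independently of every other one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.signal import get_window

from .corpus import CANONICAL_RATE, ValidationError


@dataclass(frozen=True)
class StftParams:
    """STFT analysis parameters (defaults give the canonical 513 x 125 grid)."""

    win_ms: float = 64.0
    hop_ms: float = 32.0
    nfft: int = 1024
    eps: float = 1e-10  # log floor; below any voiced magnitude

    def win_samples(self, rate: int) -> int:
        return int(round(self.win_ms * rate / 1000.0))

    def hop_samples(self, rate: int) -> int:
        return int(round(self.hop_ms * rate / 1000.0))

    @property
    def n_freq(self) -> int:
        return self.nfft // 2 + 1


@dataclass
class LogSpectrogram:
    """One crop's frequency x time matrix, tagged with its provenance."""

    matrix: np.ndarray
    speaker_id: str = ""
    crop_index: int = 0
    normalized: bool = False

    @property
    def n_freq(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


def frame_count(n_samples: int, hop: int) -> int:
    """Number of STFT frames for a signal of ``n_samples`` at hop ``hop``."""
    return n_samples // hop


def compute_log_spectrogram(
    samples: np.ndarray,
    rate: int = CANONICAL_RATE,
    params: StftParams = StftParams(),
    speaker_id: str = "",
    crop_index: int = 0,
) -> LogSpectrogram:
    """Log-magnitude STFT of one crop.

    Frames start every hop in the half-window zero-padded signal, and the
    matrix has floor(n/hop) columns and nfft/2+1 rows.  Entries are
    log(|STFT| + eps); the result is unnormalized.
    """
    x = np.asarray(samples, dtype=np.float64)
    win = params.win_samples(rate)
    hop = params.hop_samples(rate)
    if x.size < win:
        raise ValidationError(
            f"crop of {x.size} samples shorter than one {win}-sample window"
        )
    if params.nfft < win:
        raise ValidationError("nfft must be >= window length")
    t0 = frame_count(x.size, hop)
    pad = win // 2
    padded = np.concatenate([np.zeros(pad), x, np.zeros(pad)])
    # frames t*hop .. t*hop+win in the padded signal, t = 0..T0-1
    idx = np.arange(win)[None, :] + hop * np.arange(t0)[:, None]
    frames = padded[idx] * get_window("hamming", win, fftbins=True)
    mag = np.abs(np.fft.rfft(frames, n=params.nfft, axis=1))
    matrix = np.log(mag + params.eps).T.astype(np.float32)
    return LogSpectrogram(matrix, speaker_id, crop_index, normalized=False)


def minmax_normalize(spec: LogSpectrogram) -> LogSpectrogram:
    """Rescale one spectrogram to [0, 1]; a constant matrix maps to all zeros."""
    m = spec.matrix
    lo, hi = float(m.min()), float(m.max())
    if hi > lo:
        out = (m - lo) / (hi - lo)
    else:
        out = np.zeros_like(m)
    return LogSpectrogram(out.astype(np.float32), spec.speaker_id, spec.crop_index, True)


def extract_crop_features(
    recording_samples: np.ndarray,
    offsets_s: list[float],
    crop_s: float = 4.0,
    rate: int = CANONICAL_RATE,
    params: StftParams = StftParams(),
    speaker_id: str = "",
    normalize: bool = True,
) -> list[LogSpectrogram]:
    """Cut crops at the given offsets and return their (normalized) spectrograms."""
    n_crop = int(round(crop_s * rate))
    out = []
    for j, off in enumerate(offsets_s):
        i0 = int(round(off * rate))
        crop = recording_samples[i0 : i0 + n_crop]
        if crop.size < n_crop:
            raise ValidationError(
                f"offset {off}s leaves only {crop.size} samples for a "
                f"{n_crop}-sample crop of {speaker_id!r}"
            )
        spec = compute_log_spectrogram(crop, rate, params, speaker_id, j)
        out.append(minmax_normalize(spec) if normalize else spec)
    return out


# ---------------------------------------------------------------------------
# Feature container: one .npz per split with a JSON sidecar


def save_features(
    path: str | Path,
    specs_by_speaker: dict[str, np.ndarray],
    offsets_by_speaker: dict[str, list[float]],
    params: StftParams = StftParams(),
) -> None:
    """Store per-speaker spectrogram stacks (Li, F0, T0) with provenance sidecar."""
    path = Path(path)
    np.savez_compressed(path, **{sid: arr for sid, arr in specs_by_speaker.items()})
    sidecar = {
        "stft": asdict(params),
        "speakers": {
            sid: {"n_crops": int(specs_by_speaker[sid].shape[0]),
                  "offsets_s": [float(o) for o in offsets_by_speaker.get(sid, [])]}
            for sid in specs_by_speaker
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_features(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Load a feature container; returns (speaker -> (Li,F0,T0) array, sidecar)."""
    path = Path(path)
    with np.load(path) as z:
        specs = {sid: z[sid] for sid in z.files}
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return specs, sidecar
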
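"""Balanced crop sampling of heterogeneous-length recordings.

Recordings are cut into non-overlapping fixed-length crops (default 4 s)
aligned to multiples of the crop length.  Because the corpus is imbalanced
(many more non-depressed than depressed speakers) and recording lengths vary
widely, the training set is built by choosing c crops from each of k speakers
per class so that the total 2*k*c is maximal: every candidate crops-per-
speaker value c admits k(c) = min over classes of the number of speakers with
at least c available crops, and the optimizer maximizes 2*k(c)*c, breaking
ties toward smaller c (more speakers, less per-speaker bias).  Test speakers
are never dropped: each contributes min(cap, available) crops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import AudioRecording, SpeakerRecord, ValidationError


class InfeasibleSamplingError(ValueError):
    """A class has no speaker with at least one available crop."""


@dataclass(frozen=True)
class CropSpec:
    """Fixed-length, non-overlapping cropping geometry."""

    s: float = 4.0  # crop length in seconds

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValidationError("crop length must be positive")


@dataclass
class SamplingPlan:
    """The optimized balanced selection: who contributes which crop offsets."""

    c: int  # crops per selected speaker
    k: int  # speakers per class
    selected: dict[int, list[str]]  # class label -> k speaker ids
    offsets: dict[str, list[float]]  # speaker id -> c crop start offsets (s)
    seed: int = 0

    @property
    def total(self) -> int:
        return 2 * self.k * self.c


def count_available_crops(duration: float, s: float = 4.0) -> int:
    """Number of whole non-overlapping s-second crops in a recording."""
    if s <= 0:
        raise ValidationError("crop length must be positive")
    if duration < 0:
        raise ValidationError("duration must be non-negative")
    # guard against float fuzz on exact multiples (e.g. durations from n/rate)
    return int(math.floor(duration / s + 1e-9))


def optimize_sampling_plan(counts: dict[int, list[int]]) -> tuple[int, int, int]:
    """Maximize total balanced samples 2*k*c over candidate crops-per-speaker c.

    ``counts`` maps class label -> available crop counts of that class's
    speakers.  Returns (c, k, total).  Candidates are the distinct positive
    counts; k(c) is the smaller class's number of speakers with count >= c.
    Ties in total break toward smaller c.
    """
    if set(counts) != {0, 1}:
        raise ValidationError(f"expected classes {{0, 1}}, got {sorted(counts)}")
    for label, vals in counts.items():
        if not any(v >= 1 for v in vals):
            raise InfeasibleSamplingError(f"class {label} has no speaker with any crop")
    arr = {lab: np.asarray(vals, dtype=np.int64) for lab, vals in counts.items()}
    candidates = sorted({int(v) for vals in counts.values() for v in vals if v >= 1})
    best = (0, 0, -1)  # (c, k, total)
    for c in candidates:
        k = min(int((arr[0] >= c).sum()), int((arr[1] >= c).sum()))
        total = 2 * k * c
        if total > best[2]:
            best = (c, k, total)
    c, k, total = best
    if total <= 0:
        raise InfeasibleSamplingError("no feasible balanced plan")
    return c, k, total


def _aligned_offsets(duration: float, s: float) -> list[float]:
    return [i * s for i in range(count_available_crops(duration, s))]


def materialize_plan(
    records: list[SpeakerRecord],
    durations: dict[str, float],
    crop: CropSpec = CropSpec(),
    seed: int | None = None,
) -> tuple[SamplingPlan, pd.DataFrame]:
    """Turn the optimal (c, k) into concrete seeded speaker and offset draws.

    When a class has more than k eligible speakers, k are drawn uniformly
    without replacement; each selected speaker contributes c of its aligned
    non-overlapping offsets, drawn uniformly without replacement.  Returns the
    plan plus a crop manifest (speaker_id, crop_index, offset_s, label, split).
    """
    if seed is None:
        raise ValidationError("a seed is required: crop selection must be reproducible")
    by_class: dict[int, list[SpeakerRecord]] = {0: [], 1: []}
    for r in records:
        by_class[r.label].append(r)
    counts = {
        lab: [count_available_crops(durations[r.speaker_id], crop.s) for r in rs]
        for lab, rs in by_class.items()
    }
    c, k, _total = optimize_sampling_plan(counts)
    rng = np.random.default_rng(seed)
    selected: dict[int, list[str]] = {}
    offsets: dict[str, list[float]] = {}
    rows = []
    for lab in (0, 1):
        eligible = [
            r.speaker_id
            for r, n in zip(by_class[lab], counts[lab])
            if n >= c
        ]
        if len(eligible) == k:
            chosen = list(eligible)
        else:
            chosen = sorted(rng.choice(eligible, size=k, replace=False).tolist())
        selected[lab] = chosen
        for sid in chosen:
            avail = _aligned_offsets(durations[sid], crop.s)
            picked = sorted(
                float(o) for o in rng.choice(avail, size=c, replace=False)
            )
            offsets[sid] = picked
            rows.extend(
                {
                    "speaker_id": sid,
                    "crop_index": j,
                    "offset_s": off,
                    "label": lab,
                    "split": "train",
                }
                for j, off in enumerate(picked)
            )
    plan = SamplingPlan(c, k, selected, offsets, seed)
    manifest = pd.DataFrame(rows, columns=["speaker_id", "crop_index", "offset_s", "label", "split"])
    return plan, manifest


def crop_test_speakers(
    records: list[SpeakerRecord],
    durations: dict[str, float],
    c_cap: int,
    crop: CropSpec = CropSpec(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Crop manifest for evaluation speakers: min(cap, available) crops each.

    No speaker is dropped; speakers longer than cap*s seconds contribute a
    seeded random subset of their aligned offsets, shorter ones all of them.
    """
    if c_cap < 1:
        raise ValidationError("crop cap must be >= 1")
    if seed is None:
        raise ValidationError("a seed is required: crop selection must be reproducible")
    rng = np.random.default_rng(seed)
    rows = []
    for r in records:
        avail = _aligned_offsets(durations[r.speaker_id], crop.s)
        if len(avail) > c_cap:
            picked = sorted(float(o) for o in rng.choice(avail, size=c_cap, replace=False))
        else:
            picked = avail
        rows.extend(
            {
                "speaker_id": r.speaker_id,
                "crop_index": j,
                "offset_s": off,
                "label": r.label,
                "split": r.split,
            }
            for j, off in enumerate(picked)
        )
    return pd.DataFrame(rows, columns=["speaker_id", "crop_index", "offset_s", "label", "split"])


def manifest_durations(recordings: dict[str, AudioRecording]) -> dict[str, float]:
    """Convenience: map speaker id -> recording duration in seconds."""
    return {sid: rec.duration for sid, rec in recordings.items()}
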
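"""Sample-to-speaker aggregation.

A classifier emits one probability per 4-s sample; a speaker's final label is
either the mode of the thresholded sample labels or the thresholded mean of
the sample probabilities.  Both comparisons use >= 0.5 (the boundary maps to
depressed).  An exact mode tie is resolved by a fair coin seeded from
(tie_seed, speaker_id), so outcomes are reproducible yet independent across
speakers.
"""

from __future__ import annotations

import zlib

import numpy as np

from .corpus import ValidationError

THRESHOLD = 0.5


def tie_coin(tie_seed: int, *keys) -> int:
    """Reproducible fair coin: 0 or 1, keyed by the seed plus stable key hashes."""
    hashed = [zlib.crc32(str(k).encode()) for k in keys]
    rng = np.random.default_rng([int(tie_seed) & 0x7FFFFFFF, *hashed])
    return int(rng.integers(2))


def labels_from_probs(p_i, threshold: float = THRESHOLD) -> np.ndarray:
    """Binary sample labels y_{i,l} = 1 iff p_{i,l} >= threshold."""
    p = np.asarray(p_i, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(np.int64)


def speaker_label_mode(y_i, tie_seed: int = 0, speaker_id: str = "") -> int:
    """Most frequent sample label; an exact tie falls to the seeded coin."""
    y = np.asarray(y_i, dtype=np.int64)
    if y.size == 0:
        raise ValidationError("cannot take the mode of zero samples")
    ones = int(y.sum())
    zeros = y.size - ones
    if ones > zeros:
        return 1
    if zeros > ones:
        return 0
    return tie_coin(tie_seed, speaker_id)


def speaker_label_mean_prob(p_i, threshold: float = THRESHOLD) -> int:
    """Threshold the mean sample probability (>= 0.5 means depressed)."""
    p = np.asarray(p_i, dtype=np.float64)
    if p.size == 0:
        raise ValidationError("cannot average zero probabilities")
    return int(p.mean() >= threshold)
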
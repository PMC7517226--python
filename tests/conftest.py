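"""Shared fixtures: toy spectrogram sets and one trained machine pool.

The expensive fixture (`effect1_system`) builds a separable synthetic corpus
once per session — 28 speakers per class (20 train / 8 test), ~48 s
recordings, full class signature — and trains a pool of 16 machines on the
balanced plan at a reduced epoch budget.  Several end-to-end tests share it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

import speechdep as sd

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_specs(rng: np.random.Generator, n: int, f0: int = 33, t0: int = 16) -> np.ndarray:
    """Random normalized spectrogram stacks for model plumbing tests."""
    return rng.random((n, f0, t0), dtype=np.float32)


def features_from_manifest(recordings, manifest, crop_s: float = 4.0):
    """speaker -> (Li, F0, T0) normalized spectrogram stacks from a crop manifest."""
    out = {}
    for sid, grp in manifest.groupby("speaker_id", sort=True):
        offs = grp.sort_values("crop_index")["offset_s"].tolist()
        specs = sd.extract_crop_features(
            recordings[sid].samples, offs, crop_s, speaker_id=sid
        )
        out[sid] = np.stack([s.matrix for s in specs])
    return out


@dataclass
class TrainedSystem:
    """A synthetic corpus plus a pool of machines trained on its balanced plan."""

    records: list
    labels: dict[str, int]
    train_specs: dict[str, np.ndarray]
    test_specs: dict[str, np.ndarray]
    models: list
    table: "object"  # prediction table over the test speakers
    test_truth: dict[str, int]


def build_system(
    effect: float,
    seed: int,
    n_per_class=(28, 28),
    n_test_per_class=(8, 8),
    duration_law=(48.0, 12.0),
    n_machines: int = 16,
    epochs: int = 12,
    machine_seed0: int = 100,
    test_cap: int = 12,
) -> TrainedSystem:
    cfg = sd.SynthConfig(
        n_per_class=n_per_class,
        n_test_per_class=n_test_per_class,
        duration_law=duration_law,
        effect=effect,
        seed=seed,
    )
    records, recordings = sd.synthesize_roster(cfg)
    labels = {r.speaker_id: r.label for r in records}
    durations = {sid: a.duration for sid, a in recordings.items()}
    train = [r for r in records if r.split == "train"]
    test = [r for r in records if r.split == "test"]
    _, train_man = sd.materialize_plan(train, durations, sd.CropSpec(4.0), seed=seed + 1)
    test_man = sd.crop_test_speakers(test, durations, test_cap, seed=seed + 2)
    train_specs = features_from_manifest(recordings, train_man)
    test_specs = features_from_manifest(recordings, test_man)
    order = sorted(train_specs)
    x = np.concatenate([train_specs[s] for s in order])
    y = np.concatenate([np.full(len(train_specs[s]), labels[s]) for s in order])
    cnn_cfg = sd.CnnConfig(epochs=epochs)
    ens_cfg = sd.EnsembleConfig(
        m=n_machines,
        method=1,
        seeds=list(range(machine_seed0, machine_seed0 + n_machines)),
        tie_seed=seed,
    )
    models = sd.train_ensemble(x, y, cnn_cfg, ens_cfg)
    table = sd.predict_table(models, test_specs)
    return TrainedSystem(
        records=records,
        labels=labels,
        train_specs=train_specs,
        test_specs=test_specs,
        models=models,
        table=table,
        test_truth={r.speaker_id: r.label for r in test},
    )


@pytest.fixture(scope="session")
def effect1_system() -> TrainedSystem:
    """Separable corpus with a 16-machine pool (the scaled study conditions)."""
    return build_system(effect=1.0, seed=11)
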
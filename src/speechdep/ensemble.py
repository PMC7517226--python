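"""Ensemble averaging of same-architecture classifiers.

M copies of the 1-D CNN are trained on the same data under different random
initializations; their per-sample outputs for each speaker are fused by one
of three orderings of "average/mode over machines" and "average/mode over
samples":

  Method 1 - average probabilities over machines at sample level, then
             average over the speaker's samples, then threshold at 0.5
             (algebraically the grand mean of all M*L_i probabilities);
  Method 2 - pool the M*L_i hard sample labels and take their mode;
  Method 3 - per-machine speaker mode first, then the mode of the M
             per-machine speaker labels.

Mode ties (possible for even counts) fall to a fair coin seeded from the
ensemble tie seed and the speaker (and machine, where applicable).

The prediction-table substrate is a tidy DataFrame with columns
(machine, speaker_id, sample_index, prob): one row per machine per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import (
    THRESHOLD,
    labels_from_probs,
    speaker_label_mean_prob,
    speaker_label_mode,
    tie_coin,
)
from .cnn import CnnConfig, OneDCnn, build_model, train_model
from .corpus import ValidationError
from .evaluation import per_class_metrics

TABLE_COLUMNS = ["machine", "speaker_id", "sample_index", "prob"]


@dataclass
class EnsembleConfig:
    """Ensemble size, fusion method and per-machine seeds."""

    m: int = 50
    method: int = 1
    seeds: list[int] = field(default_factory=list)
    tie_seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError("ensemble size must be >= 1")
        if self.method not in (1, 2, 3):
            raise ValidationError("fusion method must be 1, 2 or 3")
        if not self.seeds:
            self.seeds = list(range(self.m))
        if len(self.seeds) != self.m:
            raise ValidationError("need exactly one seed per machine")
        if len(set(self.seeds)) != self.m:
            raise ValidationError("machine seeds must be distinct")


def train_ensemble(
    x: np.ndarray,
    y: np.ndarray,
    cnn_config: CnnConfig,
    ensemble_config: EnsembleConfig,
    f0: int | None = None,
    t0: int | None = None,
) -> list[OneDCnn]:
    """Train the M machines on identical data, differing only in their seed."""
    f0 = f0 if f0 is not None else x.shape[1]
    t0 = t0 if t0 is not None else x.shape[2]
    models = []
    for seed in ensemble_config.seeds:
        cfg = CnnConfig(**{**cnn_config.__dict__, "seed": int(seed)})
        model = build_model(cfg, f0, t0)
        train_model(model, x, y, cfg)
        models.append(model)
    return models


def predict_table(
    models: list[OneDCnn], specs_by_speaker: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-machine, per-speaker, per-sample probabilities as a tidy table."""
    rows = []
    for m, model in enumerate(models):
        for sid, stack in specs_by_speaker.items():
            probs = model.predict_proba(stack)
            rows.append(
                pd.DataFrame(
                    {
                        "machine": m,
                        "speaker_id": sid,
                        "sample_index": np.arange(len(probs)),
                        "prob": probs,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def _per_speaker_matrix(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """speaker -> (M, L_i) probability matrix; rejects ragged machine coverage."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"prediction table missing column(s): {missing}")
    machines = np.sort(table["machine"].unique())
    out: dict[str, np.ndarray] = {}
    for sid, grp in table.groupby("speaker_id", sort=True):
        pivot = grp.pivot_table(
            index="machine", columns="sample_index", values="prob", aggfunc="first"
        )
        if pivot.isna().any().any() or len(pivot) != len(machines):
            raise ValidationError(
                f"ragged coverage for speaker {sid!r}: every machine must "
                "score every sample"
            )
        out[str(sid)] = pivot.to_numpy(dtype=np.float64)
    return out


def fuse_method1(table: pd.DataFrame, threshold: float = THRESHOLD) -> dict[str, int]:
    """Probability averaging: grand mean over machines and samples, thresholded."""
    return {
        sid: int(mat.mean() >= threshold)
        for sid, mat in _per_speaker_matrix(table).items()
    }


def fuse_method2(table: pd.DataFrame, tie_seed: int = 0) -> dict[str, int]:
    """Pooled mode of all M*L_i hard sample labels per speaker."""
    out = {}
    for sid, mat in _per_speaker_matrix(table).items():
        pooled = labels_from_probs(mat.reshape(-1))
        out[sid] = speaker_label_mode(pooled, tie_seed, sid)
    return out


def fuse_method3(table: pd.DataFrame, tie_seed: int = 0) -> dict[str, int]:
    """Mode across machines of each machine's own speaker-level mode."""
    out = {}
    for sid, mat in _per_speaker_matrix(table).items():
        machine_labels = [
            speaker_label_mode(labels_from_probs(mat[m]), tie_seed, (sid, "machine", m))
            for m in range(mat.shape[0])
        ]
        out[sid] = speaker_label_mode(np.asarray(machine_labels), tie_seed, (sid, "final"))
    return out


def fuse(table: pd.DataFrame, method: int = 1, tie_seed: int = 0) -> dict[str, int]:
    """Dispatch to one of the three fusion methods."""
    if method == 1:
        return fuse_method1(table)
    if method == 2:
        return fuse_method2(table, tie_seed)
    if method == 3:
        return fuse_method3(table, tie_seed)
    raise ValidationError(f"unknown fusion method {method}")


def single_machine_labels(
    table: pd.DataFrame, machine: int, rule: str = "mean_prob", tie_seed: int = 0
) -> dict[str, int]:
    """Speaker labels from one machine, by either aggregation rule."""
    sub = table[table["machine"] == machine]
    out = {}
    for sid, grp in sub.groupby("speaker_id", sort=True):
        probs = grp.sort_values("sample_index")["prob"].to_numpy()
        if rule == "mean_prob":
            out[str(sid)] = speaker_label_mean_prob(probs)
        elif rule == "mode":
            out[str(sid)] = speaker_label_mode(labels_from_probs(probs), tie_seed, sid)
        else:
            raise ValidationError(f"unknown aggregation rule {rule!r}")
    return out


def f1_vs_m_curve(
    table: pd.DataFrame,
    true_labels: dict[str, int],
    m_grid: list[int],
    n_draws: int = 200,
    seed: int = 0,
    method: int = 1,
    tie_seed: int = 0,
) -> pd.DataFrame:
    """Mean and sd of per-class F1 as the ensemble grows.

    For each M in the grid, ``n_draws`` random M-subsets of the machine pool
    are drawn (without replacement within a draw, with replacement across
    draws), fused, and scored at speaker level.  Returns one row per M with
    mean/sd of each class's F1.
    """
    machines = np.sort(table["machine"].unique())
    pool = len(machines)
    if max(m_grid) > pool:
        raise ValidationError(f"grid asks for M={max(m_grid)} from a pool of {pool}")
    rng = np.random.default_rng(seed)
    speakers = sorted(true_labels)
    y_true = [true_labels[s] for s in speakers]
    rows = []
    for m in m_grid:
        f1_dep, f1_non = [], []
        for _ in range(n_draws):
            subset = rng.choice(machines, size=m, replace=False)
            sub = table[table["machine"].isin(subset)]
            fused = fuse(sub, method, tie_seed)
            y_pred = [fused[s] for s in speakers]
            with warnings.catch_warnings():
                # single weak machines legitimately predict one class only
                warnings.simplefilter("ignore", UserWarning)
                metrics = per_class_metrics(y_true, y_pred)
            f1_dep.append(metrics.f1[1])
            f1_non.append(metrics.f1[0])
        rows.append(
            {
                "m": m,
                "f1_depressed_mean": float(np.mean(f1_dep)),
                "f1_depressed_sd": float(np.std(f1_dep)),
                "f1_nondepressed_mean": float(np.mean(f1_non)),
                "f1_nondepressed_sd": float(np.std(f1_non)),
            }
        )
    return pd.DataFrame(rows)
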
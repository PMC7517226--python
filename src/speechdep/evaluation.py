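"""Speaker-level evaluation: per-class metrics, disjoint CV, comparison arithmetic.

The headline metric is the per-class F1-score at speaker level — the harmonic
mean of that class's precision and recall with the class treated as positive
— reported for the depressed class with the non-depressed value alongside.
Cross-validation is speaker-disjoint and class-stratified: a speaker's crops
never straddle the train/validation boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .corpus import SpeakerRecord, ValidationError


@dataclass
class ClassMetrics:
    """Accuracy plus per-class precision/recall/F1 keyed by class label."""

    accuracy: float
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]

    def row(self) -> dict[str, float]:
        """Flat 'depressed (non-depressed)' layout used in report tables."""
        return {
            "accuracy": self.accuracy,
            "f1_depressed": self.f1[1],
            "f1_nondepressed": self.f1[0],
            "precision_depressed": self.precision[1],
            "precision_nondepressed": self.precision[0],
            "recall_depressed": self.recall[1],
            "recall_nondepressed": self.recall[0],
        }


def per_class_metrics(y_true, y_pred) -> ClassMetrics:
    """Precision, recall, F1 for each class as positive, plus shared accuracy.

    A class with no predicted positives gets precision 0 (and hence F1 0),
    with a warning rather than an error, so degenerate runs stay comparable.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValidationError("label vectors must be equal-length and non-empty")
    for lab in (0, 1):
        if lab not in y_pred and lab in y_true:
            warnings.warn(
                f"no predictions for class {lab}; its precision is reported as 0",
                stacklevel=2,
            )
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0
    )
    return ClassMetrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision={0: float(prec[0]), 1: float(prec[1])},
        recall={0: float(rec[0]), 1: float(rec[1])},
        f1={0: float(f1[0]), 1: float(f1[1])},
    )


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValidationError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def relative_improvement(f1_new: float, f1_ref: float) -> float:
    """Percent F1 change relative to a reference system: 100*(new-ref)/ref."""
    if f1_ref <= 0:
        raise ValidationError("relative improvement undefined for reference F1 <= 0")
    return 100.0 * (f1_new - f1_ref) / f1_ref


def speaker_kfold_split(
    records: list[SpeakerRecord], n_folds: int = 5, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Class-stratified speaker-disjoint folds: (train_ids, held_out_ids) pairs."""
    if n_folds > len(records):
        raise ValidationError(f"{n_folds} folds exceed {len(records)} speakers")
    ids = np.array([r.speaker_id for r in records])
    labels = np.array([r.label for r in records])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        (ids[tr].tolist(), ids[va].tolist()) for tr, va in skf.split(ids, labels)
    ]


def crossval_evaluate(
    train_specs: dict[str, np.ndarray],
    train_labels: dict[str, int],
    test_specs: dict[str, np.ndarray],
    test_labels: dict[str, int],
    cnn_config,
    ensemble_config,
    n_folds: int = 5,
    seed: int = 0,
    pooling: str = "concat",
) -> dict:
    """Speaker-disjoint k-fold training with a fixed evaluation roster.

    Each fold trains the ensemble on its train-subset speakers' samples (the
    held-out fold plays the role of a validation reserve and is simply left
    out) and predicts every test speaker.  By default the per-fold speaker
    prediction lists are concatenated — each test speaker counted once per
    fold — before computing metrics; ``pooling='per_fold'`` instead averages
    the per-fold metric values.
    """
    from .ensemble import fuse, predict_table, train_ensemble  # cycle guard

    if pooling not in ("concat", "per_fold"):
        raise ValidationError(f"unknown pooling {pooling!r}")
    records = [
        SpeakerRecord(sid, 0 if lab == 0 else 10, lab)
        for sid, lab in sorted(train_labels.items())
    ]
    folds = speaker_kfold_split(records, n_folds, seed)
    speakers = sorted(test_labels)
    all_true: list[int] = []
    all_pred: list[int] = []
    fold_metrics = []
    fold_predictions = []
    for fold_idx, (train_ids, _held_out) in enumerate(folds):
        x = np.concatenate([train_specs[sid] for sid in train_ids])
        y = np.concatenate(
            [np.full(len(train_specs[sid]), train_labels[sid]) for sid in train_ids]
        )
        fold_seeds = [
            int(np.random.SeedSequence([seed, fold_idx, m]).generate_state(1)[0] % 2**31)
            for m in range(ensemble_config.m)
        ]
        cfg = type(ensemble_config)(
            m=ensemble_config.m,
            method=ensemble_config.method,
            seeds=fold_seeds,
            tie_seed=ensemble_config.tie_seed,
        )
        models = train_ensemble(x, y, cnn_config, cfg)
        table = predict_table(models, test_specs)
        fused = fuse(table, cfg.method, cfg.tie_seed)
        y_pred = [fused[s] for s in speakers]
        y_true = [test_labels[s] for s in speakers]
        all_true.extend(y_true)
        all_pred.extend(y_pred)
        fold_metrics.append(per_class_metrics(y_true, y_pred))
        fold_predictions.append({s: fused[s] for s in speakers})
    if pooling == "concat":
        metrics = per_class_metrics(all_true, all_pred)
    else:
        rows = [m.row() for m in fold_metrics]
        mean_row = {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}
        metrics = mean_row  # per-fold averaging yields a flat dict
    return {
        "metrics": metrics,
        "fold_metrics": fold_metrics,
        "fold_predictions": fold_predictions,
        "n_folds": n_folds,
        "pooling": pooling,
    }
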
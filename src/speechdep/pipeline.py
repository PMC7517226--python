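"""End-to-end orchestration from a single YAML config with full seed provenance.

Stages: simulate (optional) -> plan -> extract -> train -> fuse -> evaluate.
Every stage writes its outputs under the run directory and is skipped on
re-run when they already exist, so a run is resumable; a cold rerun with the
same config and seed reproduces every manifest byte for byte.  All
stage-level randomness derives deterministically from the one global seed
(derived seeds are logged to seeds.json).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnn import CnnConfig, build_model, load_model, save_model, train_model
from .corpus import (
    FormatError,
    load_participant_audio,
    load_roster,
    load_segments,
)
from .ensemble import EnsembleConfig, fuse, predict_table
from .evaluation import crossval_evaluate, per_class_metrics
from .features import StftParams, extract_crop_features, load_features, save_features
from .sampler import CropSpec, crop_test_speakers, materialize_plan
from .synth import SynthConfig, generate_corpus


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Everything one run needs: paths, geometry, model, ensemble, seed."""

    out_dir: str = "run"
    seed: int = 0
    simulate: dict | None = None
    corpus: dict = field(default_factory=dict)  # audio_dir, labels, segments, exclude
    crop_s: float = 4.0
    test_cap: int = 89
    stft: StftParams = field(default_factory=StftParams)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    cv_folds: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {
            "out_dir", "seed", "simulate", "corpus", "crop", "stft", "cnn",
            "ensemble", "cv",
        }
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        crop = raw.get("crop", {})
        cnn_raw = dict(raw.get("cnn", {}))
        ens_raw = dict(raw.get("ensemble", {}))
        try:
            cfg = cls(
                out_dir=str(raw.get("out_dir", "run")),
                seed=int(raw.get("seed", 0)),
                simulate=raw.get("simulate"),
                corpus=dict(raw.get("corpus", {})),
                crop_s=float(crop.get("s", 4.0)),
                test_cap=int(crop.get("test_cap", 89)),
                stft=StftParams(**raw.get("stft", {})),
                cnn=CnnConfig(**cnn_raw),
                ensemble=EnsembleConfig(**ens_raw),
                cv_folds=int(raw.get("cv", {}).get("n_folds", 0)),
            )
        except (TypeError, ValueError) as exc:
            raise PipelineError(f"config: schema violation: {exc}") from exc
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        """Fail fast — before any compute — on missing inputs."""
        if self.simulate is None:
            labels = self.corpus.get("labels")
            if not labels:
                raise PipelineError("config: corpus.labels is required without simulate")
            if not Path(labels).exists():
                raise PipelineError(f"config: label CSV not found: {labels}")
            audio_dir = self.corpus.get("audio_dir")
            if not audio_dir or not Path(audio_dir).is_dir():
                raise PipelineError(f"config: audio_dir not found: {audio_dir}")

    def derived_seed(self, tag: str) -> int:
        """Deterministic per-stage seed below 2^31, logged for forensics."""
        return int(
            np.random.SeedSequence([self.seed, zlib.crc32(tag.encode())])
            .generate_state(1)[0] % 2**31
        )


def _log_seed(out: Path, tag: str, value: int) -> None:
    path = out / "seeds.json"
    seeds = json.loads(path.read_text()) if path.exists() else {}
    seeds[tag] = value
    path.write_text(json.dumps(seeds, indent=1, sort_keys=True))


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    """Generate a synthetic corpus when the config asks for one."""
    corpus_dir = out / "corpus"
    if cfg.simulate is None:
        return cfg.corpus
    if not (corpus_dir / "labels.csv").exists():
        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.derived_seed("simulate"))
        _log_seed(out, "simulate", sim["seed"])

        def _pair(v):
            return tuple(v) if isinstance(v, (list, tuple)) else int(v)

        synth_cfg = SynthConfig(
            n_per_class=_pair(sim.get("n_per_class", (100, 42))),
            n_test_per_class=_pair(sim.get("n_test_per_class", (0, 0))),
            duration_law=(
                float(sim.get("duration_mean_s", 547.29)),
                float(sim.get("duration_sd_s", 237.58)),
            ),
            effect=float(sim.get("effect", 1.0)),
            seed=int(sim["seed"]),
        )
        generate_corpus(synth_cfg, corpus_dir)
    return {
        "audio_dir": str(corpus_dir / "wav"),
        "labels": str(corpus_dir / "labels.csv"),
        "segments": str(corpus_dir / "segments.csv"),
    }


def _load_recordings(corpus: dict):
    roster = load_roster(corpus["labels"], corpus.get("exclude", ()))
    seg_path = corpus.get("segments")
    annotations = load_segments(seg_path) if seg_path and Path(seg_path).exists() else {}
    audio_dir = Path(corpus["audio_dir"])
    recordings = {}
    for rec in roster:
        wav = audio_dir / f"{rec.speaker_id}.wav"
        if not wav.exists():
            raise PipelineError(f"plan: missing audio for speaker {rec.speaker_id!r}")
        recordings[rec.speaker_id] = load_participant_audio(
            wav, annotations.get(rec.speaker_id), rec.speaker_id
        )
    return roster, recordings


def stage_plan(cfg: PipelineConfig, out: Path, corpus: dict):
    """Balanced train plan + capped test manifest (cached as CSV)."""
    train_csv, test_csv = out / "crops_train.csv", out / "crops_test.csv"
    roster, recordings = _load_recordings(corpus)
    if not (train_csv.exists() and test_csv.exists()):
        durations = {sid: r.duration for sid, r in recordings.items()}
        train = [r for r in roster if r.split == "train"]
        test = [r for r in roster if r.split == "test"]
        plan_seed = cfg.derived_seed("plan")
        _log_seed(out, "plan", plan_seed)
        _plan, manifest = materialize_plan(
            train, durations, CropSpec(cfg.crop_s), seed=plan_seed
        )
        manifest.to_csv(train_csv, index=False)
        if test:
            test_seed = cfg.derived_seed("plan.test")
            _log_seed(out, "plan.test", test_seed)
            crop_test_speakers(
                test, durations, cfg.test_cap, CropSpec(cfg.crop_s), seed=test_seed
            ).to_csv(test_csv, index=False)
        else:
            pd.DataFrame(
                columns=["speaker_id", "crop_index", "offset_s", "label", "split"]
            ).to_csv(test_csv, index=False)
    return roster, recordings, pd.read_csv(train_csv, dtype={"speaker_id": str}), pd.read_csv(
        test_csv, dtype={"speaker_id": str}
    )


def _extract_split(cfg, recordings, manifest):
    specs, offsets = {}, {}
    for sid, grp in manifest.groupby("speaker_id", sort=True):
        offs = grp.sort_values("crop_index")["offset_s"].tolist()
        stack = extract_crop_features(
            recordings[sid].samples, offs, cfg.crop_s,
            recordings[sid].rate, cfg.stft, speaker_id=sid,
        )
        specs[sid] = np.stack([s.matrix for s in stack])
        offsets[sid] = offs
    return specs, offsets


def stage_extract(cfg: PipelineConfig, out: Path, recordings, train_man, test_man):
    """Normalized log-spectrogram containers per split (cached as npz+json)."""
    feats = {}
    for name, man in (("train", train_man), ("test", test_man)):
        path = out / f"features_{name}.npz"
        if path.exists():
            feats[name] = load_features(path)[0]
        elif len(man) == 0:
            feats[name] = {}
        else:
            specs, offsets = _extract_split(cfg, recordings, man)
            save_features(path, specs, offsets, cfg.stft)
            feats[name] = specs
    return feats["train"], feats["test"]


def _machine_seeds(cfg: PipelineConfig, out: Path) -> list[int]:
    seeds = [cfg.derived_seed(f"machine.{m}") for m in range(cfg.ensemble.m)]
    for m, s in enumerate(seeds):
        _log_seed(out, f"machine.{m}", s)
    return seeds


def stage_train(cfg: PipelineConfig, out: Path, train_specs, train_man):
    """Train the M machines (checkpoints + per-machine loss logs, cached)."""
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    labels = dict(
        train_man.drop_duplicates("speaker_id")[["speaker_id", "label"]].itertuples(
            index=False, name=None
        )
    )
    order = sorted(train_specs)
    x = np.concatenate([train_specs[s] for s in order])
    y = np.concatenate([np.full(len(train_specs[s]), labels[s]) for s in order])
    seeds = _machine_seeds(cfg, out)
    models, log_rows = [], []
    for m, seed in enumerate(seeds):
        ckpt = models_dir / f"machine_{m:03d}.npz"
        if ckpt.exists():
            models.append(load_model(ckpt))
            continue
        mcfg = CnnConfig(**{**cfg.cnn.__dict__, "seed": seed})
        model = build_model(mcfg, x.shape[1], x.shape[2])
        try:
            _, history = train_model(model, x, y, mcfg)
        except Exception as exc:
            raise PipelineError(f"train: machine {m} failed: {exc}") from exc
        save_model(ckpt, model)
        log_rows.extend({"machine": m, **h} for h in history)
        models.append(model)
    if log_rows:
        pd.DataFrame(log_rows).to_csv(out / "train_log.csv", index=False)
    return models


def stage_fuse(cfg: PipelineConfig, out: Path, models, test_specs):
    """Per-sample prediction table and fused speaker decisions (cached CSVs)."""
    pred_csv, fused_csv = out / "predictions.csv", out / "fused.csv"
    if fused_csv.exists():
        return pd.read_csv(fused_csv, dtype={"speaker_id": str})
    if not test_specs:
        raise PipelineError("fuse: no test speakers to predict")
    table = predict_table(models, test_specs)
    table.to_csv(pred_csv, index=False)
    tie_seed = cfg.derived_seed("ties")
    _log_seed(out, "ties", tie_seed)
    fused = fuse(table, cfg.ensemble.method, tie_seed)
    rows = [{"speaker_id": sid, "final_label": lab} for sid, lab in sorted(fused.items())]
    if cfg.ensemble.method == 1:
        means = table.groupby("speaker_id")["prob"].mean()
        for row in rows:
            row["mean_probability"] = float(means[row["speaker_id"]])
    df = pd.DataFrame(rows)
    df.to_csv(fused_csv, index=False)
    return df


def stage_evaluate(cfg: PipelineConfig, out: Path, roster, fused: pd.DataFrame) -> dict:
    """Speaker-level metric report in the depressed (non-depressed) layout."""
    metrics_json = out / "metrics.json"
    truth = {r.speaker_id: r.label for r in roster}
    y_true = [truth[sid] for sid in fused["speaker_id"]]
    y_pred = fused["final_label"].tolist()
    metrics = per_class_metrics(y_true, y_pred)
    report = {"n_speakers": len(y_true), **metrics.row()}
    metrics_json.write_text(json.dumps(report, indent=1, sort_keys=True))
    pd.DataFrame([report]).to_csv(out / "metrics.csv", index=False)
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the metric report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.json").write_text(
        json.dumps(
            {
                "seed": cfg.seed,
                "simulate": cfg.simulate,
                "corpus": cfg.corpus,
                "crop": {"s": cfg.crop_s, "test_cap": cfg.test_cap},
                "stft": asdict(cfg.stft),
                "cnn": asdict(cfg.cnn),
                "ensemble": {"m": cfg.ensemble.m, "method": cfg.ensemble.method},
                "cv": {"n_folds": cfg.cv_folds},
            },
            indent=1,
            sort_keys=True,
        )
    )
    try:
        corpus = stage_simulate(cfg, out)
    except Exception as exc:
        raise PipelineError(f"simulate: {exc}") from exc
    roster, recordings, train_man, test_man = stage_plan(cfg, out, corpus)
    train_specs, test_specs = stage_extract(cfg, out, recordings, train_man, test_man)
    if cfg.cv_folds > 1:
        labels = dict(
            train_man.drop_duplicates("speaker_id")[["speaker_id", "label"]].itertuples(
                index=False, name=None
            )
        )
        truth = {r.speaker_id: r.label for r in roster if r.speaker_id in test_specs}
        report = crossval_evaluate(
            train_specs, labels, test_specs, truth,
            cfg.cnn, cfg.ensemble, cfg.cv_folds, cfg.derived_seed("cv"),
        )
        flat = {"n_folds": cfg.cv_folds, **report["metrics"].row()}
        (Path(cfg.out_dir) / "metrics.json").write_text(
            json.dumps(flat, indent=1, sort_keys=True)
        )
        return flat
    models = stage_train(cfg, out, train_specs, train_man)
    fused = stage_fuse(cfg, out, models, test_specs)
    return stage_evaluate(cfg, out, roster, fused)


def run_sweep(
    base: PipelineConfig, param: str, values: list, sweep_dir: str | Path
) -> pd.DataFrame:
    """Re-run the pipeline once per hyperparameter value; one report row each.

    ``param`` is a CnnConfig field name, or the shorthand ``n_and_n4`` which
    sets the conv depth and the hidden dense width together (the two are
    swept jointly in the reference tables).
    """
    sweep_dir = Path(sweep_dir)
    rows = []
    for value in values:
        raw = {**base.cnn.__dict__}
        if param == "n_and_n4":
            raw["n_filters"] = int(value)
            raw["n4"] = int(value)
        elif param in raw:
            raw[param] = type(raw[param])(value)
        else:
            raise PipelineError(f"sweep: unknown hyperparameter {param!r}")
        cfg = PipelineConfig(
            out_dir=str(sweep_dir / f"{param}_{value}"),
            seed=base.seed,
            simulate=base.simulate,
            corpus=base.corpus,
            crop_s=base.crop_s,
            test_cap=base.test_cap,
            stft=base.stft,
            cnn=CnnConfig(**raw),
            ensemble=base.ensemble,
            cv_folds=base.cv_folds,
        )
        report = run_pipeline(cfg)
        rows.append({param: value, **report})
    df = pd.DataFrame(rows)
    df.to_csv(sweep_dir / "sweep.csv", index=False)
    return df
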
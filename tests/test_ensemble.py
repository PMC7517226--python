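"""Fusion methods, their algebraic identities, and ensemble training."""

import numpy as np
import pandas as pd
import pytest

import speechdep as sd
from speechdep.ensemble import single_machine_labels

from conftest import make_specs


def table_from_probs(probs_by_machine: dict[int, dict[str, list[float]]]) -> pd.DataFrame:
    rows = []
    for m, by_speaker in probs_by_machine.items():
        for sid, probs in by_speaker.items():
            for j, p in enumerate(probs):
                rows.append({"machine": m, "speaker_id": sid, "sample_index": j, "prob": p})
    return pd.DataFrame(rows)


def random_table(rng, n_machines=4, n_speakers=3, n_samples=5) -> pd.DataFrame:
    return table_from_probs(
        {
            m: {f"s{i}": rng.random(n_samples).tolist() for i in range(n_speakers)}
            for m in range(n_machines)
        }
    )


def test_method1_worked_example():
    """Sample means [0.4, 0.8] -> speaker mean 0.6 -> depressed."""
    table = table_from_probs({0: {"a": [0.2, 0.8]}, 1: {"a": [0.6, 0.8]}})
    assert sd.fuse_method1(table) == {"a": 1}


def test_method1_equals_grand_mean_threshold():
    rng = np.random.default_rng(0)
    for _ in range(50):
        table = random_table(rng)
        fused = sd.fuse_method1(table)
        grand = table.groupby("speaker_id")["prob"].mean()
        assert fused == {sid: int(gm >= 0.5) for sid, gm in grand.items()}


def test_method1_idempotent_over_identical_machines():
    rng = np.random.default_rng(1)
    probs = {f"s{i}": rng.random(6).tolist() for i in range(3)}
    table = table_from_probs({m: probs for m in range(5)})
    single = {sid: sd.speaker_label_mean_prob(p) for sid, p in probs.items()}
    assert sd.fuse_method1(table) == single


def test_method2_pooled_mode():
    """Pooled labels {1,0,0,1,1,1} have mode 1."""
    table = table_from_probs({0: {"a": [0.9, 0.1, 0.2]}, 1: {"a": [0.8, 0.7, 0.6]}})
    assert sd.fuse_method2(table) == {"a": 1}


def test_method2_unanimity_and_tie():
    unanimous = table_from_probs({0: {"a": [0.1, 0.2]}, 1: {"a": [0.3, 0.4]}})
    assert sd.fuse_method2(unanimous) == {"a": 0}
    tied = table_from_probs({0: {"a": [0.9, 0.1]}, 1: {"a": [0.2, 0.8]}})
    assert sd.fuse_method2(tied, tie_seed=3) == {"a": sd.tie_coin(3, "a")}


def test_method3_mode_of_machine_modes():
    """Machine-level speaker labels [0, 0, 1] give final label 0."""
    table = table_from_probs(
        {
            0: {"a": [0.1, 0.2, 0.3]},
            1: {"a": [0.4, 0.1, 0.9]},
            2: {"a": [0.9, 0.8, 0.7]},
        }
    )
    assert sd.fuse_method3(table) == {"a": 0}


def test_single_machine_reductions():
    """M=1 collapses Method 1 to the mean rule and Methods 2-3 to the mode rule."""
    rng = np.random.default_rng(2)
    probs = {f"s{i}": rng.random(7).tolist() for i in range(4)}
    table = table_from_probs({0: probs})
    mean_rule = single_machine_labels(table, 0, "mean_prob")
    mode_rule = single_machine_labels(table, 0, "mode", tie_seed=9)
    assert sd.fuse_method1(table) == mean_rule
    assert sd.fuse_method2(table, tie_seed=9) == mode_rule
    assert sd.fuse_method3(table, tie_seed=9) == {
        sid: sd.speaker_label_mode(sd.labels_from_probs(p), 9, (sid, "final"))
        for sid, p in probs.items()
    }
    # and methods 2/3 agree with each other at M=1
    assert sd.fuse_method2(table, tie_seed=9).keys() == sd.fuse_method3(table, tie_seed=9).keys()


def test_fusion_invariant_to_machine_reordering():
    rng = np.random.default_rng(3)
    table = random_table(rng)
    relabeled = table.copy()
    relabeled["machine"] = relabeled["machine"].map({0: 2, 1: 3, 2: 0, 3: 1})
    shuffled = relabeled.sample(frac=1.0, random_state=0).reset_index(drop=True)
    for method in (1, 2, 3):
        assert sd.fuse(table, method, 5) == sd.fuse(shuffled, method, 5)


def test_fusion_total_on_random_tables():
    rng = np.random.default_rng(4)
    for _ in range(10):
        table = random_table(rng, n_machines=3, n_speakers=4, n_samples=3)
        for method in (1, 2, 3):
            out = sd.fuse(table, method, 11)
            assert set(out) == {f"s{i}" for i in range(4)}
            assert set(out.values()) <= {0, 1}


def test_ragged_coverage_rejected():
    table = table_from_probs({0: {"a": [0.1, 0.2]}, 1: {"a": [0.3]}})
    with pytest.raises(sd.ValidationError):
        sd.fuse_method1(table)


def test_ensemble_config_validation():
    with pytest.raises(sd.ValidationError):
        sd.EnsembleConfig(m=2, seeds=[1, 1])
    with pytest.raises(sd.ValidationError):
        sd.EnsembleConfig(m=0)
    with pytest.raises(sd.ValidationError):
        sd.EnsembleConfig(m=2, method=4)


def test_trained_machines_differ_only_by_seed():
    rng = np.random.default_rng(5)
    x = make_specs(rng, 24)
    y = rng.integers(0, 2, 24)
    cnn_cfg = sd.CnnConfig(n_filters=8, n4=8, epochs=2, batch=8)
    models = sd.train_ensemble(
        x, y, cnn_cfg, sd.EnsembleConfig(m=2, seeds=[10, 20])
    )
    assert not np.array_equal(models[0].w1, models[1].w1)
    # machine with the same seed reproduces exactly
    again = sd.train_ensemble(x, y, cnn_cfg, sd.EnsembleConfig(m=1, seeds=[10]))
    assert np.array_equal(models[0].w1, again[0].w1)


def test_m1_ensemble_equals_single_model_pipeline():
    rng = np.random.default_rng(6)
    x = make_specs(rng, 16)
    y = rng.integers(0, 2, 16)
    cnn_cfg = sd.CnnConfig(n_filters=8, n4=8, epochs=2, batch=8, seed=33)
    ens = sd.train_ensemble(x, y, cnn_cfg, sd.EnsembleConfig(m=1, seeds=[33]))
    solo, _ = sd.train_model(sd.build_model(cnn_cfg, 33, 16), x, y, cnn_cfg)
    probe = make_specs(rng, 3)
    assert np.allclose(ens[0].predict_proba(probe), solo.predict_proba(probe))


def test_f1_curve_bookkeeping():
    rng = np.random.default_rng(7)
    table = random_table(rng, n_machines=4)
    truth = {f"s{i}": i % 2 for i in range(3)}
    curve = sd.f1_vs_m_curve(table, truth, [1, 4], n_draws=8, seed=0)
    assert curve["m"].tolist() == [1, 4]
    # M == pool size leaves a single subset: zero spread
    assert curve.loc[curve.m == 4, "f1_depressed_sd"].item() == pytest.approx(0.0)
    with pytest.raises(sd.ValidationError):
        sd.f1_vs_m_curve(table, truth, [5], n_draws=2, seed=0)
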
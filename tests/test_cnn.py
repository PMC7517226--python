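"""Model construction, bookkeeping and training behavior of the 1-D CNN."""

import numpy as np
import pytest

import speechdep as sd
from speechdep.cnn import bce_loss, load_model, pooled_length, save_model

from conftest import make_specs


@pytest.mark.parametrize(
    "t0,k,s,p,expected",
    [(125, 5, 4, 4, 32), (8, 3, 2, 2, 4), (60, 1, 1, 0, 60), (7, 7, 7, 0, 1)],
)
def test_pooled_length_same_convention(t0, k, s, p, expected):
    assert pooled_length(t0, k, s, p, mode="same") == expected


def test_pooled_length_explicit_convention():
    """The textbook formula with p=4 keeps one extra frame on the canonical grid."""
    assert pooled_length(125, 5, 4, 4, mode="explicit") == 33


def test_canonical_parameter_counts():
    model = sd.build_model(sd.CnnConfig(), 513, 125)
    counts = model.parameter_counts()
    assert counts["conv"] == 128 * (513 + 1) == 65792
    assert counts["dense"] == 4096 * 128 + 128 == 524416
    assert counts["output"] == 129
    # the weight arrays really hold that many entries
    assert model.w1.size + model.b1.size == counts["conv"]
    assert model.w2.size + model.b2.size == counts["dense"]
    assert model.w3.size + 1 == counts["output"]


def test_flatten_width_follows_pooling():
    cfg = sd.CnnConfig(n_filters=64, pool_k=3, pool_s=2, pool_p=2)
    model = sd.build_model(cfg, 65, 20)
    assert model.t1 == 10
    assert model.w2.shape[0] == cfg.n3(20) == 640


def test_geometry_mismatch_rejected():
    model = sd.build_model(sd.CnnConfig(n_filters=8, n4=8), 33, 16)
    with pytest.raises(sd.ValidationError):
        model.predict_proba(np.zeros((2, 33, 17), dtype=np.float32))


def test_training_is_bit_reproducible():
    """Same seed, same data, single thread: identical final weights."""
    rng = np.random.default_rng(0)
    x = make_specs(rng, 30)
    y = rng.integers(0, 2, 30)
    cfg = sd.CnnConfig(n_filters=8, n4=8, epochs=3, batch=10, seed=5)
    m1, h1 = sd.train_model(sd.build_model(cfg, 33, 16), x, y, cfg)
    m2, h2 = sd.train_model(sd.build_model(cfg, 33, 16), x, y, cfg)
    for k in ("w1", "b1", "w2", "b2", "w3"):
        assert np.array_equal(m1.get_weights()[k], m2.get_weights()[k])
    assert h1 == h2


def test_small_set_memorization():
    """10 samples, 200 epochs: the net drives training loss below 0.1."""
    rng = np.random.default_rng(3)
    x = make_specs(rng, 10)
    y = np.array([0, 1] * 5)
    cfg = sd.CnnConfig(n_filters=8, n4=8, epochs=200, batch=10, seed=1)
    model, history = sd.train_model(sd.build_model(cfg, 33, 16), x, y, cfg)
    assert history[-1]["loss"] < 0.1


def test_loss_trace_decreases_in_smoothed_form():
    rng = np.random.default_rng(4)
    x = make_specs(rng, 20)
    y = rng.integers(0, 2, 20)
    cfg = sd.CnnConfig(n_filters=8, n4=8, epochs=60, batch=10, seed=2)
    _, history = sd.train_model(sd.build_model(cfg, 33, 16), x, y, cfg)
    loss = np.array([h["loss"] for h in history])
    smooth = np.convolve(loss, np.ones(10) / 10, mode="valid")
    assert smooth[-1] < smooth[0]
    assert np.all(np.diff(smooth) < 0.02)  # no sustained rebound


def test_learning_rate_schedule_endpoints():
    cfg = sd.CnnConfig(epochs=50, lr_start=1.0, lr_end=0.01)
    assert cfg.learning_rate(0) == pytest.approx(1.0)
    assert cfg.learning_rate(49) == pytest.approx(0.01)
    mid = cfg.learning_rate(25)
    assert 0.01 < mid < 1.0


def test_predictions_are_probabilities_and_per_sample():
    rng = np.random.default_rng(5)
    model = sd.build_model(sd.CnnConfig(n_filters=8, n4=8, seed=0), 33, 16)
    x = make_specs(rng, 7)
    p = sd.predict_samples(model, x)
    assert p.shape == (7,)
    assert np.all((p >= 0) & (p <= 1))
    # duplicating a sample duplicates its probability
    p_dup = sd.predict_samples(model, np.concatenate([x, x[:1]]))
    assert p_dup[-1] == pytest.approx(p[0])
    # permuting the inputs permutes the outputs identically
    perm = rng.permutation(7)
    assert np.allclose(sd.predict_samples(model, x[perm]), p[perm])


def test_additive_shift_removed_only_by_normalization():
    """Min-max before the model is what makes gain shifts harmless."""
    rng = np.random.default_rng(6)
    model = sd.build_model(sd.CnnConfig(n_filters=8, n4=8, seed=0), 33, 16)
    raw = sd.LogSpectrogram(rng.standard_normal((33, 16)).astype(np.float32))
    shifted = sd.LogSpectrogram(raw.matrix + 2.5)
    direct = model.predict_proba(raw.matrix)[0]
    direct_shifted = model.predict_proba(shifted.matrix)[0]
    assert direct != pytest.approx(direct_shifted, abs=1e-6)
    norm = model.predict_proba(sd.minmax_normalize(raw).matrix)[0]
    norm_shifted = model.predict_proba(sd.minmax_normalize(shifted).matrix)[0]
    assert norm == pytest.approx(norm_shifted, abs=1e-5)


def test_empty_training_set_rejected():
    cfg = sd.CnnConfig(n_filters=8, n4=8)
    model = sd.build_model(cfg, 33, 16)
    with pytest.raises(sd.ValidationError):
        sd.train_model(model, np.zeros((0, 33, 16), dtype=np.float32), np.zeros(0), cfg)


def test_checkpoint_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    cfg = sd.CnnConfig(n_filters=8, n4=8, epochs=2, batch=8, seed=3)
    model, _ = sd.train_model(sd.build_model(cfg, 33, 16), make_specs(rng, 16), rng.integers(0, 2, 16), cfg)
    path = tmp_path / "machine.npz"
    save_model(path, model)
    loaded = load_model(path)
    x = make_specs(rng, 4)
    assert np.allclose(model.predict_proba(x), loaded.predict_proba(x))


def test_bce_loss_matches_definition():
    p = np.array([0.9, 0.1])
    y = np.array([1.0, 0.0])
    assert bce_loss(p, y) == pytest.approx(-np.log(0.9), rel=1e-6)
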
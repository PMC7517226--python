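"""The frequency-spanning 1-D convolutional classifier, in NumPy.

Architecture (for an F0 x T0 log-spectrogram input):

  1. convolution: N filters of size F0 x 1 sliding along time with stride 1
     (each output frame is a linear map of one spectrogram column), ReLU;
  2. max-pooling along time, kernel (1, k), stride (1, s), padding p;
  3. flatten, width n3 = T1 * N where T1 is the pooled frame count;
  4. dense layer of n4 units, ReLU;
  5. dense output unit with sigmoid: the probability that the 4-s sample
     belongs to the depressed class.

Training minimizes binary cross-entropy with Adadelta under a learning-rate
multiplier decaying exponentially across epochs from lr_start to lr_end
(canonically 1 -> 0.01 over 50 epochs, batch 80).  Because the convolution
spans all frequencies and one time slot, the whole forward/backward pass
reduces to dense linear algebra and runs on BLAS; no deep-learning framework
is involved, and a fixed seed makes training bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .corpus import ValidationError


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


def pooled_length(t0: int, k: int, s: int, p: int = 0, mode: str = "same") -> int:
    """Temporal frame count T1 after max-pooling.

    ``mode='same'`` (default): output ceil(t0/s), padding chosen to preserve
    the extremes.  ``mode='explicit'``: textbook floor((t0+2p-k)/s)+1 with p
    zeros on each side.  For the canonical (125, 5, 4, 4) geometry these give
    32 and 33 respectively.
    """
    if t0 <= 0 or k <= 0 or s <= 0 or p < 0:
        raise ValidationError("pooling arguments must be positive (padding >= 0)")
    if mode == "same":
        return -(-t0 // s)  # ceil
    if mode == "explicit":
        return (t0 + 2 * p - k) // s + 1
    raise ValidationError(f"unknown pooling mode {mode!r}")


def _pool_geometry(t0: int, k: int, s: int, p: int, mode: str) -> tuple[int, int, int]:
    """Return (t1, pad_left, pad_right) for the chosen convention."""
    t1 = pooled_length(t0, k, s, p, mode)
    if mode == "same":
        pad_total = max((t1 - 1) * s + k - t0, 0)
        return t1, pad_total // 2, pad_total - pad_total // 2
    return t1, p, p


@dataclass
class CnnConfig:
    """Architecture and training hyperparameters (defaults: the best-found setup)."""

    n_filters: int = 128  # N, conv depth
    pool_k: int = 5  # max-pool kernel length (time)
    pool_s: int = 4  # max-pool stride
    pool_p: int = 4  # max-pool padding (canonically == stride)
    n4: int = 128  # hidden dense width
    epochs: int = 50
    batch: int = 80
    lr_start: float = 1.0
    lr_end: float = 0.01
    seed: int = 0
    pool_mode: str = "same"  # or "explicit"

    def __post_init__(self) -> None:
        for name in ("n_filters", "pool_k", "pool_s", "n4", "epochs", "batch"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.pool_p < 0:
            raise ValidationError("pool_p must be >= 0")

    def t1(self, t0: int) -> int:
        return pooled_length(t0, self.pool_k, self.pool_s, self.pool_p, self.pool_mode)

    def n3(self, t0: int) -> int:
        return self.t1(t0) * self.n_filters

    def learning_rate(self, epoch: int) -> float:
        """Exponential decay from lr_start to lr_end across the epoch schedule."""
        if self.epochs == 1:
            return self.lr_start
        frac = epoch / (self.epochs - 1)
        return self.lr_start * (self.lr_end / self.lr_start) ** frac


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class OneDCnn:
    """The five-layer model with explicit forward/backward passes."""

    def __init__(self, config: CnnConfig, f0: int, t0: int):
        if f0 < 1 or t0 < 1:
            raise ValidationError("input geometry must be positive")
        t1, pl, pr = _pool_geometry(t0, config.pool_k, config.pool_s, config.pool_p, config.pool_mode)
        if t1 < 1:
            raise ValidationError("pooling collapses the temporal axis to nothing")
        self.config = config
        self.f0, self.t0, self.t1 = f0, t0, t1
        self._pad = (pl, pr)
        n, n3, n4 = config.n_filters, t1 * config.n_filters, config.n4
        rng = np.random.default_rng(config.seed)
        self.w1 = _glorot(rng, f0, n, (n, f0))
        self.b1 = np.zeros(n, dtype=np.float32)
        self.w2 = _glorot(rng, n3, n4, (n3, n4))
        self.b2 = np.zeros(n4, dtype=np.float32)
        self.w3 = _glorot(rng, n4, 1, (n4,))
        self.b3 = np.float32(0.0)

    # -- bookkeeping --------------------------------------------------------

    def parameter_counts(self) -> dict[str, int]:
        """Trainable parameters per layer: closed forms of the configuration."""
        n, f0, n4 = self.config.n_filters, self.f0, self.config.n4
        n3 = self.t1 * n
        counts = {
            "conv": n * (f0 + 1),
            "dense": n3 * n4 + n4,
            "output": n4 + 1,
        }
        counts["total"] = sum(counts.values())
        return counts

    def _params(self):
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    def get_weights(self) -> dict[str, np.ndarray]:
        return {
            "w1": self.w1, "b1": self.b1, "w2": self.w2,
            "b2": self.b2, "w3": self.w3, "b3": np.float32(self.b3),
        }

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.w1 = weights["w1"].astype(np.float32)
        self.b1 = weights["b1"].astype(np.float32)
        self.w2 = weights["w2"].astype(np.float32)
        self.b2 = weights["b2"].astype(np.float32)
        self.w3 = weights["w3"].astype(np.float32).reshape(-1)
        self.b3 = np.float32(np.asarray(weights["b3"]).reshape(()))

    # -- forward / backward -------------------------------------------------

    def _check_geometry(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.f0 or x.shape[2] != self.t0:
            raise ValidationError(
                f"input shape {x.shape} incompatible with model geometry "
                f"(F0={self.f0}, T0={self.t0})"
            )
        return x

    def _forward(self, x: np.ndarray, want_cache: bool):
        b = x.shape[0]
        n, t0, t1 = self.config.n_filters, self.t0, self.t1
        k, s = self.config.pool_k, self.config.pool_s
        pl, pr = self._pad
        # conv = per-frame linear map: (N,F0) x (B,F0,T0) -> (B,N,T0)
        z1 = np.tensordot(self.w1, x, axes=([1], [1])).transpose(1, 0, 2)
        z1 += self.b1[None, :, None]
        a1 = np.maximum(z1, 0.0)
        padded = np.full((b, n, pl + t0 + pr), -np.inf, dtype=np.float32)
        padded[:, :, pl : pl + t0] = a1
        starts = s * np.arange(t1)
        windows = padded[:, :, starts[:, None] + np.arange(k)[None, :]]  # (B,N,T1,k)
        arg = windows.argmax(axis=3)
        pooled = np.take_along_axis(windows, arg[..., None], axis=3)[..., 0]
        flat = pooled.reshape(b, -1)
        z2 = flat @ self.w2 + self.b2
        a2 = np.maximum(z2, 0.0)
        z3 = a2 @ self.w3 + self.b3
        prob = 1.0 / (1.0 + np.exp(-z3))
        if not want_cache:
            return prob
        return prob, (x, z1, arg, flat, z2, a2)

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Per-sample depression probabilities, order-preserving."""
        x = self._check_geometry(x)
        return np.concatenate(
            [self._forward(x[i : i + batch], False) for i in range(0, len(x), batch)]
        ).astype(np.float64)

    def _backward(self, prob, y, cache):
        x, z1, arg, flat, z2, a2 = cache
        b = x.shape[0]
        t1, k, s = self.t1, self.config.pool_k, self.config.pool_s
        pl, _ = self._pad
        dz3 = (prob - y).astype(np.float32) / np.float32(b)  # BCE + sigmoid
        gw3 = a2.T @ dz3
        gb3 = dz3.sum()
        dz2 = np.outer(dz3, self.w3)
        dz2[z2 <= 0] = 0.0
        gw2 = flat.T @ dz2
        gb2 = dz2.sum(axis=0)
        dflat = dz2 @ self.w2.T
        dpool = dflat.reshape(b, self.config.n_filters, t1)
        # scatter gradients back through max-pool to the argmax positions
        dpadded = np.zeros((b, self.config.n_filters, pl + self.t0 + (self._pad[1])), dtype=np.float32)
        starts = s * np.arange(t1)
        pos = starts[None, None, :] + arg  # (B,N,T1) absolute padded index
        np.add.at(
            dpadded,
            (
                np.arange(b)[:, None, None],
                np.arange(self.config.n_filters)[None, :, None],
                pos,
            ),
            dpool,
        )
        da1 = dpadded[:, :, pl : pl + self.t0]
        da1[z1 <= 0] = 0.0
        gw1 = np.tensordot(da1, cache[0], axes=([0, 2], [0, 2]))
        gb1 = da1.sum(axis=(0, 2))
        return [gw1, gb1, gw2, gb2, gw3, np.float32(gb3)]


def build_model(config: CnnConfig, f0: int = 513, t0: int = 125) -> OneDCnn:
    """Construct the seeded, untrained model for the given input geometry."""
    return OneDCnn(config, f0, t0)


def bce_loss(prob: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(prob, 1e-7, 1.0 - 1e-7)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


class _Adadelta:
    """Adadelta accumulators (rho=0.95, eps=1e-6) with an external lr multiplier."""

    def __init__(self, params, rho: float = 0.95, eps: float = 1e-6):
        self.rho, self.eps = np.float32(rho), np.float32(eps)
        self.eg = [np.zeros_like(np.asarray(p), dtype=np.float32) for p in params]
        self.ed = [np.zeros_like(np.asarray(p), dtype=np.float32) for p in params]

    def step(self, params, grads, lr: float):
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.eg[i] = self.rho * self.eg[i] + (1 - self.rho) * g * g
            delta = -np.sqrt(self.ed[i] + self.eps) / np.sqrt(self.eg[i] + self.eps) * g
            self.ed[i] = self.rho * self.ed[i] + (1 - self.rho) * delta * delta
            out.append((p + np.float32(lr) * delta).astype(np.float32))
        return out


def train_model(
    model: OneDCnn,
    x: np.ndarray,
    y: np.ndarray,
    config: CnnConfig | None = None,
) -> tuple[OneDCnn, list[dict]]:
    """Train in place on sample spectrograms with binary sample labels.

    Samples inherit their speaker's label.  Returns the model plus a per-epoch
    history of mean loss and learning rate.  Shuffling and any tie-breaking
    derive from the config seed, so a fixed seed reproduces the final weights
    exactly on a single-threaded run.
    """
    cfg = config or model.config
    x = model._check_geometry(x)
    y = np.asarray(y, dtype=np.float32).reshape(-1)
    if x.shape[0] == 0:
        raise ValidationError("empty training set")
    if x.shape[0] != y.shape[0]:
        raise ValidationError("sample/label count mismatch")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    opt = _Adadelta(model._params())
    history: list[dict] = []
    n = x.shape[0]
    for epoch in range(cfg.epochs):
        lr = cfg.learning_rate(epoch)
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch):
            sel = perm[lo : lo + cfg.batch]
            prob, cache = model._forward(x[sel], True)
            losses.append(bce_loss(prob, y[sel]) * len(sel))
            grads = model._backward(prob, y[sel], cache)
            new = opt.step(model._params(), grads, lr)
            model.w1, model.b1, model.w2, model.b2, model.w3, model.b3 = new
        mean_loss = float(np.sum(losses) / n)
        if not np.isfinite(mean_loss):
            raise DivergenceError(epoch)
        history.append({"epoch": epoch, "loss": mean_loss, "lr": lr})
    return model, history


def predict_samples(model: OneDCnn, x_i: np.ndarray) -> np.ndarray:
    """Probabilities p_{i,l} for one speaker's sample stack (L_i, F0, T0)."""
    return model.predict_proba(x_i)


def save_model(path, model: OneDCnn) -> None:
    """Checkpoint: weights plus a config echo (npz, loadable without the class)."""
    import json
    from pathlib import Path

    meta = {"f0": model.f0, "t0": model.t0, "config": asdict(model.config)}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.get_weights())


def load_model(path) -> OneDCnn:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        weights = {k: z[k] for k in ("w1", "b1", "w2", "b2", "w3", "b3")}
    model = OneDCnn(CnnConfig(**meta["config"]), meta["f0"], meta["t0"])
    model.set_weights(weights)
    return model
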
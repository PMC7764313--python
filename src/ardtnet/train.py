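"""Training and scoring.

The optimizer is SGD with momentum 0.9 and weight decay 1e-4 on a weighted
binary cross-entropy; the learning rate starts at 1e-4 and is halved every 30
epochs, with batches of 10 — the schedule used for the full-scale model. All
of it is configurable for desk-scale runs.

Test-time scoring follows the patch protocol: the same multi-scale patch set
used in training is extracted from the test image, every patch is scored, and
the image score is the mean positive-class probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arch import ARDTDenseNet
from .data import DEFAULT_SCALES, ImageRecord, Manifest, augment as _augment, extract_patches

EPS = 1e-7


@dataclass
class TrainConfig:
    batch_size: int = 10
    initial_lr: float = 1e-4
    lr_halving_period: int = 30
    max_epochs: int = 100
    momentum: float = 0.9
    weight_decay: float = 1e-4
    class_weights: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    # patch protocol
    scales: tuple[float, ...] = DEFAULT_SCALES
    per_scale: int = 15
    out_size: int = 224
    augment: bool = True

    def validate(self):
        if self.batch_size < 1 or self.initial_lr <= 0 or self.lr_halving_period < 1:
            raise ValueError("batch_size, initial_lr and lr_halving_period must be positive")
        if min(self.class_weights) <= 0:
            raise ValueError("class weights must be positive")


def weighted_bce(probs, labels, weights=1.0) -> float:
    """Mean weighted binary cross-entropy,
    ``-w_i * (y_i log x_i + (1 - y_i) log(1 - x_i))``, with probabilities
    clamped to (1e-7, 1 - 1e-7)."""
    x = np.clip(np.asarray(probs, dtype=float), EPS, 1 - EPS)
    y = np.asarray(labels, dtype=float)
    w = np.broadcast_to(np.asarray(weights, dtype=float), x.shape)
    return float(np.mean(-w * (y * np.log(x) + (1 - y) * np.log1p(-x))))


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate at a (0-based) epoch: halved every ``lr_halving_period``."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    return cfg.initial_lr * 0.5 ** (epoch // cfg.lr_halving_period)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class EpochLog:
    epoch: int
    lr: float
    loss: float
    train_acc: float


@dataclass
class TrainResult:
    model: ARDTDenseNet
    log: list[EpochLog] = field(default_factory=list)

    def log_rows(self) -> list[dict]:
        return [{"epoch": e.epoch, "lr": e.lr, "loss": e.loss, "train_acc": e.train_acc}
                for e in self.log]


def manifest_to_patches(manifest: Manifest, cfg: TrainConfig, task: int = 1,
                        rng: np.random.Generator | None = None):
    """Extract the training patch set for every record; returns (X, y) with X
    in NCHW float32. Augmentation (when enabled) is applied per patch."""
    rng = rng or np.random.default_rng(cfg.seed)
    xs, ys = [], []
    for rec in manifest.records:
        ps = extract_patches(rec, scales=cfg.scales, per_scale=cfg.per_scale,
                             out_size=cfg.out_size, seed=int(rng.integers(2**31 - 1)))
        for p in ps.patches:
            if cfg.augment:
                p = _augment(p, seed=int(rng.integers(2**31 - 1)))
            xs.append(p.transpose(2, 0, 1))
            ys.append(rec.task1_label if task == 1 else rec.task2_label)
    return np.stack(xs).astype(np.float32), np.asarray(ys, dtype=int)


def train_on_arrays(model: ARDTDenseNet, x: np.ndarray, y: np.ndarray,
                    cfg: TrainConfig) -> TrainResult:
    """Minibatch SGD with momentum on the weighted binary cross-entropy.
    Deterministic under ``cfg.seed`` up to floating-point reduction order."""
    from .layers import SGDMomentum

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    opt = SGDMomentum(model.layers_flat, lr=cfg.initial_lr,
                      momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    n = len(x)
    w_cls = np.asarray(cfg.class_weights, dtype=np.float32)
    logs: list[EpochLog] = []
    for epoch in range(cfg.max_epochs):
        opt.lr = lr_at(epoch, cfg)
        order = rng.permutation(n)
        loss_sum, correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True)
            p = _softmax(logits)
            w = w_cls[yb]
            batch_loss = weighted_bce(p[:, 1], yb, w)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch starting at {start}")
            onehot = np.zeros_like(p)
            onehot[np.arange(len(yb)), yb] = 1.0
            dlogits = (w[:, None] * (p - onehot) / len(yb)).astype(np.float32)
            model.backward(dlogits)
            opt.step()
            loss_sum += batch_loss * len(yb)
            correct += int(((p[:, 1] >= 0.5).astype(int) == yb).sum())
        logs.append(EpochLog(epoch, lr_at(epoch, cfg), loss_sum / n, correct / n))
    return TrainResult(model=model, log=logs)


def train(model: ARDTDenseNet, manifest: Manifest, cfg: TrainConfig,
          task: int = 1) -> TrainResult:
    """End-to-end: extract the patch dataset from a (balanced) manifest and
    fit the model."""
    rng = np.random.default_rng(cfg.seed)
    x, y = manifest_to_patches(manifest, cfg, task=task, rng=rng)
    return train_on_arrays(model, x, y, cfg)


def predict_image(model: ARDTDenseNet, rec: ImageRecord, seed: int = 0,
                  scales=DEFAULT_SCALES, per_scale: int = 15,
                  out_size: int = 224, batch_size: int = 10) -> float:
    """Image-level score: mean positive-class probability over the standard
    multi-scale patch set."""
    ps = extract_patches(rec, scales=scales, per_scale=per_scale,
                         out_size=out_size, seed=seed)
    x = ps.as_array()
    probs = []
    for start in range(0, len(x), batch_size):
        probs.append(model.predict_proba(x[start : start + batch_size])[:, 1])
    return float(np.concatenate(probs).mean())


def score_manifest(model: ARDTDenseNet, manifest: Manifest, seed: int = 0,
                   task: int = 1, **patch_kw) -> tuple[np.ndarray, np.ndarray]:
    """Scores and labels for every record of a manifest."""
    rng = np.random.default_rng(seed)
    scores = np.array([
        predict_image(model, rec, seed=int(rng.integers(2**31 - 1)), **patch_kw)
        for rec in manifest.records
    ])
    return scores, manifest.labels(task)
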
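"""Surrogate-gradient training: Adam, cross-entropy loss, experiment loop.

The loss is the softmax cross-entropy of the per-pixel class evidence
accumulated over the T simulation steps — the same quantity rate
decoding thresholds at inference — averaged over pixels and batch.
Backpropagation substitutes the rectangular surrogate for the spike
derivative (straight-through); every other operation is differentiated
exactly.  All stochasticity (shuffling, per-batch colour jitter,
initialisation done by the caller) flows from ``TrainConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .data import AugmentPolicy, LabeledImage, _jitter, _JITTER_KINDS
from .metrics import evaluate_masks

__all__ = ["TrainConfig", "Adam", "ce_loss", "train", "train_classifier",
           "evaluate", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 1000
    batch_size: int = 8
    seed: int = 0
    shuffle: bool = True
    loss: str = "cross_entropy"
    online_jitter: bool = True  # re-draw one colour jitter per image per batch
    jitter_policy: AugmentPolicy = field(default_factory=AugmentPolicy)

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


class Adam:
    """Adaptive-moment optimizer over a list of parameter tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def ce_loss(pred: np.ndarray, label: np.ndarray) -> float:
    """Cross-entropy of per-pixel class evidence against a binary mask.

    ``pred``: [n_classes, H, W] real evidence (softmax applied over the
    class axis); ``label``: [H, W] in {0, 1}.  Returns the mean over
    pixels of −log p(true class).
    """
    pred = np.asarray(pred, dtype=np.float64)
    label = np.asarray(label)
    if not np.all(np.isin(np.unique(label), (0, 1))):
        raise ValueError("label mask must be binary")
    z = pred - pred.max(axis=0, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=0, keepdims=True))
    return float(-np.take_along_axis(logp, label[None].astype(int), axis=0).mean())


def _batches(n, batch_size, rng, shuffle):
    idx = rng.permutation(n) if shuffle else np.arange(n)
    for s in range(0, n, batch_size):
        yield idx[s:s + batch_size]


def _jitter_batch(images: np.ndarray, cfg: TrainConfig, rng) -> np.ndarray:
    policy = cfg.jitter_policy
    out = images.copy()
    for i in range(len(out)):
        kind = _JITTER_KINDS[rng.integers(0, 4)]
        lo, hi = getattr(policy, kind)
        out[i] = _jitter(out[i], kind, rng.uniform(lo, hi))
    return out


def _check_finite_loss(value: float, epoch: int):
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite training loss {value} at epoch {epoch}; "
            "check learning rate and input scaling")


def evaluate(model, items: list[LabeledImage], batch_size: int = 8):
    """Mean CE loss and pixel metrics of a segmentation model on a dataset."""
    losses = []
    preds, trues = [], []
    for s in range(0, len(items), batch_size):
        chunk = items[s:s + batch_size]
        x = np.stack([it.image for it in chunk])
        y = np.stack([it.mask for it in chunk]).astype(int)
        logits = model.forward(ag.tensor(x))
        evidence = logits.data.sum(axis=0)  # [B, C, H, W]
        for b in range(len(chunk)):
            losses.append(ce_loss(evidence[b], y[b]))
            preds.append(np.argmax(evidence[b], axis=0))
            trues.append(y[b])
    report = evaluate_masks(trues, preds)
    return float(np.mean(losses)), report


def train(model, train_items: list[LabeledImage], cfg: TrainConfig,
          test_items: list[LabeledImage] | None = None,
          target_pa: float | None = None, verbose: bool = False):
    """Train a segmentation network; returns ``(model, history)``.

    ``history`` is a list of per-epoch records with train loss and, when
    a test set is given, test loss and pixel accuracy.  ``target_pa``
    stops training early once the test pixel accuracy reaches it.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history = []
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for batch in _batches(len(train_items), cfg.batch_size, rng, cfg.shuffle):
            x = np.stack([train_items[i].image for i in batch])
            y = np.stack([train_items[i].mask for i in batch]).astype(int)
            if cfg.online_jitter:
                x = _jitter_batch(x, cfg, rng)
            opt.zero_grad()
            logits = model.forward(ag.tensor(x))           # [T, B, C, H, W]
            evidence = _sum_time(logits)                   # [B, C, H, W]
            loss = ag.softmax_cross_entropy(evidence, y, class_axis=-3)
            _check_finite_loss(loss.data, epoch)
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        rec = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if test_items:
            test_loss, report = evaluate(model, test_items, cfg.batch_size)
            rec.update(test_loss=test_loss, test_pa=report.pa,
                       test_miou=report.mean_iou, test_dice=report.dice)
        history.append(rec)
        if verbose:
            print("  ".join(f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                            for k, v in rec.items()), flush=True)
        if target_pa is not None and rec.get("test_pa", 0.0) >= target_pa:
            break
    return model, history


def train_classifier(model, images: np.ndarray, labels: np.ndarray,
                     cfg: TrainConfig, test_images=None, test_labels=None,
                     verbose: bool = False):
    """Train a rate-decoded spiking classifier; returns ``(model, history)``."""
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history = []
    labels = np.asarray(labels, dtype=int)
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for batch in _batches(len(images), cfg.batch_size, rng, cfg.shuffle):
            opt.zero_grad()
            logits = model.forward(ag.tensor(images[batch]))
            loss = ag.softmax_cross_entropy(logits, labels[batch], class_axis=-1)
            _check_finite_loss(loss.data, epoch)
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        rec = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if test_images is not None:
            pred = _predict_batched(model, test_images, cfg.batch_size)
            rec["test_acc"] = float((pred == np.asarray(test_labels)).mean())
        history.append(rec)
        if verbose:
            print("  ".join(f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                            for k, v in rec.items()), flush=True)
    return model, history


def _predict_batched(model, images, batch_size):
    preds = []
    for s in range(0, len(images), batch_size):
        preds.append(model.predict(images[s:s + batch_size]))
    return np.concatenate(preds)


def _sum_time(logits: ag.Tensor) -> ag.Tensor:
    out = logits.data.sum(axis=0)

    def bwd(g):
        ag._accum(logits, np.broadcast_to(g, logits.data.shape))

    return ag.Tensor(out, parents=(logits,), backward_fn=bwd)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model, path, config: dict | None = None) -> None:
    """Single-file archive of all weights with the config embedded."""
    arrays = {f"param_{i:04d}": p.data for i, p in enumerate(model.parameters())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(config or {}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(model, path) -> dict:
    """Load weights into a compatibly-shaped model; returns the stored config."""
    with np.load(path) as data:
        params = model.parameters()
        for i, p in enumerate(params):
            arr = data[f"param_{i:04d}"]
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint parameter {i} has shape {arr.shape}, "
                    f"model expects {p.data.shape}")
            p.data = arr.astype(np.float64)
        cfg = json.loads(bytes(data["config_json"]).decode() or "{}")
    return cfg
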
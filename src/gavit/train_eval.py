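"""Training loop, learning-rate schedule, and evaluation metrics.

Training uses Adam with categorical cross-entropy and a
reduce-on-plateau schedule: when the validation loss has not improved for
``patience`` consecutive epochs the learning rate is multiplied by
``factor`` (never below ``floor``).  Evaluation derives one-vs-rest
TP/TN/FP/FN counts per class from the multi-class confusion matrix and
computes

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the 0/0 cases returned as 0 and the affected classes flagged in the
report.  One run seed fans out to data shuffling, dropout and augmentation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._tensor import Tensor, logsumexp
from .augment import CutMixSpec, RandAugmentSpec, cutmix, randaugment
from .classifier_model import Model

__all__ = [
    "TrainConfig",
    "Adam",
    "ReduceLROnPlateau",
    "EvalCounts",
    "cross_entropy",
    "stratified_split",
    "train",
    "confusion_matrix",
    "counts_from_confusion",
    "accuracy",
    "precision_recall_f1",
    "predict",
    "evaluate",
    "save_report",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    lr_floor: float = 1e-8
    epochs: int = 51
    batch_size: int = 32
    splits: tuple[float, float, float] = (0.8, 0.1, 0.1)
    augment: str = "none"  # "cutmix" | "randaugment" | "none"
    restore_best: bool = True  # keep the best-validation-loss weights
    grad_clip_norm: float | None = 5.0  # global-norm gradient clipping
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.plateau_factor < 1.0):
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError(f"splits must sum to 1, got {self.splits}")
        if self.augment not in ("cutmix", "randaugment", "none"):
            raise ValueError(f"unknown augment mode {self.augment!r}")


class Adam:
    """Adam with bias correction; beta1=0.9, beta2=0.999, eps=1e-8."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class ReduceLROnPlateau:
    """Multiply lr by ``factor`` after ``patience`` epochs without improvement."""

    def __init__(self, optimizer: Adam, factor: float, patience: int,
                 floor: float):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.floor = floor
        self.best = np.inf
        self.wait = 0

    def step(self, metric: float) -> float:
        if metric < self.best:
            self.best = metric
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.floor)
                self.wait = 0
        return self.opt.lr


def cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy; labels may be soft (CutMix)."""
    logp = logits - logsumexp(logits, axis=-1, keepdims=True)
    return -(Tensor(onehot) * logp).sum() * (1.0 / logits.shape[0])


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    return np.eye(num_classes)[np.asarray(labels, dtype=int)]


def stratified_split(labels: np.ndarray, splits: tuple[float, float, float],
                     rng: np.random.Generator):
    """Per-class shuffled index split into (train, val, test)."""
    tr, va, te = [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n = len(idx)
        n_tr = int(round(splits[0] * n))
        n_va = int(round(splits[1] * n))
        tr.extend(idx[:n_tr])
        va.extend(idx[n_tr:n_tr + n_va])
        te.extend(idx[n_tr + n_va:])
    return np.array(tr), np.array(va), np.array(te)


def _eval_loss_acc(model: Model, images: np.ndarray, onehot: np.ndarray,
                   batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for lo in range(0, len(images), batch_size):
        xb = images[lo:lo + batch_size]
        yb = onehot[lo:lo + batch_size]
        logits = model.forward_logits(Tensor(xb), training=False)
        losses.append(cross_entropy(logits, yb).data * len(xb))
        correct += int((logits.data.argmax(1) == yb.argmax(1)).sum())
    return float(np.sum(losses) / len(images)), correct / len(images)


def train(model: Model, train_data, val_data, cfg: TrainConfig):
    """Fit the model; returns ``(model, history)``.

    ``train_data``/``val_data`` are ``(images float (N,H,W,3), labels int)``
    pairs.  History rows record per-epoch training loss, validation loss,
    validation accuracy and the learning rate in force.
    """
    x_tr, y_tr = train_data
    x_va, y_va = val_data
    k = model.cfg.num_classes
    y_tr_oh = one_hot(y_tr, k)
    y_va_oh = one_hot(y_va, k)

    root_rng = np.random.default_rng(cfg.seed)
    shuffle_rng = np.random.default_rng(root_rng.integers(2 ** 31))
    drop_rng = np.random.default_rng(root_rng.integers(2 ** 31))
    aug_rng = np.random.default_rng(root_rng.integers(2 ** 31))

    params = model.parameters()
    opt = Adam(params, cfg.learning_rate)
    sched = ReduceLROnPlateau(opt, cfg.plateau_factor, cfg.plateau_patience,
                              cfg.lr_floor)
    history = []
    best_val, best_state = np.inf, None
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(x_tr))
        epoch_losses = []
        for bi, lo in enumerate(range(0, len(order), cfg.batch_size)):
            sel = order[lo:lo + cfg.batch_size]
            xb, yb = x_tr[sel], y_tr_oh[sel]
            if cfg.augment == "cutmix" and len(sel) >= 2:
                xb, yb = cutmix(xb, yb, CutMixSpec(), rng=aug_rng)
            elif cfg.augment == "randaugment":
                spec = RandAugmentSpec()
                xb = np.stack([randaugment(im, spec, aug_rng) for im in xb])
            logits = model.forward_logits(Tensor(xb), training=True,
                                          rng=drop_rng)
            loss = cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {bi}")
            loss.backward()
            if cfg.grad_clip_norm is not None:
                total = np.sqrt(sum(float((p.grad ** 2).sum())
                                    for p in params.values()
                                    if p.grad is not None))
                if total > cfg.grad_clip_norm:
                    scale = cfg.grad_clip_norm / total
                    for p in params.values():
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            epoch_losses.append(float(loss.data) * len(sel))
        val_loss, val_acc = _eval_loss_acc(model, x_va, y_va_oh, cfg.batch_size)
        if cfg.restore_best and val_loss < best_val:
            best_val = val_loss
            best_state = {k: p.data.copy() for k, p in params.items()}
        lr_now = opt.lr
        sched.step(val_loss)
        history.append({"epoch": epoch,
                        "loss": float(np.sum(epoch_losses) / len(order)),
                        "val_loss": val_loss, "val_accuracy": val_acc,
                        "lr": lr_now})
    if best_state is not None:
        for k, p in params.items():
            p.data[...] = best_state[k]
    return model, history


def save_history(history: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "loss", "val_loss",
                                                "val_accuracy", "lr"])
        writer.writeheader()
        writer.writerows(history)


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class EvalCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     num_classes: int) -> np.ndarray:
    """Rows are true classes, columns predicted classes."""
    m = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(m, (np.asarray(y_true, int), np.asarray(y_pred, int)), 1)
    return m


def counts_from_confusion(m: np.ndarray) -> list[EvalCounts]:
    total = int(m.sum())
    out = []
    for k in range(m.shape[0]):
        tp = int(m[k, k])
        fp = int(m[:, k].sum() - tp)
        fn = int(m[k, :].sum() - tp)
        out.append(EvalCounts(tp=tp, tn=total - tp - fp - fn, fp=fp, fn=fn))
    return out


def accuracy(counts: EvalCounts) -> float:
    if counts.total == 0:
        raise ZeroDivisionError("accuracy undefined for zero samples")
    return (counts.tp + counts.tn) / counts.total


def precision_recall_f1(counts: EvalCounts) -> tuple[float, float, float]:
    """Returns (precision, recall, F1); 0/0 cases yield 0 by convention."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def predict(model: Model, images: np.ndarray,
            batch_size: int = 32) -> np.ndarray:
    probs = []
    for lo in range(0, len(images), batch_size):
        probs.append(model.forward(Tensor(images[lo:lo + batch_size]),
                                   training=False).data)
    return np.concatenate(probs, axis=0)


def evaluate(model: Model, images: np.ndarray, labels: np.ndarray,
             class_names: list[str] | None = None,
             batch_size: int = 32) -> dict:
    """Full evaluation report: confusion matrix and per-class metrics."""
    if len(images) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    k = model.cfg.num_classes
    names = list(class_names) if class_names else [f"class_{i}" for i in range(k)]
    preds = predict(model, images, batch_size).argmax(axis=1)
    m = confusion_matrix(labels, preds, k)
    per_class, degenerate = {}, []
    for c, counts in enumerate(counts_from_confusion(m)):
        p, r, f1 = precision_recall_f1(counts)
        if counts.tp == 0 and (counts.fp == 0 or counts.fn == 0):
            degenerate.append(names[c])
        per_class[names[c]] = {
            "tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn,
            "precision": p, "recall": r, "f1": f1,
            "accuracy": accuracy(counts),
        }
    return {
        "confusion_matrix": m.tolist(),
        "class_names": names,
        "per_class": per_class,
        "overall_accuracy": float(np.trace(m) / m.sum()),
        "degenerate_classes": degenerate,
        "n_samples": int(m.sum()),
    }


def save_report(report: dict, json_path, csv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    if csv_path is not None:
        names = report["class_names"]
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["true\\pred"] + names)
            for name, row in zip(names, report["confusion_matrix"]):
                writer.writerow([name] + row)


def smoke_config(seed: int = 0) -> tuple:
    """Desk-scale study conditions: a tiny 2-stub-block model on 64-px data.

    Returns ``(ModelConfig, TrainConfig, SynthSpec)`` for the end-to-end
    check that the architecture can fit the synthetic 4-class task
    (60 train / 20 val / 20 test per class, lr 1e-3, 30 epochs).
    """
    from .classifier_model import BlockConfig, ModelConfig
    from .component_block import EncoderConfig, PatchEmbedConfig
    from .msfm import FusionConfig
    from .synthetic_data import SynthSpec

    patch = PatchEmbedConfig(patch_size=8, hidden_dim=32, grid_side=24)
    enc = EncoderConfig(num_layers=2, num_heads=2, mlp_dim=64, dropout=0.1)
    model_cfg = ModelConfig(
        blocks=(BlockConfig("stub", patch, enc), BlockConfig("stub", patch, enc)),
        fusion=FusionConfig(branch_width=16),
        head_widths=(128, 32), head_dropout=0.1,
        num_classes=4, image_side=64, seed=seed)
    train_cfg = TrainConfig(learning_rate=1e-3, epochs=30, batch_size=16,
                            splits=(0.6, 0.2, 0.2), seed=seed)
    synth = SynthSpec(n_per_class=100, image_side=64, seed=seed)
    return model_cfg, train_cfg, synth


def run_smoke(seed: int = 0, epochs: int | None = None) -> dict:
    """Generate data, train the smoke model, and return the eval report."""
    from .classifier_model import build_model
    from .synthetic_data import CLASS_NAMES, generate_arrays, to_model_input

    model_cfg, train_cfg, synth = smoke_config(seed)
    if epochs is not None:
        train_cfg = TrainConfig(learning_rate=train_cfg.learning_rate,
                                epochs=epochs, batch_size=train_cfg.batch_size,
                                splits=train_cfg.splits, seed=seed)
    images, labels = generate_arrays(synth)
    x = to_model_input(images)
    rng = np.random.default_rng(seed)
    tr, va, te = stratified_split(labels, train_cfg.splits, rng)
    model = build_model(model_cfg)
    model, history = train(model, (x[tr], labels[tr]), (x[va], labels[va]),
                           train_cfg)
    report = evaluate(model, x[te], labels[te], list(CLASS_NAMES))
    report["history"] = history
    return report
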
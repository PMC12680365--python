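"""Joint classification + quality-assessment objective and training loop.

The objective is

    L_total = L_cls + lambda * L_q

with ``L_cls`` the mean softmax cross-entropy over the batch and ``L_q``
the mean binary cross-entropy between the QA head's confidence q̂ and a
binary target q.  The binary "true quality" is defined here as
prediction correctness — q_i = 1 iff argmax ŷ_i equals the label — the
standard self-supervised confidence target; it is recomputed every
forward pass with no gradient flowing through the argmax, and is
pluggable for users who hold real image-quality annotations.

Optimisation follows the reference recipe: AdamW (lr 5e-5, decoupled
weight decay 0.01), ReduceLROnPlateau on the validation loss (patience
7, min lr 1e-7), early stopping (patience 15), batch size 32, up to 50
epochs, everything seeded (default 42).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import _nn
from .gcnnet import GraphDRModel
from .phantoms import LabeledSample

__all__ = [
    "TrainConfig",
    "LossReport",
    "TrainingDivergedError",
    "quality_loss",
    "total_loss",
    "derive_quality_targets",
    "ReduceLROnPlateau",
    "TrainingLog",
    "TrainResult",
    "train",
]

_EPS = 1e-7


class TrainingDivergedError(RuntimeError):
    """Raised when a non-finite loss appears during optimisation."""


@dataclass
class TrainConfig:
    """Hyperparameters of the tuning pipeline (reference defaults)."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 5e-5
    weight_decay: float = 0.01
    scheduler_patience: int = 7
    scheduler_factor: float = 0.1
    min_lr: float = 1e-7
    early_stop_patience: int = 15
    lam: float = 0.1
    mc_passes: int = 10
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "scheduler_patience", "early_stop_patience", "mc_passes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("learning_rate", "min_lr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.early_stop_patience <= self.scheduler_patience:
            raise ValueError("early_stop_patience must exceed scheduler_patience")


@dataclass
class LossReport:
    """The components of one objective evaluation."""

    l_cls: float
    l_q: float
    lam: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.l_cls) and np.isfinite(self.l_q)):
            raise TrainingDivergedError("non-finite loss component")
        if self.l_cls < 0 or self.l_q < 0 or self.lam < 0:
            raise ValueError("loss components and lambda must be non-negative")

    @property
    def l_total(self) -> float:
        return total_loss(self.l_cls, self.l_q, self.lam)


def quality_loss(q_hat: np.ndarray, q: np.ndarray) -> float:
    """Mean binary cross-entropy  -q log q̂ - (1-q) log(1-q̂).

    Predictions are clamped to [eps, 1-eps] with eps = 1e-7; targets must
    be exactly binary.
    """
    q_hat = np.asarray(q_hat, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if not np.isin(q, (0.0, 1.0)).all():
        raise ValueError("quality targets must be binary (0 or 1)")
    qc = np.clip(q_hat, _EPS, 1.0 - _EPS)
    return float(np.mean(-q * np.log(qc) - (1.0 - q) * np.log(1.0 - qc)))


def total_loss(l_cls: float, l_q: float, lam: float) -> float:
    """L_total = L_cls + lambda * L_q (exact weighted sum)."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if not (np.isfinite(l_cls) and np.isfinite(l_q)):
        raise TrainingDivergedError("non-finite loss component")
    return float(l_cls + lam * l_q)


def derive_quality_targets(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Binary correctness targets: q_i = 1 iff argmax ŷ_i == y_i.

    ``np.argmax`` resolves ties toward the lowest class index.  The
    targets are plain data (no gradient flows through the argmax).
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    return (probs.argmax(axis=1) == labels).astype(np.float64)


QualityTargetPolicy = Callable[[np.ndarray, np.ndarray], np.ndarray]


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after the monitored loss
    fails to improve for more than ``patience`` consecutive epochs; never
    below ``min_lr``."""

    def __init__(self, lr: float, factor: float = 0.1, patience: int = 7, min_lr: float = 1e-7):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, value: float) -> float:
        if value < self.best - 1e-8:
            self.best = value
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
        return self.lr


@dataclass
class TrainingLog:
    """Per-epoch records (each with its per-batch loss trace)."""

    epochs: list[dict] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        cols = ["epoch", "train_loss", "train_cls", "train_q", "val_loss", "lr"]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(cols)
            for rec in self.epochs:
                writer.writerow([rec[c] for c in cols])


@dataclass
class TrainResult:
    model: GraphDRModel
    log: TrainingLog
    best_val_loss: float
    best_epoch: int
    stopped_epoch: int


def _as_arrays(samples: Sequence[LabeledSample]):
    images = np.stack([s.image for s in samples]).astype(np.float64)
    labels = np.array([s.grade for s in samples], dtype=np.int64)
    return images, labels


def _forward_losses(model, images, labels, lam, dropout_rng, policy):
    # GCN dropout (0.2) regularises optimisation; the classifier-head
    # rate (0.3) is the inference dropout of the MC-sampling stage and
    # is not applied while training.
    res = model.forward(images, dropout_rng=dropout_rng, clf_dropout=0.0)
    l_cls, probs, dlogits = _nn.softmax_cross_entropy(res.logits, labels)
    q = policy(probs, labels)
    l_q = quality_loss(res.q_hat, q)
    return res, probs, q, LossReport(l_cls=l_cls, l_q=l_q, lam=lam), dlogits


def evaluate_loss(
    model: GraphDRModel,
    samples: Sequence[LabeledSample],
    lam: float,
    batch_size: int = 32,
    policy: QualityTargetPolicy = derive_quality_targets,
) -> LossReport:
    """Dropout-off loss over a labelled set, batch-graph per mini-batch."""
    images, labels = _as_arrays(samples)
    n = len(samples)
    tot_cls = tot_q = 0.0
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        _, _, _, report, _ = _forward_losses(
            model, images[sl], labels[sl], lam, None, policy
        )
        size = sl.stop - sl.start
        tot_cls += report.l_cls * size
        tot_q += report.l_q * size
    return LossReport(l_cls=tot_cls / n, l_q=tot_q / n, lam=lam)


def train(
    train_samples: Sequence[LabeledSample],
    val_samples: Sequence[LabeledSample],
    model: GraphDRModel,
    config: TrainConfig | None = None,
    quality_policy: QualityTargetPolicy = derive_quality_targets,
) -> TrainResult:
    """Mini-batch training of backbone + GCN + heads under L_total.

    Per epoch: seeded shuffle; per batch: extract features, build the
    batch graph, refine, classify, derive quality targets, backpropagate
    and take one AdamW step.  After each epoch the validation loss is
    evaluated dropout-off, the plateau scheduler steps, the best
    parameters are checkpointed, and early stopping halts after
    ``early_stop_patience`` non-improving epochs.
    """
    config = config or TrainConfig()
    if len(train_samples) == 0 or len(val_samples) == 0:
        raise ValueError("train and validation partitions must be non-empty")
    images, labels = _as_arrays(train_samples)
    n = len(train_samples)

    ss = np.random.SeedSequence(config.seed)
    shuffle_seed, dropout_seed, calib_seed = ss.spawn(3)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    # fix the standardisation scales once, from the training set
    model.calibrate(
        images, config.batch_size, rng=np.random.default_rng(calib_seed)
    )

    optimizer = _nn.AdamW(
        model.params,
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    scheduler = ReduceLROnPlateau(
        lr=config.learning_rate,
        factor=config.scheduler_factor,
        patience=config.scheduler_patience,
        min_lr=config.min_lr,
    )

    log = TrainingLog()
    best_val = np.inf
    best_epoch = -1
    best_params = model.copy_params()
    bad_epochs = 0
    stopped = config.epochs - 1

    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        batch_losses: list[float] = []
        sum_cls = sum_q = 0.0
        for b, start in enumerate(range(0, n, config.batch_size)):
            idx = order[start : start + config.batch_size]
            # fresh seeded substream per batch keeps runs reproducible
            drop_rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=dropout_seed.entropy, spawn_key=(epoch, b)
                )
            )
            try:
                res, probs, q, report, dlogits = _forward_losses(
                    model, images[idx], labels[idx], config.lam, drop_rng, quality_policy
                )
            except TrainingDivergedError as err:
                raise TrainingDivergedError(
                    f"training diverged at epoch {epoch}, batch {b}: {err}"
                ) from err
            dq_logit = None
            if config.lam > 0:
                dq_logit = config.lam * (res.q_hat - q) / len(idx)
            grads = model.backward(res, dlogits, dq_logit)
            for key in model.params:
                grads.setdefault(key, np.zeros_like(model.params[key]))
            optimizer.step(grads)
            batch_losses.append(report.l_total)
            sum_cls += report.l_cls * len(idx)
            sum_q += report.l_q * len(idx)

        val_report = evaluate_loss(
            model, val_samples, config.lam, config.batch_size, quality_policy
        )
        optimizer.lr = scheduler.step(val_report.l_total)
        log.epochs.append(
            {
                "epoch": epoch,
                "train_loss": (sum_cls + config.lam * sum_q) / n,
                "train_cls": sum_cls / n,
                "train_q": sum_q / n,
                "val_loss": val_report.l_total,
                "val_cls": val_report.l_cls,
                "val_q": val_report.l_q,
                "lr": optimizer.lr,
                "batch_losses": batch_losses,
            }
        )
        if val_report.l_total < best_val - 1e-8:
            best_val = val_report.l_total
            best_epoch = epoch
            best_params = model.copy_params()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stop_patience:
                stopped = epoch
                break
        stopped = epoch

    model.set_params(best_params)
    return TrainResult(
        model=model,
        log=log,
        best_val_loss=float(best_val),
        best_epoch=best_epoch,
        stopped_epoch=stopped,
    )
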
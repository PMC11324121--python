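"""Pretraining loop and the downstream fine-tuning protocol.

Pretraining draws a fresh random mask per record each epoch, takes
AdamW steps on the masked-patch reconstruction error under a
warmup-plus-cosine learning-rate schedule, and clips gradients by global
norm.  Fine-tuning minimises binary cross-entropy with Adam under a
plateau schedule: if the monitored validation loss fails to improve for
3 consecutive epochs the learning rate is halved, after 10 consecutive
non-improving epochs training stops, and the weights from the best epoch
are restored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .model import ECGClassifier, MAEModel
from .patching import make_mask_batch

#: published pretraining batch sizes per encoder size
PAPER_PRETRAIN_BATCH = {"base": 1536, "large": 1280, "huge": 768}

#: fine-tuning search grid
FINETUNE_BATCH_GRID = (32, 64, 128, 256)
FINETUNE_LR_GRID = (1e-3, 1e-4, 1e-5, 1e-6)


@dataclass
class PretrainConfig:
    epochs: int = 1600
    batch_size: int = 32
    base_lr: float = 1.5e-4        # scaled by batch_size / 256
    warmup_epochs: int = 40
    weight_decay: float = 0.05
    betas: tuple = (0.9, 0.95)
    clip_norm: float = 1.0
    mask_ratio: float = 0.75
    strategy: str = "random"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")

    @property
    def lr(self) -> float:
        return self.base_lr * self.batch_size / 256.0


@dataclass
class FinetuneConfig:
    batch_size: int = 32
    lr: float = 1e-3
    max_epochs: int = 100
    plateau_patience: int = 3
    lr_factor: float = 0.5
    stop_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.plateau_patience <= 0 or self.stop_patience <= 0:
            raise ValueError("patiences must be positive")
        if self.stop_patience < self.plateau_patience:
            raise ValueError("stop patience must be >= plateau patience")


@dataclass(frozen=True)
class TrainState:
    """Plateau-schedule state; advanced by the pure :func:`scheduler_step`."""

    epoch: int = 0
    best_loss: float = math.inf
    best_epoch: int = -1
    since_improve: int = 0
    lr: float = 1e-3
    improved: bool = False
    stop: bool = False


def scheduler_step(state: TrainState, val_loss: float,
                   plateau_patience: int = 3, lr_factor: float = 0.5,
                   stop_patience: int = 10) -> TrainState:
    """Advance the plateau schedule by one epoch of monitored loss.

    Strict improvement (``< best``) resets the non-improvement counter
    and marks the epoch as the new best (the caller snapshots weights).
    Otherwise the counter increments; at every positive multiple of
    ``plateau_patience`` the rate is multiplied by ``lr_factor``, and at
    ``stop_patience`` the stop flag is set.  A tie is a non-improvement.
    """
    epoch = state.epoch + 1
    if val_loss < state.best_loss:
        return replace(state, epoch=epoch, best_loss=val_loss,
                       best_epoch=epoch, since_improve=0, improved=True,
                       stop=False)
    since = state.since_improve + 1
    lr = state.lr
    if since % plateau_patience == 0:
        lr = lr * lr_factor
    return replace(state, epoch=epoch, since_improve=since, lr=lr,
                   improved=False, stop=since >= stop_patience)


def _cosine_lr(cfg: PretrainConfig, epoch: int) -> float:
    """Linear warmup to ``cfg.lr`` then cosine decay to zero."""
    if cfg.warmup_epochs > 0 and epoch < cfg.warmup_epochs:
        return cfg.lr * (epoch + 1) / cfg.warmup_epochs
    span = max(1, cfg.epochs - cfg.warmup_epochs)
    t = (epoch - cfg.warmup_epochs) / span
    return cfg.lr * 0.5 * (1.0 + math.cos(math.pi * t))


def pretrain(model: MAEModel, patches: np.ndarray, cfg: PretrainConfig
             ) -> list[float]:
    """Pretrain on unlabeled records; returns per-epoch mean losses.

    ``patches`` is the patchified record stack (n_records, 240, 250),
    already normalized.  Fresh seeded masks are drawn per record per
    epoch; reproducible for a fixed ``cfg.seed`` on one device.
    """
    if patches.shape[0] == 0:
        raise ValueError("empty record set")
    patches = np.ascontiguousarray(patches, dtype=nn.DTYPE)
    params = model.params()
    opt = nn.AdamW(params, lr=cfg.lr, betas=cfg.betas,
                   weight_decay=cfg.weight_decay)
    order_rng = np.random.default_rng(cfg.seed)
    n = patches.shape[0]
    history: list[float] = []
    mask_seed = cfg.seed * 100003 + 1
    from .model import mae_loss

    for epoch in range(cfg.epochs):
        opt.lr = _cosine_lr(cfg, epoch)
        order = order_rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = patches[idx]
            visible_idx = make_mask_batch(len(idx), cfg.mask_ratio,
                                          cfg.strategy, mask_seed)
            mask_seed += len(idx)
            maskb = np.ones((len(idx), batch.shape[1]), dtype=bool)
            rows = np.arange(len(idx))[:, None]
            maskb[rows, visible_idx] = False
            pred = model.forward_batch(batch, visible_idx)
            loss, grad = mae_loss(pred, batch, maskb, return_grad=True)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite pretraining loss at epoch {epoch}"
                )
            opt.zero_grad()
            model.backward_batch(grad)
            nn.clip_grad_norm(params, cfg.clip_norm)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def finetune(classifier: ECGClassifier, train_patches: np.ndarray,
             train_labels: np.ndarray, val_patches: np.ndarray,
             val_labels: np.ndarray, cfg: FinetuneConfig
             ) -> tuple[ECGClassifier, dict]:
    """Fine-tune with Adam, plateau halving and early stopping.

    Returns the classifier carrying the best-epoch weights and a history
    dict (train/val losses, learning rates, best epoch).
    """
    if train_patches.shape[0] == 0:
        raise ValueError("empty training set")
    y = np.asarray(train_labels)
    flat = y.reshape(y.shape[0], -1)
    if flat.shape[1] == 1 and len(np.unique(flat)) < 2:
        warnings.warn("training labels contain a single class", stacklevel=2)
    train_patches = np.ascontiguousarray(train_patches, dtype=nn.DTYPE)
    val_patches = np.ascontiguousarray(val_patches, dtype=nn.DTYPE)
    params = classifier.params()
    opt = nn.AdamW(params, lr=cfg.lr, betas=(0.9, 0.999), weight_decay=0.0)
    rng = np.random.default_rng(cfg.seed)
    state = TrainState(lr=cfg.lr)
    best_weights = classifier.copy_values()
    history = {"train_loss": [], "val_loss": [], "lr": [], "best_epoch": -1}
    n = train_patches.shape[0]
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            loss = classifier.bce_loss_and_grad(train_patches[idx],
                                                y[idx])
            if not math.isfinite(loss):
                raise FloatingPointError("non-finite fine-tuning loss")
            opt.step()
            epoch_losses.append(loss)
        val_loss = classifier.bce_loss(val_patches, val_labels)
        state = scheduler_step(state, val_loss,
                               plateau_patience=cfg.plateau_patience,
                               lr_factor=cfg.lr_factor,
                               stop_patience=cfg.stop_patience)
        opt.lr = state.lr
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(state.lr)
        if state.improved:
            best_weights = classifier.copy_values()
            history["best_epoch"] = state.best_epoch
        if state.stop:
            break
    classifier.set_values(best_weights)
    return classifier, history


def finetune_grid(classifier_factory, train_patches, train_labels,
                  val_patches, val_labels,
                  batch_grid=FINETUNE_BATCH_GRID, lr_grid=FINETUNE_LR_GRID,
                  max_epochs: int = 100, seed: int = 0):
    """Sweep the batch-size x learning-rate grid.

    ``classifier_factory()`` must return a freshly initialised classifier
    for each cell.  The winning cell is the one whose best epoch attains
    the lowest validation loss.  Returns ``(classifier, cfg, history)``.
    """
    best = None
    for batch in batch_grid:
        for lr in lr_grid:
            cfg = FinetuneConfig(batch_size=batch, lr=lr,
                                 max_epochs=max_epochs, seed=seed)
            clf, hist = finetune(classifier_factory(), train_patches,
                                 train_labels, val_patches, val_labels, cfg)
            score = min(hist["val_loss"]) if hist["val_loss"] else math.inf
            if best is None or score < best[0]:
                best = (score, clf, cfg, hist)
    return best[1], best[2], best[3]
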
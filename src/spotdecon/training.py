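"""Mini-batch training with validation checkpointing, patience and warm
restarts.

Each epoch shuffles the training spots into mini-batches, takes Adam steps
on the pre-scaling L1 loss, then scores the validation set (same
criterion).  Every strictly lower validation loss checkpoints the current
weights.  The stopping rule counts epochs from the *best* epoch: when
``patience`` epochs pass without improvement, the best weights are loaded
back and training continues (a warm restart) until the restart budget is
exhausted, at which point training stops and the best checkpoint is
restored.  Thus a run with patience P and no restarts ends at
``best_epoch + P``, and its final model always attains the minimum recorded
validation loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import jensen_shannon_divergence, summarize_jsd
from .network import DeconvolutionModel, l1_loss
from .sampler import SpotDataset

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 1024
    max_epochs: int = 500
    patience: int = 100
    warm_restarts: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.warm_restarts < 0:
            raise ValueError("warm_restarts must be >= 0")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    is_best: list[bool] = field(default_factory=list)
    restart_epochs: list[int] = field(default_factory=list)
    best_epoch: int | None = None
    best_val_loss: float | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)

    @property
    def n_restarts(self) -> int:
        return len(self.restart_epochs)

    def to_frame(self):
        import pandas as pd

        restart_id = np.zeros(self.n_epochs, dtype=int)
        for r, e in enumerate(self.restart_epochs, start=1):
            restart_id[e:] = r
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "is_best": self.is_best,
                "restart_id": restart_id,
            }
        )


class EarlyStopping:
    """The patience / warm-restart stopping rule, isolated so it can be
    traced against a scripted loss sequence.

    ``update`` is called once per epoch (1-based) with the validation loss
    and returns one of ``"continue"``, ``"restart"`` or ``"stop"``.
    Improvement means a strictly lower loss than the best seen so far.
    """

    def __init__(self, patience: int, warm_restarts: int = 0):
        self.patience = patience
        self.warm_restarts = warm_restarts
        self.best_loss: float | None = None
        self.best_epoch: int | None = None
        self.restarts_used = 0
        self._epochs_since_best = 0

    def update(self, epoch: int, val_loss: float) -> str:
        if self.best_loss is None or val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self._epochs_since_best = 0
            return "continue"
        self._epochs_since_best += 1
        if self._epochs_since_best < self.patience:
            return "continue"
        if self.restarts_used < self.warm_restarts:
            self.restarts_used += 1
            self._epochs_since_best = 0
            return "restart"
        return "stop"


class Adam:
    """Standard Adam over a ``{name: array}`` parameter dict."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )


def _dataset_loss(model: DeconvolutionModel, dataset: SpotDataset,
                  batch_size: int) -> float:
    """Mean pre-scaling L1 loss over a dataset in evaluation mode."""
    total = 0.0
    n = dataset.n_spots
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        out = model.forward(dataset.profiles[sl], train=False)
        total += l1_loss(out.raw, dataset.proportions[sl]) * (sl.stop - sl.start)
    return total / n


def train(
    model: DeconvolutionModel,
    train_set: SpotDataset,
    val_set: SpotDataset,
    config: TrainingConfig | None = None,
    checkpoint_path=None,
) -> tuple[DeconvolutionModel, TrainingHistory]:
    """Train ``model`` in place; returns it with the best weights restored.

    ``checkpoint_path`` optionally mirrors the in-memory best checkpoint to
    disk every time it improves.
    """
    config = config or TrainingConfig()
    if train_set.n_spots == 0 or val_set.n_spots == 0:
        raise ValueError("train and validation sets must be nonempty")
    if train_set.gene_ids != val_set.gene_ids:
        raise ValueError("train and validation sets disagree on gene order")
    if train_set.label_order != val_set.label_order:
        raise ValueError("train and validation sets disagree on cell types")

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params, lr=config.learning_rate)
    stopper = EarlyStopping(config.patience, config.warm_restarts)
    history = TrainingHistory()
    best_state = model.state_dict()

    n = train_set.n_spots
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        running = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            X = train_set.profiles[idx]
            y = train_set.proportions[idx]
            out, cache = model.forward(X, train=True)
            loss = l1_loss(out.raw, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            grads = model.backward(cache, out.raw, y)
            optimizer.step(model.params, grads)
            running += loss * len(idx)
        train_loss = running / n
        val_loss = _dataset_loss(model, val_set, config.batch_size)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")

        improved = stopper.best_loss is None or val_loss < stopper.best_loss
        action = stopper.update(epoch, val_loss)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.is_best.append(improved)
        if improved:
            best_state = model.state_dict()
            if checkpoint_path is not None:
                model.save(checkpoint_path)
        logger.info(
            "epoch %d: train %.6f val %.6f%s",
            epoch,
            train_loss,
            val_loss,
            " *" if improved else "",
        )
        if action == "restart":
            model.load_state_dict(best_state)
            history.restart_epochs.append(epoch)
            logger.info("warm restart %d at epoch %d", stopper.restarts_used, epoch)
        elif action == "stop":
            break

    model.load_state_dict(best_state)
    history.best_epoch = stopper.best_epoch
    history.best_val_loss = stopper.best_loss
    return model, history


def evaluate(
    model: DeconvolutionModel, test_set: SpotDataset, batch_size: int = 4096
):
    """Per-spot Jensen-Shannon divergences of predictions vs ground truth.

    Returns ``(per_spot, summary)`` where per_spot is an array of base-2
    divergences and summary their mean/SD.
    """
    if model.gene_ids is not None and test_set.gene_ids != model.gene_ids:
        raise ValueError("test set gene order does not match the checkpoint")
    per_spot = np.empty(test_set.n_spots)
    for start in range(0, test_set.n_spots, batch_size):
        sl = slice(start, min(start + batch_size, test_set.n_spots))
        pred = model.predict(test_set.profiles[sl])
        for i in range(pred.shape[0]):
            per_spot[sl.start + i] = jensen_shannon_divergence(
                pred[i], test_set.proportions[sl.start + i]
            )
    return per_spot, summarize_jsd(per_spot)
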
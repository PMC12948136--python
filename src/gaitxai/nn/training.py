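"""Mini-batch training loop with early stopping and best-weight restore.

The loop mirrors the study protocol: Adam, categorical cross-entropy on
one-hot labels, up to ``max_epochs`` (capped at 1000) with early stopping
once the validation loss fails to improve for ``patience`` consecutive
epochs, restoring the best weights on stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, softmax_cross_entropy
from .modules import Module, softmax
from .optim import Adam

__all__ = ["TrainConfig", "TrainingDiverged", "fit", "evaluate_loss"]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 1000
    patience: int = 20
    min_delta: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs > 1000:
            raise ValueError("max_epochs is capped at 1000")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def _take(inputs, idx):
    if isinstance(inputs, dict):
        return {k: v[idx] for k, v in inputs.items()}
    return inputs[idx]


def _n_samples(inputs):
    if isinstance(inputs, dict):
        return len(next(iter(inputs.values())))
    return len(inputs)


def _onehot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes), np.float32)
    out[np.arange(len(y)), y] = 1.0
    return out


def evaluate_loss(model: Module, inputs, y: np.ndarray, n_classes: int,
                  batch_size: int = 64):
    """Mean cross-entropy and accuracy without touching gradients."""
    model.eval()
    n = _n_samples(inputs)
    total, correct = 0.0, 0
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        logits = model(_take(inputs, idx)).data
        p = softmax(logits)
        yy = y[idx]
        total += -np.log(np.clip(p[np.arange(len(idx)), yy], 1e-12, None)).sum()
        correct += int((p.argmax(1) == yy).sum())
    return total / n, correct / n


def fit(model: Module, train_inputs, train_y: np.ndarray,
        val_inputs, val_y: np.ndarray, config: TrainConfig,
        n_classes: int = 4) -> dict:
    """Train ``model`` in place; returns the per-epoch history.

    History keys: ``loss``, ``accuracy``, ``val_loss``, ``val_accuracy``,
    plus ``stopped_epoch`` and ``best_epoch`` (1-based).
    """
    n = _n_samples(train_inputs)
    if n == 0 or _n_samples(val_inputs) == 0:
        raise ValueError("training and validation partitions must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    onehot = _onehot(train_y, n_classes)

    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_loss, best_state, best_epoch, wait = np.inf, None, 0, 0

    for epoch in range(1, config.max_epochs + 1):
        model.train()
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            logits = model(_take(train_inputs, idx))
            loss = softmax_cross_entropy(logits, onehot[idx])
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
            ep_correct += int((logits.data.argmax(1) == train_y[idx]).sum())
        val_loss, val_acc = evaluate_loss(model, val_inputs, val_y, n_classes)
        history["loss"].append(ep_loss / n)
        history["accuracy"].append(ep_correct / n)
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)

        if val_loss < best_loss - config.min_delta:
            best_loss, best_epoch, wait = val_loss, epoch, 0
            best_state = model.state_dict()
        else:
            wait += 1
            if wait >= config.patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    history["stopped_epoch"] = len(history["loss"])
    history["best_epoch"] = best_epoch
    return history
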
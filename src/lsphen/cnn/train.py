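"""Training loop: Adam, MSE loss over the five traits jointly, reduce-on-
plateau learning-rate schedule, best-validation-MSE checkpointing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..exceptions import TrainingDivergedError
from .model import TraitCNN


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (standard desk-scale defaults)."""

    epochs: int = 100
    lr: float = 1e-3
    batch_size: int = 128
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    min_lr: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.lr <= 0 or self.batch_size <= 0:
            raise ValueError("epochs, lr and batch_size must be positive")
        if not (self.min_lr < self.lr):
            raise ValueError("min_lr must be below the initial lr")


class Adam:
    """Adam optimiser over a model's parameter dict."""

    def __init__(self, model: TraitCNN, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer in self.model.parameters():
            name = key[-1]
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self.m.get(key, 0.0)
            v = self.v.get(key, 0.0)
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self.m[key], self.v[key] = m, v
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            layer.params[name] = layer.params[name] - (
                self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(layer.params[name].dtype)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate when the monitored loss stops
    improving for ``patience`` epochs, never going below ``min_lr``."""

    def __init__(self, optimizer: Adam, factor: float, patience: int, min_lr: float):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> bool:
        """Returns True when a reduction was applied this epoch."""
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            new_lr = max(self.optimizer.lr * self.factor, self.min_lr)
            reduced = new_lr < self.optimizer.lr
            self.optimizer.lr = new_lr
            self.bad_epochs = 0
            return reduced
        return False


def mse(estimates: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error (1/n) * ||Yhat - Y||^2 over all traits jointly."""
    diff = estimates - targets
    return float(np.sum(diff * diff) / len(targets))


@dataclass
class TrainResult:
    model: TraitCNN
    log: pd.DataFrame
    best_epoch: int
    best_val_mse: float
    history: list = field(default_factory=list)


def train_model(
    model: TraitCNN,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> TrainResult:
    """Train ``model`` minimising the joint-trait MSE; return the checkpoint
    with the lowest validation MSE.

    Targets are expected z-score normalised.  Fully seeded: batch order comes
    from ``cfg.seed``; dropout noise is seeded at model construction.  A
    non-finite loss aborts with diagnostics of the offending batch.
    """
    x_train, y_train = (np.asarray(a, dtype=np.float32) for a in train)
    x_val, y_val = (np.asarray(a, dtype=np.float32) for a in val)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, lr=cfg.lr)
    sched = ReduceLROnPlateau(
        opt, cfg.scheduler_factor, cfg.scheduler_patience, cfg.min_lr
    )

    best_state = model.clone_state()
    best_val = _eval_mse(model, x_val, y_val, cfg.batch_size)
    best_epoch = 0
    rows = []

    n = len(x_train)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            _, est = model.forward(xb, training=True)
            loss = mse(est, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss {loss} at epoch {epoch}, batch "
                    f"{n_batches} (rows {idx[:5]}...)"
                )
            model.backward(2.0 * (est - yb) / len(yb))
            opt.step()
            epoch_loss += loss
            n_batches += 1

        val_mse = _eval_mse(model, x_val, y_val, cfg.batch_size)
        reduced = sched.step(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_state = model.clone_state()
            best_epoch = epoch
        rows.append(
            {
                "epoch": epoch,
                "train_mse": epoch_loss / max(n_batches, 1),
                "val_mse": val_mse,
                "lr": opt.lr,
                "lr_reduced": reduced,
            }
        )

    model.load_state_dict(best_state)
    return TrainResult(
        model=model,
        log=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_mse=best_val,
    )


def _eval_mse(model: TraitCNN, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    total = 0.0
    for i in range(0, len(x), batch_size):
        _, est = model.forward(x[i : i + batch_size], training=False)
        total += float(np.sum((est - y[i : i + batch_size]) ** 2))
    return total / len(x)
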
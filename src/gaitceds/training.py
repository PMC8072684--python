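"""Training protocol: stratified validation split, Adam, early stopping.

The protocol holds out a fraction of the training data as a validation
set, minimizes softmax cross-entropy with an adaptive-moment optimizer,
and stops when the monitored validation metric has not improved for
``patience`` consecutive epochs, restoring the best epoch's weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn


@dataclass
class TrainConfig:
    """Optimization settings.

    learning_rate 1e-4 and batch_size 512 are the reference protocol;
    val_fraction 0.20 of the training data forms the validation set and
    early stopping uses patience 30 on the monitored metric
    (``val_loss`` by default, ``val_accuracy`` optionally).
    max_epochs bounds the run regardless of patience.
    """

    learning_rate: float = 1e-4
    batch_size: int = 512
    val_fraction: float = 0.20
    patience: int = 30
    max_epochs: int = 500
    seed: int = 0
    monitor: str = "val_loss"

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.monitor not in ("val_loss", "val_accuracy"):
            raise ValueError(f"unknown monitor {self.monitor!r}")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_accuracy: float
    val_loss: float
    val_accuracy: float


@dataclass
class TrainHistory:
    epochs: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0
    best_value: float = float("nan")
    monitor: str = "val_loss"


class EarlyStopping:
    """Patience-based stopping with strict-improvement semantics.

    ``mode`` is ``"min"`` (loss) or ``"max"`` (accuracy).  Any strict
    improvement resets the counter; after ``patience`` consecutive
    epochs without improvement :meth:`update` returns True.
    """

    def __init__(self, patience: int, mode: str = "min"):
        if mode not in ("min", "max"):
            raise ValueError("mode must be 'min' or 'max'")
        self.patience = patience
        self.mode = mode
        self.best_value = np.inf if mode == "min" else -np.inf
        self.best_epoch = 0
        self.wait = 0

    def update(self, value: float, epoch: int) -> bool:
        improved = value < self.best_value if self.mode == "min" else value > self.best_value
        if improved:
            self.best_value = value
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


def split_train_val(
    x: np.ndarray, y: np.ndarray, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split; returns (train_idx, val_idx).

    Per-class validation counts are rounded to the nearest integer but
    kept strictly below the class size; a single-sample class goes to
    the training set with a warning.  Deterministic under ``seed``.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        if idx.size == 1:
            warnings.warn(f"class {label} has a single sample; kept in training set")
            train_idx.append(idx)
            continue
        perm = rng.permutation(idx)
        n_val = int(round(idx.size * val_fraction))
        n_val = min(max(n_val, 1), idx.size - 1)
        val_idx.append(perm[:n_val])
        train_idx.append(perm[n_val:])
    tr = np.sort(np.concatenate(train_idx))
    va = np.sort(np.concatenate(val_idx)) if val_idx else np.array([], dtype=int)
    return tr, va


def _evaluate_loss_acc(net: nn.Network, x, y, batch_size=1024) -> tuple[float, float]:
    logits = net.logits(x, batch_size=batch_size)
    loss, _ = nn.cross_entropy(logits, y)
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def fit(
    net: nn.Network,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    verbose: bool = False,
    log_fn=None,
) -> tuple[nn.Network, TrainHistory]:
    """Train a network in place and return it with its history.

    The returned network carries the weights of the best epoch under the
    monitored validation metric, not the last epoch's.
    """
    x = np.ascontiguousarray(x, dtype=np.float32)
    y = np.asarray(y)
    if x.shape[0] == 0:
        raise ValueError("empty training data")
    head_width = net.children[-1].p["b"].shape[0]
    if y.min() < 0 or y.max() >= head_width:
        raise ValueError(
            f"labels span [{y.min()}, {y.max()}] but the head has {head_width} outputs"
        )
    if x.ndim == 3:
        x = x[..., None]

    tr_idx, va_idx = split_train_val(x, y, cfg.val_fraction, cfg.seed)
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_va, y_va = x[va_idx], y[va_idx]

    optimizer = nn.Adam(net, lr=cfg.learning_rate)
    mode = "min" if cfg.monitor == "val_loss" else "max"
    stopper = EarlyStopping(cfg.patience, mode=mode)
    history = TrainHistory(monitor=cfg.monitor)
    best_weights = net.get_weights()
    rng = np.random.default_rng(cfg.seed + 1)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(x_tr.shape[0])
        losses, correct, seen = [], 0, 0
        for lo in range(0, order.size, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            logits = net.forward(xb, training=True)
            loss, grad = nn.cross_entropy(logits, yb)
            net.backward(grad)
            optimizer.step()
            losses.append(loss * sel.size)
            correct += int((logits.argmax(axis=1) == yb).sum())
            seen += sel.size
        train_loss = float(np.sum(losses) / seen)
        train_acc = correct / seen
        val_loss, val_acc = _evaluate_loss_acc(net, x_va, y_va)
        rec = EpochRecord(epoch, train_loss, train_acc, val_loss, val_acc)
        history.epochs.append(rec)
        if log_fn is not None:
            log_fn(rec)
        elif verbose:
            print(
                f"epoch {epoch:4d}  loss {train_loss:.4f} acc {train_acc:.4f}  "
                f"val_loss {val_loss:.4f} val_acc {val_acc:.4f}"
            )
        monitored = val_loss if cfg.monitor == "val_loss" else val_acc
        stop = stopper.update(monitored, epoch)
        if stopper.best_epoch == epoch:
            best_weights = net.get_weights()
        if stop:
            break

    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = history.epochs[-1].epoch
    history.best_value = float(stopper.best_value)
    net.set_weights(best_weights)
    return net, history
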
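"""Mini-batch training loop for the patch classifier."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..errors import InvalidInputError
from ..image import CLASS_INDEX
from ..patches import LabeledPatch
from .loss import cross_entropy_loss, softmax_cross_entropy_grad
from .network import Network
from .optim import SGD, TrainingConfig
from .layers import softmax

logger = logging.getLogger(__name__)


def patches_to_arrays(patches: list[LabeledPatch]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patches into ``(X, y)`` with raw 0-255 windows and int labels."""
    if not patches:
        raise InvalidInputError("empty patch list")
    x = np.stack([p.window for p in patches]).astype(np.float32)
    if x.ndim == 3:
        x = x[..., None]
    y = np.array([CLASS_INDEX[p.label] for p in patches], dtype=np.int64)
    return x, y


def train(
    model: Network,
    train_patches: list[LabeledPatch],
    val_patches: list[LabeledPatch],
    config: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Train ``model`` in place; returns the per-epoch history.

    The history frame has columns (epoch, lr, train_loss, val_accuracy) and
    is suitable for plotting accuracy against epochs.  Training is
    deterministic given ``config.seed``.  A non-finite loss aborts with
    diagnostics.
    """
    if config is None:
        config = TrainingConfig()
    if not train_patches or not val_patches:
        raise InvalidInputError("training and validation splits must be nonempty")

    x_train, y_train = patches_to_arrays(train_patches)
    x_val, y_val = patches_to_arrays(val_patches)

    # channel statistics from the training split only
    model.input_mean = (x_train.astype(np.float64) / 255.0).mean(axis=(0, 1, 2))
    x_train = model.prepare_input(x_train)
    x_val = model.prepare_input(x_val)

    rng = np.random.default_rng(config.seed)
    model.rng = rng  # dropout shares the training RNG for reproducibility
    optimizer = SGD(model, config)

    history = []
    best_acc, stale = -1.0, 0
    for epoch in range(config.max_epochs):
        lr = config.lr_at_epoch(epoch)
        order = rng.permutation(len(x_train))
        losses = []
        for lo in range(0, len(order), config.train_batch):
            idx = order[lo:lo + config.train_batch]
            logits = model.forward(x_train[idx], train=True)
            probs = softmax(logits.astype(np.float64))
            loss = cross_entropy_loss(probs, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // config.train_batch}: "
                    f"loss={loss}, lr={lr}"
                )
            losses.append(loss)
            dlogits = softmax_cross_entropy_grad(probs, y_train[idx]).astype(np.float32)
            model.backward(dlogits)
            optimizer.step(lr)
        val_acc = _accuracy(model, x_val, y_val, config.eval_batch)
        history.append(
            dict(epoch=epoch, lr=lr, train_loss=float(np.mean(losses)),
                 val_accuracy=val_acc)
        )
        logger.info("epoch %d lr %.4g loss %.4f val_acc %.4f",
                    epoch, lr, history[-1]["train_loss"], val_acc)
        if config.early_stop_patience is not None:
            if val_acc > best_acc + 1e-6:
                best_acc, stale = val_acc, 0
            else:
                stale += 1
                if stale >= config.early_stop_patience:
                    break
    return pd.DataFrame(history)


def _accuracy(model: Network, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    correct = 0
    for lo in range(0, len(x), batch):
        probs = model.predict_proba(x[lo:lo + batch], prepared=True)
        correct += int((probs.argmax(axis=1) == y[lo:lo + batch]).sum())
    return correct / len(x)
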
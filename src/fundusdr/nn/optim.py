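"""Stochastic gradient descent with classical momentum and weight decay.

The update rule is applied literally as

    theta(p+1) = theta(p) - gamma * dL/dtheta + momentum * delta_theta(p)
                 - decay * gamma * theta(p)

where ``delta_theta(p)`` is the previous applied step (classical momentum)
and ``decay`` is the weight-decay rate.  The learning rate follows a
step-down policy: it is multiplied by ``lr_gamma`` every ``step_size``
epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidConfigError, InvalidInputError


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and schedule hyperparameters.

    Defaults follow the conventional recipe for this classifier: learning
    rate 0.01, momentum 0.9, Gaussian weight init std 0.01, batch 128 for
    training and 32 for evaluation, step-down LR with factor 0.1 every 33
    epochs, 43 epochs maximum.  ``weight_decay`` defaults to the customary
    5e-4 companion value.
    """

    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    weight_init_scale: float = 0.01
    train_batch: int = 128
    eval_batch: int = 32
    lr_gamma: float = 0.1
    step_size: int = 33
    max_epochs: int = 43
    seed: int = 0
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if not self.learning_rate >= 0:
            raise InvalidConfigError("learning_rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise InvalidConfigError("momentum must be in [0, 1)")
        if not 0 < self.lr_gamma <= 1:
            raise InvalidConfigError("lr_gamma must be in (0, 1]")
        if self.step_size < 1:
            raise InvalidConfigError("step_size must be >= 1")

    def lr_at_epoch(self, epoch: int) -> float:
        """Effective learning rate at 0-based ``epoch``."""
        return self.learning_rate * self.lr_gamma ** (epoch // self.step_size)


def sgd_update(
    theta: np.ndarray | float,
    gradient: np.ndarray | float,
    lr: float,
    momentum: float = 0.0,
    weight_decay: float = 0.0,
    velocity: np.ndarray | float = 0.0,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """One SGD step; returns ``(new_theta, new_velocity)``.

    ``velocity`` is the previously applied step delta-theta; the returned
    velocity is the step applied now, i.e. ``new_theta - theta``.
    """
    theta_arr = np.asarray(theta, dtype=np.float64)
    grad_arr = np.asarray(gradient, dtype=np.float64)
    if theta_arr.shape != grad_arr.shape:
        raise InvalidInputError(
            f"shape mismatch: theta {theta_arr.shape} vs gradient {grad_arr.shape}"
        )
    vel_arr = np.broadcast_to(np.asarray(velocity, dtype=np.float64), theta_arr.shape)
    step = -lr * grad_arr + momentum * vel_arr - weight_decay * lr * theta_arr
    new_theta = theta_arr + step
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(new_theta), float(step)
    return new_theta, step


class SGD:
    """Stateful optimizer applying :func:`sgd_update` to every parameter."""

    def __init__(self, model, config: TrainingConfig) -> None:
        self.model = model
        self.config = config
        self.velocities = {
            name: np.zeros_like(layer.params[key])
            for name, layer, key in model.parameters()
        }

    def step(self, lr: float) -> None:
        cfg = self.config
        for name, layer, key in self.model.parameters():
            p = layer.params[key]
            g = layer.grads[key]
            v = self.velocities[name]
            step = (-lr * g + cfg.momentum * v - cfg.weight_decay * lr * p).astype(p.dtype)
            p += step
            self.velocities[name] = step
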
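"""The four-block patch classifier.

Architecture: 4 x [conv(16, 3x3, same) -> ReLU -> maxpool(2x2, floor) ->
normalization] -> flatten -> FC(256) -> ReLU -> dropout(0.5) -> FC(4) ->
softmax.  For a 50-px input the feature-map sides after the four pools are
25, 12, 6, 3, so the fully-connected stage sees 3*3*16 = 144 features.

Weights are initialized from a zero-mean Gaussian (std 0.01 by default, the
conventional companion of the SGD hyperparameters used for training);
biases start at zero.  The normalization layer after each pool is batch
normalization by default; across-channel local response normalization is
available as a configuration alternative.  With the small Gaussian init the
useful signal shrinks multiplicatively through the four blocks, and batch
normalization restores its scale after every pool, which is what makes
training converge quickly at these depths; LRN leaves the collapse
untouched (see docs/methods.md).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..errors import InvalidConfigError, InvalidInputError
from ..image import CLASSES
from .layers import (
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    LocalResponseNorm,
    MaxPool2D,
    ReLU,
    softmax,
)


@dataclass(frozen=True)
class NetworkConfig:
    """Shape of the patch classifier."""

    n_conv_blocks: int = 4
    feature_maps: int = 16
    conv_kernel: int = 3
    pool_kernel: int = 2
    fc_units: int = 256
    n_classes: int = 4
    dropout_rate: float = 0.5
    input_side: int = 50
    in_channels: int = 3
    norm: str = "batch"  # "batch" | "lrn" | "none"

    def __post_init__(self) -> None:
        if self.n_classes != 4:
            raise InvalidConfigError("the classifier is four-class by design")
        for name in ("n_conv_blocks", "feature_maps", "fc_units"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        side = self.input_side
        for _ in range(self.n_conv_blocks):
            side //= self.pool_kernel
        if side < 1:
            raise InvalidConfigError(
                f"input_side {self.input_side} too small for "
                f"{self.n_conv_blocks} poolings"
            )
        if self.norm not in ("lrn", "batch", "none"):
            raise InvalidConfigError(f"unknown norm {self.norm!r}")

    @property
    def flat_features(self) -> int:
        side = self.input_side
        for _ in range(self.n_conv_blocks):
            side //= self.pool_kernel
        return side * side * self.feature_maps


class Network:
    """A stack of layers with softmax output over the four patch classes.

    ``input_mean`` holds the training-set per-channel mean of the [0, 1]
    scaled inputs; :meth:`prepare_input` applies the same scaling and
    centering at inference.
    """

    def __init__(self, config: NetworkConfig, layers: list[Layer],
                 rng: np.random.Generator) -> None:
        self.config = config
        self.layers = layers
        self.rng = rng
        self.input_mean = np.zeros(config.in_channels)
        self.n_forward_evals = 0  # windows classified, for cost accounting

    # -- running ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch ``(N, S, S, C)`` of *prepared* inputs."""
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dlogits = layer.backward(dlogits)
        return dlogits

    def prepare_input(self, windows: np.ndarray) -> np.ndarray:
        """Scale raw 0-255 windows to [0, 1] and subtract the channel mean."""
        x = np.asarray(windows, dtype=np.float32) / 255.0
        return x - self.input_mean.astype(np.float32)

    def predict_proba(self, windows: np.ndarray, batch_size: int = 256,
                      prepared: bool = False) -> np.ndarray:
        """Class probabilities for raw windows ``(N, S, S, C)``.

        Dropout is inactive; two calls on the same input are identical.
        """
        windows = np.asarray(windows)
        if windows.ndim == 3:
            windows = windows[None]
        s = self.config.input_side
        if windows.shape[1] != s or windows.shape[2] != s:
            raise InvalidInputError(
                f"patch side {windows.shape[1:3]} does not match input_side {s}"
            )
        x = windows if prepared else self.prepare_input(windows)
        out = np.empty((x.shape[0], self.config.n_classes), dtype=np.float64)
        for lo in range(0, x.shape[0], batch_size):
            logits = self.forward(x[lo:lo + batch_size], train=False)
            out[lo:lo + batch_size] = softmax(logits.astype(np.float64))
        self.n_forward_evals += x.shape[0]
        return out

    # -- parameter access ------------------------------------------------
    def parameters(self) -> list[tuple[str, Layer, str]]:
        """(unique name, layer, param key) for every trainable array."""
        out = []
        for i, layer in enumerate(self.layers):
            for key in layer.params:
                out.append((f"layer{i}.{key}", layer, key))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: layer.params[key] for name, layer, key in self.parameters()}
        state["input_mean"] = self.input_mean
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.parameters():
            layer.params[key][...] = state[name]
        self.input_mean = np.asarray(state["input_mean"], dtype=np.float64)
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"layer{i}.running_mean"])
                layer.running_var = np.asarray(state[f"layer{i}.running_var"])

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameters + config, .npz format."""
        payload = {k: np.asarray(v) for k, v in self.state_dict().items()}
        payload["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        buf = io.BytesIO()
        np.savez(buf, **payload)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "Network":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg = NetworkConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = build_network(cfg, seed=seed)
            model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model


def build_network(config: NetworkConfig | None = None, init_std: float = 0.01,
                  seed: int = 0, dtype=np.float32) -> Network:
    """Construct the classifier with Gaussian(0, ``init_std``) weights.

    Raises :class:`InvalidConfigError` when ``input_side`` cannot survive the
    configured number of poolings (< 16 px for the default four blocks).
    """
    if config is None:
        config = NetworkConfig()
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    in_ch = config.in_channels
    for block in range(config.n_conv_blocks):
        conv = Conv2D(in_ch, config.feature_maps, config.conv_kernel,
                      needs_input_grad=block > 0)
        conv.params["W"] = rng.normal(
            0.0, init_std, conv.params["W"].shape
        ).astype(dtype)
        conv.params["b"] = conv.params["b"].astype(dtype)
        conv.grads = {k: np.zeros_like(v) for k, v in conv.params.items()}
        layers.append(conv)
        layers.append(ReLU())
        layers.append(MaxPool2D(config.pool_kernel))
        if config.norm == "lrn":
            layers.append(LocalResponseNorm())
        elif config.norm == "batch":
            bn = BatchNorm(config.feature_maps)
            bn.params = {k: v.astype(dtype) for k, v in bn.params.items()}
            bn.grads = {k: np.zeros_like(v) for k, v in bn.params.items()}
            layers.append(bn)
        in_ch = config.feature_maps
    layers.append(Flatten())
    fc1 = Dense(config.flat_features, config.fc_units)
    fc1.params["W"] = rng.normal(0.0, init_std, fc1.params["W"].shape).astype(dtype)
    fc1.params["b"] = fc1.params["b"].astype(dtype)
    fc1.grads = {k: np.zeros_like(v) for k, v in fc1.params.items()}
    layers.append(fc1)
    layers.append(ReLU())
    layers.append(Dropout(config.dropout_rate, rng=rng))
    fc2 = Dense(config.fc_units, config.n_classes)
    fc2.params["W"] = rng.normal(0.0, init_std, fc2.params["W"].shape).astype(dtype)
    fc2.params["b"] = fc2.params["b"].astype(dtype)
    fc2.grads = {k: np.zeros_like(v) for k, v in fc2.params.items()}
    layers.append(fc2)
    return Network(config, layers, rng)


def predict_patch(model: Network, patch: np.ndarray) -> np.ndarray:
    """Probability 4-vector (exudate, hemorrhage, microaneurysm, no-sign).

    Accepts one raw ``(S, S, C)`` window; dropout is inactive.
    """
    probs = model.predict_proba(patch[None] if patch.ndim == 3 else patch)
    return probs[0]


CLASS_NAMES = CLASSES
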
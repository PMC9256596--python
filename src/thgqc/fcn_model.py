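"""The 6-block fully-convolutional binary classifier.

Blocks 1-4: 5x5 convolution -> batch normalization -> ReLU -> 2x2 max
pooling, with 32, 64, 128 and 256 channels. Block 5: 1x1 convolution with
64 channels -> batch normalization -> ReLU. Block 6: 1x1 convolution with
1 channel followed by global average pooling; a sigmoid squashes the
pooled logit into a score in (0, 1). Every convolution kernel is
L2-regularized (factor 0.01) and initialized with He uniform variance
scaling. There are no dense layers, so the model accepts any input of at
least 16x16 pixels (four pooling stages) and emits one score per image —
the property that lets one network classify single shots, stack slices and
sliding windows of arbitrary size alike.

Default configuration parameter count (convolution weights + biases):
832 + 51,264 + 204,928 + 819,456 + 16,448 + 65 = 1,092,993.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from thgqc.nn import (
    BatchNorm2D,
    Conv2D,
    GlobalAvgPool,
    Layer,
    MaxPool2x2,
    ReLU,
    sigmoid,
)


class InputSizeError(ValueError):
    """Raised for inputs below the architecture's minimum spatial size."""


@dataclass(frozen=True)
class FCNConfig:
    """Architecture hyperparameters of the classifier."""

    block_channels: tuple[int, ...] = (32, 64, 128, 256)
    conv_kernel: int = 5
    pool: int = 2
    head_channels: int = 64
    l2_factor: float = 0.01
    input_channels: int = 1
    #: decay of the batch-norm running statistics; lower values let the
    #: inference statistics converge within few optimizer steps, which
    #: matters for short desk-scale runs
    bn_momentum: float = 0.9

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.block_channels) or self.head_channels <= 0:
            raise ValueError("channel counts must be positive")
        if self.conv_kernel % 2 != 1:
            raise ValueError("conv_kernel must be odd")

    @property
    def min_input_side(self) -> int:
        """Smallest usable input side: one pixel must survive all poolings."""
        return self.pool ** len(self.block_channels)


class FCNClassifier:
    """Trained-parameter container with forward/backward passes.

    Use :func:`build_fcn` to construct one. ``forward_logits`` runs in
    training mode (batch statistics, caches for backprop);
    ``predict_scores`` runs per-image in inference mode (running
    statistics, no padding).
    """

    def __init__(self, config: FCNConfig, seed: int, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        k = config.conv_kernel
        l2 = config.l2_factor
        layers: list[Layer] = []
        cin = config.input_channels
        for cout in config.block_channels:
            layers += [
                Conv2D(cin, cout, k, rng, dtype=dtype, l2=l2),
                BatchNorm2D(cout, dtype=dtype, momentum=config.bn_momentum),
                ReLU(),
                MaxPool2x2(),
            ]
            cin = cout
        layers += [
            Conv2D(cin, config.head_channels, 1, rng, dtype=dtype, l2=l2),
            BatchNorm2D(config.head_channels, dtype=dtype,
                        momentum=config.bn_momentum),
            ReLU(),
            Conv2D(config.head_channels, 1, 1, rng, dtype=dtype, l2=l2),
            GlobalAvgPool(),
        ]
        self.layers = layers

    # -- introspection ----------------------------------------------------
    @property
    def conv_layers(self) -> list[Conv2D]:
        return [l for l in self.layers if isinstance(l, Conv2D)]

    @property
    def parameter_count(self) -> int:
        """Convolution weight + bias parameters (batch-norm excluded)."""
        return sum(l.params["w"].size + l.params["b"].size
                   for l in self.conv_layers)

    def l2_penalty(self) -> float:
        return sum(l.l2_penalty() for l in self.conv_layers)

    # -- passes ------------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        m = self.config.min_input_side
        if x.shape[1] < m or x.shape[2] < m:
            raise InputSizeError(
                f"input {x.shape[1]}x{x.shape[2]} below the minimum "
                f"side of {m} px required by "
                f"{len(self.config.block_channels)} pooling stages"
            )

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Batch (B, H, W) or (B, H, W, 1) in [0,1] -> pre-sigmoid logits (B,)."""
        if x.ndim == 3:
            x = x[..., None]
        self._check_input(x)
        out = x.astype(self.dtype)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dout = dlogits[:, None].astype(self.dtype)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def predict_scores(self, images: Sequence[np.ndarray],
                       batch_size: int = 32) -> np.ndarray:
        """Sigmoid scores in [0,1], one per image; unpadded inference.

        Images may have different sizes; same-shaped images are batched
        for speed, which cannot change any score (inference mode uses
        running batch-norm statistics, so each image's score is
        independent of batch composition), and no image is ever padded.
        """
        arrays = []
        for img in images:
            arr = np.asarray(img)
            if arr.ndim != 2:
                raise ValueError("each image must be 2-D")
            arrays.append(arr)
        scores = np.empty(len(arrays))
        by_shape: dict[tuple[int, int], list[int]] = {}
        for i, arr in enumerate(arrays):
            by_shape.setdefault(arr.shape, []).append(i)
        for idx in by_shape.values():
            for start in range(0, len(idx), batch_size):
                chunk = idx[start:start + batch_size]
                z = self.forward_logits(
                    np.stack([arrays[i] for i in chunk]), train=False
                )
                scores[chunk] = sigmoid(z)
        return scores

    # -- (de)serialization -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.params.items():
                state[f"layer{i}:{key}"] = val
            if isinstance(layer, BatchNorm2D):
                state[f"layer{i}:running_mean"] = layer.running_mean
                state[f"layer{i}:running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for key in layer.params:
                layer.params[key][...] = state[f"layer{i}:{key}"]
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = state[f"layer{i}:running_mean"].copy()
                layer.running_var = state[f"layer{i}:running_var"].copy()

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def save(self, path) -> None:
        """Single-file checkpoint with the config embedded."""
        cfg = self.config
        np.savez_compressed(
            str(path),
            __config__=np.array([
                list(cfg.block_channels), [cfg.conv_kernel], [cfg.pool],
                [cfg.head_channels], [cfg.l2_factor], [cfg.input_channels],
                [cfg.bn_momentum],
            ], dtype=object),
            **self.state_arrays(),
        )

    @classmethod
    def load(cls, path) -> "FCNClassifier":
        with np.load(str(path), allow_pickle=True) as data:
            raw = data["__config__"]
            cfg = FCNConfig(
                block_channels=tuple(int(c) for c in raw[0]),
                conv_kernel=int(raw[1][0]),
                pool=int(raw[2][0]),
                head_channels=int(raw[3][0]),
                l2_factor=float(raw[4][0]),
                input_channels=int(raw[5][0]),
                bn_momentum=float(raw[6][0]),
            )
            model = cls(cfg, seed=0)
            model.load_state_arrays(
                {k: data[k] for k in data.files if k != "__config__"}
            )
        return model


def build_fcn(config: FCNConfig = FCNConfig(), seed: int = 0,
              dtype=np.float32) -> FCNClassifier:
    """Instantiate the classifier with deterministically seeded weights."""
    return FCNClassifier(config, seed=seed, dtype=dtype)


def predict_scores(model: FCNClassifier,
                   images: Sequence[np.ndarray]) -> np.ndarray:
    """Module-level convenience wrapper around the model method."""
    return model.predict_scores(images)


def describe(model: FCNClassifier) -> str:
    """Human-readable architecture summary (used by the CLI)."""
    cfg = model.config
    lines = [f"FCN binary classifier ({model.parameter_count:,} conv parameters)"]
    cin = cfg.input_channels
    for i, cout in enumerate(cfg.block_channels, start=1):
        lines.append(
            f"  block {i}: {cfg.conv_kernel}x{cfg.conv_kernel} conv "
            f"{cin}->{cout}, batch norm, ReLU, {cfg.pool}x{cfg.pool} max pool"
        )
        cin = cout
    lines.append(f"  block 5: 1x1 conv {cin}->{cfg.head_channels}, "
                 "batch norm, ReLU")
    lines.append(f"  block 6: 1x1 conv {cfg.head_channels}->1, "
                 "global average pool, sigmoid")
    lines.append(f"  minimum input side: {cfg.min_input_side} px; "
                 f"L2 factor {cfg.l2_factor} on conv kernels")
    return "\n".join(lines)
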
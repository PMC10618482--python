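"""The convolutional feature extractor: 15 conv layers, 5 max-pools, 1024 channels.

The network is a VGG-style encoder: a 32-channel stem convolution followed
by five blocks of widths 64, 128, 256, 512 and 1024 (i.e. 32·2ⁿ for
n = 1..5) with 2, 3, 3, 3, 3 convolutions each — 15 convolutions in total,
every one 3x3 / stride 1 / ReLU.  A max-pool follows each block; the first
four have stride 2 and the fifth stride 1 with same padding, so the total
spatial reduction is 16 and a 2048x1664x3 input yields a 128x104x1024
feature stack.  The stride-1 fifth pool reconciles the five-pool layer
count with the /16 output geometry.

Training attaches an auxiliary 1x1-convolution softmax head (8 classes) at
the 1/16 grid and minimizes pixel-wise cross-entropy against blockwise-
majority downsampled masks (label 0 excluded).  Weights are checkpointed
only when the validation loss improves on the best value seen so far; the
head is discarded at feature-extraction time.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Conv, MaxPool2, MaxPool2Same, ReLU
from .errors import ConfigurationError
from .image import AnnotatedImage
from .labels import N_CLASSES
from .preprocess import DOWNSAMPLE_FACTOR, downsample_mask

__all__ = [
    "CNNConfig",
    "FeatureStack",
    "TrainingHistory",
    "FeatureExtractor",
    "build_feature_extractor",
    "train_feature_extractor",
    "extract_features",
    "infer_feature_shape",
]


@dataclass(frozen=True)
class CNNConfig:
    stem_channels: int = 32
    block_channels: tuple[int, ...] = (64, 128, 256, 512, 1024)
    convs_per_block: tuple[int, ...] = (2, 3, 3, 3, 3)
    kernel_size: int = 3
    stride: int = 1
    pool_strides: tuple[int, ...] = (2, 2, 2, 2, 1)
    head_classes: int = N_CLASSES
    learning_rate: float = 1e-3
    epochs: int = 8
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_channels) != len(self.convs_per_block):
            raise ConfigurationError("block_channels and convs_per_block must align")
        if len(self.pool_strides) != len(self.block_channels):
            raise ConfigurationError("one pool per block required")
        for n, ch in enumerate(self.block_channels, start=1):
            if ch != self.stem_channels * 2**n:
                raise ConfigurationError(
                    f"block {n} must have {self.stem_channels * 2 ** n} channels, got {ch}"
                )

    @property
    def conv_layer_count(self) -> int:
        return 1 + sum(self.convs_per_block)

    @property
    def pool_layer_count(self) -> int:
        return len(self.pool_strides)

    @property
    def total_stride(self) -> int:
        return int(np.prod(self.pool_strides))

    @property
    def feature_channels(self) -> int:
        return self.block_channels[-1]


@dataclass
class FeatureStack:
    """Per-pixel deep features at 1/16 resolution: (H/16, W/16, 1024), ≥ 0."""

    values: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("feature stack must be 3-D (rows, cols, channels)")

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    def as_matrix(self) -> np.ndarray:
        """Flatten the grid to an (N, channels) feature matrix (row-major)."""
        return self.values.reshape(-1, self.n_channels)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    checkpoint_epoch: int = -1

    def validate(self) -> None:
        if self.val_loss and self.checkpoint_epoch >= 0:
            best = min(self.val_loss)
            if self.val_loss[self.checkpoint_epoch] != best:
                raise AssertionError("checkpoint epoch does not hold the best validation loss")


def infer_feature_shape(config: CNNConfig, input_shape: tuple[int, int]) -> tuple[int, int, int]:
    """Propagate spatial shape analytically through the pooling schedule."""
    h, w = input_shape
    s = config.total_stride
    if h % s or w % s:
        raise ValueError(f"input dims {h}x{w} must be divisible by {s}")
    for stride in config.pool_strides:
        h //= stride
        w //= stride
    return h, w, config.feature_channels


class FeatureExtractor:
    """The built network: feature trunk plus the training-only softmax head."""

    def __init__(self, config: CNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.layers: list = []
        cin = 3
        self.layers.append(Conv(cin, config.stem_channels, rng))
        self.layers.append(ReLU())
        cin = config.stem_channels
        for ch, n_convs, stride in zip(
            config.block_channels, config.convs_per_block, config.pool_strides
        ):
            for _ in range(n_convs):
                self.layers.append(Conv(cin, ch, rng))
                self.layers.append(ReLU())
                cin = ch
            self.layers.append(MaxPool2() if stride == 2 else MaxPool2Same())
        self.head = Conv(cin, config.head_classes, rng, ksize=1)

    # -- introspection -------------------------------------------------
    @property
    def conv_layers(self) -> list[Conv]:
        return [l for l in self.layers if isinstance(l, Conv)]

    @property
    def pool_layers(self) -> list:
        return [l for l in self.layers if isinstance(l, (MaxPool2, MaxPool2Same))]

    def parameter_count(self) -> int:
        return sum(p.size for l in self.layers for p in l.params())

    def manifest(self) -> dict:
        return {
            "stem_channels": self.config.stem_channels,
            "block_channels": list(self.config.block_channels),
            "convs_per_block": list(self.config.convs_per_block),
            "pool_strides": list(self.config.pool_strides),
            "conv_layers": len(self.conv_layers),
            "pool_layers": len(self.pool_layers),
            "feature_channels": self.config.feature_channels,
            "total_stride": self.config.total_stride,
        }

    # -- forward/backward ----------------------------------------------
    def _check_dims(self, shape: tuple[int, int]) -> None:
        s = self.config.total_stride
        if shape[0] % s or shape[1] % s:
            raise ValueError(f"input dims {shape} must be divisible by {s}")

    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_dims(x.shape[:2])
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def _loss_and_head_grad(
        self, feats: np.ndarray, labels: np.ndarray
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Pixel-wise softmax cross-entropy at the 1/16 grid; label 0 excluded."""
        logits = self.head.forward(feats, train=True)
        valid = labels > 0
        n = int(valid.sum())
        if n == 0:
            raise ValueError("no labeled grid cells in this image")
        z = logits - logits.max(axis=2, keepdims=True)
        ez = np.exp(z)
        prob = ez / ez.sum(axis=2, keepdims=True)
        idx = labels.astype(int) - 1
        p_true = np.take_along_axis(prob, np.clip(idx, 0, None)[..., None], axis=2)[..., 0]
        loss = float(-np.log(np.clip(p_true[valid], 1e-12, None)).mean())
        onehot = np.zeros_like(prob)
        np.put_along_axis(onehot, np.clip(idx, 0, None)[..., None], 1.0, axis=2)
        dlogits = (prob - onehot) * valid[..., None] / n
        return loss, prob, dlogits.astype(np.float32)

    def loss_on(self, image: AnnotatedImage) -> float:
        x = image.as_rgb()
        labels = downsample_mask(image.mask, DOWNSAMPLE_FACTOR)
        feats = self.forward_features(x, train=False)
        loss, _, _ = self._loss_and_head_grad(feats, labels)
        return loss

    def train_step(self, image: AnnotatedImage, opt: Adam) -> float:
        x = image.as_rgb()
        labels = downsample_mask(image.mask, DOWNSAMPLE_FACTOR)
        feats = self.forward_features(x, train=True)
        loss, _, dlogits = self._loss_and_head_grad(feats, labels)
        grad = self.head.backward(dlogits)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        opt.step([g for l in self.layers for g in l.grads()] + list(self.head.grads()))
        return loss

    def head_predict(self, image: AnnotatedImage) -> np.ndarray:
        """Class labels (1..8) from the auxiliary head alone (CNN-only model)."""
        feats = self.forward_features(image.as_rgb(), train=False)
        logits = self.head.forward(feats, train=False)
        return (logits.argmax(axis=2) + 1).astype(np.uint8)

    # -- weight snapshots ----------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        out = [p.copy() for l in self.layers for p in l.params()]
        out += [p.copy() for p in self.head.params()]
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = [p for l in self.layers for p in l.params()] + list(self.head.params())
        if len(params) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


def build_feature_extractor(config: CNNConfig | None = None) -> FeatureExtractor:
    """Instantiate the encoder (plus auxiliary head) from its configuration."""
    return FeatureExtractor(config or CNNConfig())


def train_feature_extractor(
    model: FeatureExtractor,
    train_set: list[AnnotatedImage],
    val_set: list[AnnotatedImage],
    config: CNNConfig | None = None,
) -> tuple[FeatureExtractor, TrainingHistory]:
    """Train with per-image Adam steps; keep the best-validation weights.

    Deterministic given ``config.seed``: weight init, data order and all
    arithmetic are seeded and single-threaded.
    """
    config = config or model.config
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    for img in train_set + val_set:
        if img.mask is None:
            raise ValueError("all training/validation images need masks")
    if all(
        downsample_mask(img.mask, DOWNSAMPLE_FACTOR).max() == 0 for img in train_set
    ):
        raise ValueError("all training masks are unannotated (label 0 everywhere)")

    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(
        [p for l in model.layers for p in l.params()] + list(model.head.params()),
        lr=config.learning_rate,
    )
    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        losses = [model.train_step(train_set[i], opt) for i in order]
        val = float(np.mean([model.loss_on(img) for img in val_set]))
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_weights = model.get_weights()
            history.checkpoint_epoch = epoch
    model.set_weights(best_weights)
    history.validate()
    return model, history


def extract_features(model: FeatureExtractor, image: AnnotatedImage) -> FeatureStack:
    """Run the trunk (no head): the 1024-channel post-ReLU activation grid."""
    values = model.forward_features(image.as_rgb(), train=False)
    return FeatureStack(values=values, image_id=str(image.meta.get("index", "")))
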
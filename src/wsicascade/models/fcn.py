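"""The modified single-stream FCN-32s tile segmenter (numpy, SGD-trained).

The network is fully convolutional, so one set of weights serves any tile
size whose pool5 feature map still fits the 7x7 fc6 kernel.  Scores come
out as three planes (background, lesion, ignore); the per-pixel lesion
probability is the softmax mass of the lesion plane, which keeps every
output in [0, 1] as the segmenter contract requires.

Training follows the classic FCN recipe: stochastic gradient descent on a
pixelwise softmax cross-entropy.  ``loss='sum'`` is the unnormalized
summed cross-entropy that pairs with very small learning rates (the 1e-10
default); ``loss='mean'`` normalizes by pixel count and pairs with
ordinary learning rates, which is what CPU-scale experiments use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from .trace import FCN32sSpec, trace_shapes

__all__ = ["TrainConfig", "FCN32sSegmenter", "build_fcn32s", "train"]

LESION_CLASS = 1  # plane order: (background, lesion, ignore)


@dataclass(frozen=True)
class TrainConfig:
    """SGD + cross-entropy training hyperparameters."""

    learning_rate: float = 1e-10
    dropout: float = 0.5
    weight_decay: float = 0.0005
    momentum: float = 0.9
    loss: str = "sum"  # 'sum' (classic recipe) or 'mean'
    n_steps: int = 100
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.loss not in ("sum", "mean"):
            raise ValueError("loss must be 'sum' or 'mean'")


class FCN32sSegmenter(BaseEstimator):
    """Sklearn-style estimator wrapping the modified FCN-32s.

    Parameters mirror :class:`FCN32sSpec` (architecture) and
    :class:`TrainConfig` (optimization); ``width`` below 1.0 builds the
    reduced-width variant for CPU-scale experiments.  ``level`` is an
    optional tag naming the pyramid level the model serves.

    Fitted attributes: ``net_`` (the weight stack), ``loss_history_``
    (one entry per SGD step), ``spec_`` (the realized architecture).
    """

    def __init__(
        self,
        width: float = 1.0,
        first_pad: int = 100,
        n_classes: int = 3,
        learning_rate: float = 1e-10,
        dropout: float = 0.5,
        weight_decay: float = 0.0005,
        momentum: float = 0.9,
        loss: str = "sum",
        n_steps: int = 100,
        batch_size: int = 1,
        random_state: int = 0,
        bilinear_upsampling: bool = True,
        level: int | None = None,
    ):
        self.width = width
        self.first_pad = first_pad
        self.n_classes = n_classes
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.weight_decay = weight_decay
        self.momentum = momentum
        self.loss = loss
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.random_state = random_state
        self.bilinear_upsampling = bilinear_upsampling
        self.level = level

    # -- construction -----------------------------------------------------

    def _spec(self) -> FCN32sSpec:
        base = FCN32sSpec(first_pad=self.first_pad, n_classes=self.n_classes)
        return base if self.width == 1.0 else base.scaled(self.width)

    def _build(self) -> None:
        spec = self._spec()
        rng = np.random.default_rng(self.random_state)
        c1, c2, c3, c4, c5 = spec.channels
        L: list[_nn.Layer] = []

        def block(name, widths, c_in, pad_first=1):
            nonlocal L
            pad = pad_first
            for i, c_out in enumerate(widths, start=1):
                L.append(_nn.Conv(f"{name}_{i}", 3, c_in, c_out, pad, rng))
                L.append(_nn.ReLU())
                c_in, pad = c_out, 1
            L.append(_nn.MaxPool2())
            return c_in

        L.append(_nn.Conv("conv1_1", 3, 3, c1, 1, rng))
        L.append(_nn.ReLU())
        L.append(_nn.Conv("conv1_2", 3, c1, c1, spec.first_pad, rng))
        L.append(_nn.ReLU())
        L.append(_nn.MaxPool2())
        c = block("conv2", (c2, c2), c1)
        c = block("conv3", (c3, c3, c3), c)
        c = block("conv4", (c4, c4, c4), c)
        c = block("conv5", (c5, c5, c5), c)
        L.append(_nn.Conv("fc6", spec.fc6_kernel, c, spec.fc_channels, 0, rng))
        L.append(_nn.ReLU())
        L.append(_nn.Dropout(self.dropout, rng))
        L.append(_nn.Conv("fc7", 1, spec.fc_channels, spec.fc_channels, 0, rng))
        L.append(_nn.ReLU())
        L.append(_nn.Dropout(self.dropout, rng))
        L.append(_nn.Conv("score", 1, spec.fc_channels, spec.n_classes, 0, rng))
        L.append(
            _nn.ConvTranspose(
                "upscore",
                spec.upsample_stride,
                spec.n_classes,
                spec.n_classes,
                rng,
                bilinear_init=self.bilinear_upsampling,
            )
        )
        L.append(_nn.CenterCrop())
        self.net_ = _nn.Network(L)
        self.spec_ = spec
        self.loss_history_: list[float] = []

    def trace_shapes(self, input_hw: int | tuple[int, int]):
        """Spatial-dimension trace of this model's architecture."""
        return trace_shapes(self._spec(), input_hw)

    # -- inference --------------------------------------------------------

    @staticmethod
    def _prep(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[2] != 3:
            raise ValueError("a tile must be an (H, W, 3) array")
        return x / 255.0 - 0.5

    def _forward_probs(self, tile: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._prep(tile)
        self.net_.set_output_size(x.shape[:2])
        logits = self.net_.forward(x, train)
        return _nn.softmax(logits)[..., LESION_CLASS]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Lesion probability maps, same spatial dims as the input tile(s)."""
        if not hasattr(self, "net_"):
            self._build()
        X = np.asarray(X)
        if X.ndim == 3:
            return self._forward_probs(X)
        return np.stack([self._forward_probs(t) for t in X])

    def predict(self, X: np.ndarray, alpha: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= alpha).astype(np.uint8)

    # -- training ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FCN32sSegmenter":
        """Train on labeled tiles: X (n, H, W, 3), y (n, H, W) binary."""
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4 or len(X) == 0:
            raise ValueError("training set must be a non-empty (n, H, W, 3) array")
        if y.shape != X.shape[:3]:
            raise ValueError("masks must align with tiles, one (H, W) mask per tile")
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError(f"masks must be binary (0/1); got values {uniq[:5]}")
        trace_shapes(self._spec(), X.shape[1:3])  # validates tile size

        self._build()
        rng = np.random.default_rng(
            np.random.SeedSequence((self.random_state, 0xF17))
        )
        n = len(X)
        bs = min(self.batch_size, n)
        for _ in range(self.n_steps):
            idx = rng.choice(n, size=bs, replace=False)
            self.net_.zero_grad()
            batch_loss = 0.0
            for i in idx:
                x = self._prep(X[i])
                self.net_.set_output_size(x.shape[:2])
                logits = self.net_.forward(x, train=True)
                loss, grad = _nn.softmax_cross_entropy(
                    logits, y[i], reduction=self.loss
                )
                batch_loss += loss
                self.net_.backward(grad)
            _nn.sgd_update(
                self.net_,
                lr=self.learning_rate,
                momentum=self.momentum,
                weight_decay=self.weight_decay,
                scale=1.0 / bs,
            )
            self.loss_history_.append(batch_loss / bs)
        return self

    # -- persistence ------------------------------------------------------

    def save_weights(self, path) -> None:
        if not hasattr(self, "net_"):
            self._build()
        np.savez_compressed(path, **self.net_.state_dict())

    def load_weights(self, path) -> "FCN32sSegmenter":
        """Load a checkpoint (or VGG16-layout .npz with matching names/shapes)."""
        if not hasattr(self, "net_"):
            self._build()
        try:
            with np.load(path) as data:
                state = {k: data[k] for k in data.files}
        except Exception as exc:  # malformed archive
            raise ValueError(f"cannot read weight file {path}: {exc}") from exc
        self.net_.load_state_dict(state)
        return self


def build_fcn32s(
    spec: FCN32sSpec | None = None, train_config: TrainConfig | None = None
) -> FCN32sSegmenter:
    """Functional constructor mirroring the estimator."""
    spec = spec or FCN32sSpec()
    tc = train_config or TrainConfig()
    width = spec.channels[0] / 64.0
    model = FCN32sSegmenter(
        width=width,
        first_pad=spec.first_pad,
        n_classes=spec.n_classes,
        learning_rate=tc.learning_rate,
        dropout=tc.dropout,
        weight_decay=tc.weight_decay,
        momentum=tc.momentum,
        loss=tc.loss,
        n_steps=tc.n_steps,
        batch_size=tc.batch_size,
        random_state=tc.seed,
    )
    model._build()
    return model


def train(
    model: FCN32sSegmenter,
    tiles: np.ndarray,
    masks: np.ndarray,
    train_config: TrainConfig | None = None,
) -> tuple[FCN32sSegmenter, list[float]]:
    """Train a model in place; returns (model, loss history)."""
    if train_config is not None:
        model.set_params(
            learning_rate=train_config.learning_rate,
            dropout=train_config.dropout,
            weight_decay=train_config.weight_decay,
            momentum=train_config.momentum,
            loss=train_config.loss,
            n_steps=train_config.n_steps,
            batch_size=train_config.batch_size,
            random_state=train_config.seed,
        )
    model.fit(tiles, masks)
    return model, model.loss_history_
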
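"""Minimal numpy neural-network layers with hand-written backprop.

Only what the modified FCN-32s needs: 2-D convolution (arbitrary padding),
ReLU, ceil-mode 2x2/2 max-pooling, inverted dropout, a strided transposed
convolution whose kernel is twice its stride, softmax cross-entropy, and
SGD with momentum and weight decay.  Activations are (H, W, C) float64 for
a single sample; gradients are accumulated across a mini-batch by the
training loop.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv",
    "ReLU",
    "MaxPool2",
    "Dropout",
    "ConvTranspose",
    "CenterCrop",
    "Network",
    "softmax",
    "softmax_cross_entropy",
    "bilinear_kernel",
    "sgd_update",
]


def _correlate(x: np.ndarray, W: np.ndarray, pad: int) -> np.ndarray:
    """Valid cross-correlation of padded x (H,W,Cin) with W (kh,kw,Cin,Cout)."""
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    kh, kw = W.shape[:2]
    win = sliding_window_view(x, (kh, kw), axis=(0, 1))  # (Ho, Wo, Cin, kh, kw)
    return np.tensordot(win, W, axes=([3, 4, 2], [0, 1, 2]))


class Layer:
    trainable = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv(Layer):
    """3x3 / 7x7 / 1x1 convolution, stride 1, configurable zero padding."""

    trainable = True

    def __init__(self, name, kernel, c_in, c_out, pad, rng):
        self.name = name
        self.kernel = kernel
        self.pad = pad
        # He initialization (ReLU gain).
        fan_in = kernel * kernel * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kernel, kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.zero_grad()

    def zero_grad(self):
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return _correlate(x, self.W, self.pad) + self.b

    def backward(self, g):
        x, pad, k = self._x, self.pad, self.kernel
        xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0))) if pad else x
        win = sliding_window_view(xp, (k, k), axis=(0, 1))  # (Ho,Wo,Cin,kh,kw)
        # dW[kh,kw,cin,cout] = sum_{h,w} win[h,w,cin,kh,kw] * g[h,w,cout]
        self.gW += np.tensordot(win, g, axes=([0, 1], [0, 1])).transpose(1, 2, 0, 3)
        self.gb += g.sum(axis=(0, 1))
        # dx: full correlation of g with the spatially flipped kernel.
        Wf = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh,kw,Cout,Cin)
        gx_p = _correlate(g, Wf, k - 1)
        if pad:
            gx_p = gx_p[pad:-pad, pad:-pad]
        return gx_p

    def params(self):
        return [(f"{self.name}_W", self.W, self.gW), (f"{self.name}_b", self.b, self.gb)]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class MaxPool2(Layer):
    """2x2 stride-2 max pooling, ceil mode (ragged edges padded with -inf)."""

    def forward(self, x, train):
        h, w, c = x.shape
        self._hw = (h, w)
        ho, wo = -(-h // 2), -(-w // 2)
        xp = np.full((ho * 2, wo * 2, c), -np.inf)
        xp[:h, :w] = x
        v = xp.reshape(ho, 2, wo, 2, c).transpose(0, 2, 1, 3, 4).reshape(ho, wo, 4, c)
        self._idx = v.argmax(axis=2)
        self._shape = (ho, wo, c)
        return np.take_along_axis(v, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, g):
        ho, wo, c = self._shape
        gv = np.zeros((ho, wo, 4, c))
        np.put_along_axis(gv, self._idx[:, :, None, :], g[:, :, None, :], axis=2)
        gp = gv.reshape(ho, wo, 2, 2, c).transpose(0, 2, 1, 3, 4).reshape(ho * 2, wo * 2, c)
        h, w = self._hw
        return gp[:h, :w]


class Dropout(Layer):
    """Inverted dropout: scaling at train time, identity at inference."""

    def __init__(self, p, rng):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class ConvTranspose(Layer):
    """Transposed convolution with kernel = 2 * stride (upsampling layer).

    Output size is exactly ``(d + 1) * stride`` for a d-wide input, i.e.
    ``(d - 1) * stride + kernel``.
    """

    trainable = True

    def __init__(self, name, stride, c_in, c_out, rng, bilinear_init=True):
        self.name = name
        self.s = stride
        k = 2 * stride
        if bilinear_init and c_in == c_out:
            self.W = np.zeros((k, k, c_in, c_out))
            f = bilinear_kernel(k)
            for c in range(c_in):
                self.W[:, :, c, c] = f
        else:
            fan_in = k * k * c_in
            self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, c_in, c_out))
        self.b = np.zeros(c_out)
        self.zero_grad()

    def zero_grad(self):
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        s = self.s
        dh, dw, c_in = x.shape
        c_out = self.W.shape[3]
        # Y[i,j,dy,dx,co] = sum_ci x[i,j,ci] W[dy,dx,ci,co]
        Y = np.tensordot(x, self.W, axes=([2], [2]))
        Y6 = Y.reshape(dh, dw, 2, s, 2, s, c_out)
        out = np.zeros(((dh + 1) * s, (dw + 1) * s, c_out))
        o5 = out.reshape(dh + 1, s, dw + 1, s, c_out)
        for q1 in range(2):
            for q2 in range(2):
                o5[q1 : q1 + dh, :, q2 : q2 + dw, :, :] += Y6[
                    :, :, q1, :, q2, :, :
                ].transpose(0, 2, 1, 3, 4)
        return out + self.b

    def backward(self, g):
        x, s = self._x, self.s
        dh, dw, c_in = x.shape
        c_out = self.W.shape[3]
        g5 = g.reshape(dh + 1, s, dw + 1, s, c_out)
        gY6 = np.empty((dh, dw, 2, s, 2, s, c_out))
        for q1 in range(2):
            for q2 in range(2):
                gY6[:, :, q1, :, q2, :, :] = g5[
                    q1 : q1 + dh, :, q2 : q2 + dw, :, :
                ].transpose(0, 2, 1, 3, 4)
        gY = gY6.reshape(dh, dw, 2 * s, 2 * s, c_out)
        # tensordot yields (cin, kh, kw, cout); reorder to (kh, kw, cin, cout).
        self.gW += np.tensordot(x, gY, axes=([0, 1], [0, 1])).transpose(1, 2, 0, 3)
        self.gb += g.sum(axis=(0, 1))
        return np.tensordot(gY, self.W, axes=([2, 3, 4], [0, 1, 3]))

    def params(self):
        return [(f"{self.name}_W", self.W, self.gW), (f"{self.name}_b", self.b, self.gb)]


class CenterCrop(Layer):
    """Symmetric crop of the upsampled map back to the network input size."""

    def __init__(self):
        self.target = None  # set per forward pass by the network

    def forward(self, x, train):
        th, tw = self.target
        h, w = x.shape[:2]
        self._pre = (h, w)
        o1, o2 = (h - th) // 2, (w - tw) // 2
        self._off = (o1, o2)
        return x[o1 : o1 + th, o2 : o2 + tw]

    def backward(self, g):
        h, w = self._pre
        o1, o2 = self._off
        out = np.zeros((h, w) + g.shape[2:])
        out[o1 : o1 + g.shape[0], o2 : o2 + g.shape[1]] = g
        return out


def bilinear_kernel(k: int) -> np.ndarray:
    """Standard bilinear upsampling filter of size k (stride k/2)."""
    factor = (k + 1) // 2
    center = factor - 1 if k % 2 == 1 else factor - 0.5
    og = np.arange(k)
    f1 = 1.0 - np.abs(og - center) / factor
    return np.outer(f1, f1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, target: np.ndarray, reduction: str = "mean"
) -> tuple[float, np.ndarray]:
    """Pixelwise softmax cross-entropy; returns (loss, dloss/dlogits).

    ``reduction='sum'`` is the classic unnormalized FCN recipe (pairs with
    tiny learning rates such as 1e-10); ``'mean'`` divides by pixel count.
    """
    p = softmax(logits)
    h, w = target.shape
    idx = target.astype(np.intp)
    picked = np.take_along_axis(p, idx[:, :, None], axis=2)[:, :, 0]
    losses = -np.log(np.maximum(picked, 1e-300))
    grad = p.copy()
    np.put_along_axis(
        grad,
        idx[:, :, None],
        np.take_along_axis(grad, idx[:, :, None], axis=2) - 1.0,
        axis=2,
    )
    if reduction == "mean":
        return float(losses.mean()), grad / (h * w)
    if reduction == "sum":
        return float(losses.sum()), grad
    raise ValueError("reduction must be 'mean' or 'sum'")


class Network:
    """A plain sequential stack with per-parameter momentum buffers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.velocity: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            if isinstance(layer, CenterCrop):
                layer.target = self._target
            x = layer.forward(x, train)
        return x

    def set_output_size(self, hw: tuple[int, int]) -> None:
        self._target = hw

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def zero_grad(self) -> None:
        for layer in self.layers:
            if layer.trainable:
                layer.zero_grad()

    def parameters(self):
        for layer in self.layers:
            if layer.trainable:
                yield from layer.params()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.parameters():
            if name not in state:
                raise ValueError(f"weight file is missing parameter '{name}'")
            arr = np.asarray(state[name])
            if arr.shape != p.shape:
                raise ValueError(
                    f"parameter '{name}' has shape {arr.shape}, expected {p.shape}"
                )
            p[...] = arr


def sgd_update(
    net: Network,
    lr: float,
    momentum: float = 0.0,
    weight_decay: float = 0.0,
    scale: float = 1.0,
) -> None:
    """SGD step with momentum and (decoupled-from-loss) L2 weight decay.

    ``scale`` divides accumulated gradients (e.g. by the batch size).
    """
    for name, p, g in net.parameters():
        step = g * scale
        if weight_decay and not name.endswith("_b"):
            step = step + weight_decay * p
        if momentum:
            v = net.velocity.get(name)
            v = momentum * v - lr * step if v is not None else -lr * step
            net.velocity[name] = v
            p += v
        else:
            p -= lr * step
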
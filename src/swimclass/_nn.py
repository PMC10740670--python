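"""Minimal NumPy neural-network layers for the track-image classifier.

Implements exactly what the classifier needs — 3x3 same-padding
convolutions (im2col), 2x2 max pooling, ReLU, global average pooling, dense
layers, residual blocks, Adam, and the focal loss with its analytic
gradient.  Everything is float32, seeded, and deterministic on one device;
there is no autograd: each layer caches its forward inputs and implements
``backward`` explicitly.
"""

from __future__ import annotations

import math

import numpy as np

_EPS_PT = 1e-7  # clip for the true-class probability inside the loss


# ---------------------------------------------------------------------------
# focal loss (the training objective)
# ---------------------------------------------------------------------------

def focal_loss_value(p_t: np.ndarray, gamma: float) -> np.ndarray:
    """Per-sample focal loss −(1−p_t)^γ·log(p_t) with p_t clipped to [ε, 1]."""
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    p_t = np.clip(np.asarray(p_t, dtype=np.float64), _EPS_PT, 1.0)
    return -((1.0 - p_t) ** gamma) * np.log(p_t)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def focal_loss_and_grad(logits: np.ndarray, targets: np.ndarray, gamma: float):
    """Mean focal loss over a batch and its gradient w.r.t. the logits.

    Because the loss depends on the probabilities only through p_t,
    dL/dz_j = dL/dp_t · p_t (δ_tj − p_j); at γ=0 this reduces to the
    familiar softmax cross-entropy gradient p − onehot.
    """
    n, k = logits.shape
    p = softmax(logits.astype(np.float64))
    rows = np.arange(n)
    pt = np.clip(p[rows, targets], _EPS_PT, 1.0)
    loss = float(focal_loss_value(pt, gamma).mean())
    one_minus = 1.0 - pt
    if gamma == 0:
        dl_dpt = -1.0 / pt
    else:
        # γ(1−p)^{γ−1}·log p − (1−p)^γ / p ; safe at p→1 since γ ≥ 0
        dl_dpt = gamma * np.power(one_minus, max(gamma - 1.0, 0.0)) * np.log(pt) \
            - np.power(one_minus, gamma) / pt
        if gamma < 1.0:  # (1−p)^{γ−1} diverges at p=1; the product still → 0
            dl_dpt = np.where(one_minus <= 0, 0.0, dl_dpt)
    onehot = np.zeros_like(p)
    onehot[rows, targets] = 1.0
    dz = dl_dpt[:, None] * pt[:, None] * (onehot - p) / n
    return loss, dz.astype(np.float32)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    def params(self):
        return []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding (im2col + batched matmul)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / (c_in * 9))
        self.w = Param(rng.normal(0.0, std, size=(c_out, c_in * 9)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = np.empty((n, c, 9, h, w), dtype=x.dtype)
        k = 0
        for ki in range(3):
            for kj in range(3):
                cols[:, :, k] = xp[:, :, ki:ki + h, kj:kj + w]
                k += 1
        return cols.reshape(n, c * 9, h * w)

    def forward(self, x):
        n, c, h, w = x.shape
        cols = self._im2col(x)
        out = (self.w.value @ cols) + self.b.value[None, :, None]
        self._cache = (cols, x.shape)
        return out.reshape(n, -1, h, w)

    def backward(self, dout):
        cols, (n, c, h, w) = self._cache
        dflat = dout.reshape(n, -1, h * w)
        self.w.grad = np.einsum("nop,ncp->oc", dflat, cols, optimize=True)
        self.b.grad = dflat.sum(axis=(0, 2))
        dcols = (self.w.value.T @ dflat).reshape(n, c, 9, h, w)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=dout.dtype)
        k = 0
        for ki in range(3):
            for kj in range(3):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, k]
                k += 1
        return dxp[:, :, 1:-1, 1:-1]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0.0, std, size=(d_in, d_out)).astype(np.float32))
        self.b = Param(np.zeros(d_out, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad = self._x.T @ dout
        self.b.grad = dout.sum(axis=0)
        return dout @ self.w.value.T


class ResBlock(Layer):
    """conv-relu-conv plus identity (or 1x1-projected) skip, then ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv3x3(c_in, c_out, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv3x3(c_out, c_out, rng)
        self.proj = None
        if c_in != c_out:
            std = math.sqrt(2.0 / c_in)
            self.proj = Param(rng.normal(0.0, std, size=(c_in, c_out)).astype(np.float32))
        self.relu_out = ReLU()

    def params(self):
        p = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            p.append(self.proj)
        return p

    def forward(self, x):
        out = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        if self.proj is None:
            skip = x
        else:
            self._x = x
            skip = np.einsum("nchw,co->nohw", x, self.proj.value, optimize=True)
        return self.relu_out.forward(out + skip)

    def backward(self, dout):
        dout = self.relu_out.backward(dout)
        dx_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(dout)))
        if self.proj is None:
            return dx_main + dout
        self.proj.grad = np.einsum("nchw,nohw->co", self._x, dout, optimize=True)
        return dx_main + np.einsum("nohw,co->nchw", dout, self.proj.value, optimize=True)


# ---------------------------------------------------------------------------
# network + optimizer
# ---------------------------------------------------------------------------

class Network:
    """A feature stack followed by an embedding Dense+ReLU and a decision Dense.

    The embedding exposed to the analysis is the ReLU output of the layer
    directly under the decision layer.
    """

    def __init__(self, layers: list[Layer], head: Dense):
        self.layers = layers  # everything up to and including the embedding ReLU
        self.head = head

    def all_params(self):
        params = []
        for layer in self.layers:
            params.extend(layer.params())
        params.extend(self.head.params())
        return params

    def embed(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.embed(x))

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        for layer in reversed(self.layers):
            d = layer.backward(d)


def build_small_cnn(n_classes: int, rng: np.random.Generator,
                    embed_dim: int = 64) -> Network:
    """Four conv blocks with pooling, global average pool, dense embedding."""
    layers: list[Layer] = [
        Conv3x3(3, 8, rng), ReLU(), MaxPool2(),
        Conv3x3(8, 16, rng), ReLU(), MaxPool2(),
        Conv3x3(16, 32, rng), ReLU(), MaxPool2(),
        Conv3x3(32, 32, rng), ReLU(),
        GlobalAvgPool(),
        Dense(32, embed_dim, rng), ReLU(),
    ]
    return Network(layers, Dense(embed_dim, n_classes, rng))


def build_resnet_small(n_classes: int, rng: np.random.Generator,
                       embed_dim: int = 64) -> Network:
    """Compact residual backbone: stem conv + two residual stages."""
    layers: list[Layer] = [
        Conv3x3(3, 16, rng), ReLU(), MaxPool2(),
        ResBlock(16, 16, rng), MaxPool2(),
        ResBlock(16, 32, rng), MaxPool2(),
        ResBlock(32, 32, rng),
        GlobalAvgPool(),
        Dense(32, embed_dim, rng), ReLU(),
    ]
    return Network(layers, Dense(embed_dim, n_classes, rng))


BACKBONES = {"small_cnn": build_small_cnn, "resnet_small": build_resnet_small}


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * (p.grad * p.grad)
            p.value -= self.lr * (p.m / bc1) / (np.sqrt(p.v / bc2) + self.eps)
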
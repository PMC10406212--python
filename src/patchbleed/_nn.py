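"""Minimal CNN building blocks in numpy.

Implements exactly what the patch classifier needs: 3x3 same-padding
convolutions (im2col / GEMM), batch normalization, leaky rectifiers,
2x2 max pooling, flatten, dense layers, softmax cross-entropy, and SGD
with momentum.  Convolution and dense layers are the *freeze units*: the
training loop can hold the first N of them fixed during fine-tuning
(frozen parameters are never touched, so they stay bit-identical), while
batch-normalization scale/shift and running statistics keep adapting.

All arrays are channel-first: images are (B, C, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer; parameterized layers override params()/grads().

    ``freeze_unit`` marks the layers that count when "the first N layers"
    are frozen during fine-tuning: convolution and dense layers.  Batch
    normalization is parameterized but is not a freeze unit — its scale/
    shift and running statistics keep adapting to the new task, as is
    standard fine-tuning practice.
    """

    name: str = "layer"
    freeze_unit: bool = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def state(self) -> list[np.ndarray]:
        """Parameters plus non-trained buffers (for checkpointing)."""
        return self.params()


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 ('same')."""

    freeze_unit = True

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str = "conv"):
        self.name = name
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * 9
        scale = np.sqrt(2.0 / fan_in)  # He init for rectifier nets
        self.W = rng.normal(0.0, scale, size=(c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B,C,H,W,3,3)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * 9)
        self._cols, self._in_shape = cols, x.shape
        out = cols @ self.W.T + self.b
        return out.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        g = grad.transpose(0, 2, 3, 1).reshape(B * H * W, self.c_out)
        self.dW = (g.T @ self._cols) / B
        self.db = g.sum(axis=0) / B
        dcols = (g @ self.W).reshape(B, H, W, C, 3, 3)
        dxp = np.zeros((B, C, H + 2, W + 2), dtype=np.float32)
        for ki in range(3):
            for kj in range(3):
                dxp[:, :, ki : ki + H, kj : kj + W] += dcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        self._cols = None
        return dxp[:, :, 1 : H + 1, 1 : W + 1]

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Normalizing activations keeps the backbone well-conditioned across
    task switches, which is what makes fine-tuning from pretrained
    weights converge quickly instead of crawling out of the source
    task's minimum.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        self.name = name
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = grad.shape
        m = B * H * W
        xhat, inv = self._xhat, self._inv
        self.dgamma = (grad * xhat).sum(axis=(0, 2, 3)) / B
        self.dbeta = grad.sum(axis=(0, 2, 3)) / B
        g = grad * self.gamma[None, :, None, None]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = inv[None, :, None, None] * (g - sum_g / m - xhat * sum_gx / m)
        self._xhat = None
        return dx.astype(np.float32)

    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    def grads(self) -> list[np.ndarray]:
        return [self.dgamma, self.dbeta]

    def state(self) -> list[np.ndarray]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]


class LeakyReLU(Layer):
    """Leaky rectifier; the negative slope keeps hypointense (negative
    pre-activation) structure visible through frozen layers."""

    name = "relu"

    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.alpha * grad)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are cropped."""

    name = "maxpool"

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :, : H2 * 2, : W2 * 2].reshape(B, C, H2, 2, W2, 2)
        out = xc.max(axis=(3, 5))
        self._mask = xc == out[:, :, :, None, :, None]
        self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        H2, W2 = H // 2, W // 2
        # split gradient evenly among tied maxima to keep backward exact
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        g = self._mask * (grad[:, :, :, None, :, None] / counts)
        dx = np.zeros((B, C, H, W), dtype=np.float32)
        dx[:, :, : H2 * 2, : W2 * 2] = g.reshape(B, C, H2 * 2, W2 * 2)
        return dx


class Flatten(Layer):
    """Flatten spatial maps to vectors; unlike global pooling this keeps
    the positional information that center-voxel classification needs."""

    name = "flatten"

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Dense(Layer):
    freeze_unit = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        self.name = name
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B = grad.shape[0]
        self.dW = grad.T @ self._x / B
        self.db = grad.sum(axis=0) / B
        self._x = None
        return grad @ self.W

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(y)), y] + eps).mean())


class Sequential:
    """Ordered layer stack; ``weighted_layers`` are the freeze units
    (convolution/dense) in network order."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def weighted_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.freeze_unit]

    @property
    def param_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for l in self.layers for p in l.state()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for l in self.layers for p in l.state()]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(flat, weights):
            p[...] = w


class SGDM:
    """SGD with momentum; parameters of frozen freeze-units are never
    updated (bit-identical before/after)."""

    def __init__(self, model: Sequential, lr: float, momentum: float = 0.9,
                 freeze_layers: int = 0):
        units = model.weighted_layers
        if freeze_layers > len(units):
            raise ValueError(f"freeze_layers={freeze_layers} exceeds {len(units)} weighted layers")
        frozen = set(id(l) for l in units[:freeze_layers])
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self.trainable = [l for l in model.param_layers if id(l) not in frozen]
        self.velocity = [[np.zeros_like(p) for p in l.params()] for l in self.trainable]

    def step(self) -> None:
        for layer, vel in zip(self.trainable, self.velocity):
            for p, g, v in zip(layer.params(), layer.grads(), vel):
                v *= self.momentum
                v -= self.lr * g
                p += v
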
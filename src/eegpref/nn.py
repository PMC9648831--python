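"""A small, deterministic CNN engine on NumPy.

Implements exactly the operators the seven classifier architectures need:
stride-1 'same'-padded 2-D convolution, ELU, max pooling (3x3, stride 1,
same), dropout, flatten, dense, branch containers, softmax cross-entropy,
Adam, and Glorot-uniform initialisation.  Activations are single-precision
and channels-last internally, (N, H, W, C), which makes the reshapes around
the BLAS matrix products free; the public interface
(:meth:`Network.logits` etc.) accepts the conventional (N, C, H, W).
Everything is reproducible: all randomness flows through
``numpy.random.Generator`` objects supplied by the caller.

'same' padding follows the zero-padding convention: for kernel k the input
is padded by (k-1)//2 before and k-1-(k-1)//2 after, so output spatial size
equals input spatial size for every k (including even kernels such as 2x2).
"""

from __future__ import annotations

import numpy as np

from ._kernels import elu_forward, im2col_same
from .errors import ShapeError

__all__ = [
    "Conv2D", "ELU", "MaxPool2D", "Dropout", "Flatten", "Dense",
    "Sequential", "BranchConcat", "SplitBranches", "Network", "Adam",
    "softmax", "softmax_cross_entropy", "glorot_uniform",
]

#: dtype of all weights and activations.
DTYPE = np.float32


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _same_pad(k: int) -> tuple[int, int]:
    return ((k - 1) // 2, k - 1 - (k - 1) // 2)


class Layer:
    """Base layer: forward/backward plus (param, grad) exposure."""

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 2-D convolution with 'same' zero padding.

    Weights are stored (out_channels, in_channels, k, k); the forward pass
    runs as one patch-matrix product.  The input gradient is computed as the
    correlation of the output gradient with the spatially flipped kernel,
    which reuses the same patch-extraction kernel.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, input_grad: bool = True):
        k = int(kernel)
        self.input_grad = input_grad
        fan_in = in_channels * k * k
        fan_out = out_channels * k * k
        self.w = glorot_uniform((out_channels, in_channels, k, k), fan_in, fan_out, rng)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.kernel = k
        self.in_channels = in_channels
        self.out_channels = out_channels

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train):
        if x.ndim != 4 or x.shape[3] != self.in_channels:
            raise ShapeError(
                f"Conv2D expected (N, H, W, {self.in_channels}), got {x.shape}")
        n, h, w, _ = x.shape
        k = self.kernel
        p0, _ = _same_pad(k)
        col = im2col_same(np.ascontiguousarray(x), k, p0)
        # (k, k, Cin, Cout) matching the column layout (i, j, c)
        wmat = self.w.transpose(2, 3, 1, 0).reshape(k * k * self.in_channels,
                                                    self.out_channels)
        out = col @ np.ascontiguousarray(wmat) + self.b
        self._col, self._xshape = col, x.shape
        return out.reshape(n, h, w, self.out_channels)

    def backward(self, grad):
        n, h, w, _ = self._xshape
        k = self.kernel
        p0, _ = _same_pad(k)
        g = grad.reshape(n * h * w, self.out_channels)
        dwmat = self._col.T @ g  # (k*k*Cin, Cout)
        self.dw[...] = dwmat.reshape(k, k, self.in_channels,
                                     self.out_channels).transpose(3, 2, 0, 1)
        self.db[...] = g.sum(axis=0)
        if not self.input_grad:
            return None
        colg = im2col_same(np.ascontiguousarray(grad), k, k - 1 - p0)
        wrot = self.w[:, :, ::-1, ::-1].transpose(2, 3, 0, 1).reshape(
            k * k * self.out_channels, self.in_channels)
        dx = colg @ np.ascontiguousarray(wrot)
        return dx.reshape(n, h, w, self.in_channels)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train):
        out, self._deriv = elu_forward(np.ascontiguousarray(x, dtype=DTYPE),
                                       self.alpha)
        return out

    def backward(self, grad):
        return grad * self._deriv


class MaxPool2D(Layer):
    """k x k max pooling, stride 1, 'same' padding (pads with -inf)."""

    def __init__(self, kernel: int = 3):
        self.kernel = int(kernel)

    def forward(self, x, train):
        k = self.kernel
        p0, p1 = _same_pad(k)
        xp = np.pad(x, ((0, 0), (p0, p1), (p0, p1), (0, 0)),
                    constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        out = win.max(axis=(4, 5))
        self._xp, self._out, self._shape = xp, out, x.shape
        return np.ascontiguousarray(out)

    def backward(self, grad):
        n, h, w, c = self._shape
        k = self.kernel
        p0, p1 = _same_pad(k)
        dxp = np.zeros_like(self._xp)
        # route the gradient to every position attaining the window max
        for i in range(k):
            for j in range(k):
                mask = self._xp[:, i:i + h, j:j + w, :] == self._out
                dxp[:, i:i + h, j:j + w, :] += grad * mask
        return dxp[:, p0:p0 + h, p0:p0 + w, :]


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = DTYPE(1.0 - self.rate)
        self._mask = (self.rng.random(x.shape, dtype=DTYPE) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.w = glorot_uniform((in_features, out_features), in_features, out_features, rng)
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train):
        if x.ndim != 2 or x.shape[1] != self.w.shape[0]:
            raise ShapeError(f"Dense expected (N, {self.w.shape[0]}), got {x.shape}")
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class BranchConcat(Layer):
    """Feed the same input to several branches; concatenate along channels."""

    def __init__(self, branches: list[Layer]):
        self.branches = branches

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def forward(self, x, train):
        outs = [b.forward(x, train) for b in self.branches]
        self._widths = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, grad):
        splits = np.cumsum(self._widths)[:-1]
        parts = np.split(grad, splits, axis=-1)
        total = None
        for b, g in zip(self.branches, parts):
            gx = b.backward(np.ascontiguousarray(g))
            total = gx if total is None else total + gx
        return total


class SplitBranches(Layer):
    """Feed input channel c to branch c; concatenate branch outputs."""

    def __init__(self, branches: list[Layer]):
        self.branches = branches

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def forward(self, x, train):
        if x.shape[-1] != len(self.branches):
            raise ShapeError(
                f"expected {len(self.branches)} input channels, got {x.shape[-1]}")
        outs = [b.forward(np.ascontiguousarray(x[..., c:c + 1]), train)
                for c, b in enumerate(self.branches)]
        self._widths = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, grad):
        splits = np.cumsum(self._widths)[:-1]
        parts = np.split(grad, splits, axis=-1)
        gxs = [b.backward(np.ascontiguousarray(g))
               for b, g in zip(self.branches, parts)]
        if any(g is None for g in gxs):  # input branches skip their dx
            return None
        return np.concatenate(gxs, axis=-1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


class Network:
    """A trainable graph: body producing 2-class logits + loss/predict API."""

    def __init__(self, body: Layer, name: str):
        self.body = body
        self.name = name

    def params(self):
        return self.body.params()

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, C, H, W) in the conventional layout."""
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim != 4:
            raise ShapeError(f"expected a (N, C, H, W) batch, got {x.shape}")
        return self.body.forward(np.ascontiguousarray(np.moveaxis(x, 1, -1)), train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.logits(x, train=False).argmax(axis=1)

    def train_step(self, x, labels, optimizer: "Adam") -> float:
        logits = self.logits(x, train=True)
        loss, dlogits = softmax_cross_entropy(logits, labels)
        self.body.backward(dlogits)
        optimizer.step()
        return loss

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ShapeError("weight list length mismatch")
        for (w, _), new in zip(own, weights):
            w[...] = new


class Adam:
    """Adam with the conventional defaults (lr set by the caller)."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 2e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1 = DTYPE(self.beta1)
        b2 = DTYPE(self.beta2)
        bc1 = DTYPE(1 - self.beta1 ** self.t)
        bc2 = DTYPE(1 - self.beta2 ** self.t)
        lr = DTYPE(self.lr)
        eps = DTYPE(self.eps)
        one = DTYPE(1)
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (one - b1) * g
            v *= b2
            v += (one - b2) * g * g
            w -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)
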
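"""Compact NumPy neural-network layer library.

Implements exactly what the classification and saliency stages need:
2-D convolution (im2col), ReLU, non-overlapping max pooling, dropout, dense
layers, and a softmax/cross-entropy head, each with an explicit backward
pass.  The backward pass exposes, besides parameter gradients, the
quantities saliency methods consume:

* the gradient of a chosen scalar (e.g. a class logit) with respect to the
  network input (FullGrad input-gradient term, guided backprop);
* per-layer bias gradients at full spatial resolution (FullGrad bias terms);
* activations of, and gradients at, any intermediate layer (Grad-CAM++).

A ``guided`` flag switches every ReLU backward to guided-backpropagation
gating (negative upstream gradients suppressed).

All arrays are ``float64`` NCHW.  Determinism: parameter initialization and
dropout consume a generator owned by the :class:`Sequential`.
"""

from __future__ import annotations

import numpy as np

# Compute dtype: single precision keeps the conv stack fast under BLAS;
# tests that need tighter arithmetic can cast a network with .astype().
DTYPE = np.float32


class Layer:
    """Base layer: forward caches whatever backward needs."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    # x: (B, C, H, W) -> (B, C*k*k, H*W) with zero padding, stride 1
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k)
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, h * w)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    # inverse scatter-add of _im2col
    b, c, h, w = x_shape
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(b, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d(Layer):
    """Same-padded stride-1 convolution (cross-correlation), square kernel."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        scale = np.sqrt(2.0 / (cin * k * k))  # He init
        self.W = rng.normal(0.0, scale, size=(cout, cin * k * k)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE) if bias else None
        self.params = [self.W] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]
        self.bias_grad_map: np.ndarray | None = None  # (B, cout, H, W)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.W.dtype)
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.pad)
        b = x.shape[0]
        h, w = x.shape[2], x.shape[3]
        out = self.W[None] @ self._cols
        if self.b is not None:
            out += self.b[None, :, None]
        return out.reshape(b, self.cout, h, w)

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        gout = np.ascontiguousarray(gout, dtype=self.W.dtype)
        b, _, h, w = gout.shape
        g = gout.reshape(b, self.cout, h * w)
        self.grads[0][...] = (g @ self._cols.transpose(0, 2, 1)).sum(axis=0)
        if self.b is not None:
            self.grads[1][...] = g.sum(axis=(0, 2))
            # spatially-resolved bias gradient for FullGrad
            self.bias_grad_map = gout.copy()
        gcols = self.W.T[None] @ g
        return _col2im(gcols, self._x_shape, self.k, self.pad)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        g = np.where(self._mask, gout, 0.0)
        if guided:
            g = np.where(g > 0, g, 0.0)
        return g


class MaxPool2d(Layer):
    """Non-overlapping max pooling; spatial dims must divide the pool size."""

    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {s}")
        xr = x.reshape(b, c, h // s, s, w // s, s)
        out = xr.max(axis=(3, 5))
        self._argmask = xr == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per window
        flat = self._argmask.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // s, w // s, s * s)
        first = np.cumsum(flat, axis=-1) == 1
        flat &= first
        self._argmask = flat.reshape(b, c, h // s, w // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        self._x_shape = x.shape
        return out

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        b, c, h, w = self._x_shape
        s = self.size
        g = gout[:, :, :, None, :, None] * self._argmask
        return g.reshape(b, c, h // s, s, w // s, s).reshape(b, c, h, w)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train and self.p > 0:
            self._mask = self.rng.random(x.shape) >= self.p
            return x * self._mask / (1 - self.p)
        self._mask = None
        return x

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        if self._mask is None:
            return gout
        return gout * self._mask / (1 - self.p)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        return gout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout)).astype(DTYPE)
        self.b = np.zeros(nout, dtype=DTYPE) if bias else None
        self.params = [self.W] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]
        self.bias_grad_map: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.W.dtype)
        self._x = x
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def backward(self, gout: np.ndarray, guided: bool = False) -> np.ndarray:
        self.grads[0][...] = self._x.T @ gout
        if self.b is not None:
            self.grads[1][...] = gout.sum(axis=0)
            self.bias_grad_map = gout.copy()
        return gout @ self.W.T


class Sequential:
    """A feed-forward stack with explicit forward/backward."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self.outputs: list[np.ndarray] = []  # per-layer outputs of this pass
        for layer in self.layers:
            x = layer.forward(x, train=train)
            self.outputs.append(x)
        return x

    def backward(
        self,
        gout: np.ndarray,
        guided: bool = False,
        upto: int = 0,
        record: bool = False,
    ) -> np.ndarray:
        """Backpropagate ``gout`` through layers [upto, end) in reverse.

        Returns the gradient at the input of layer ``upto``.  With
        ``record=True``, ``self.grad_outputs[i]`` holds the gradient at the
        output of layer ``i`` (saliency methods read these).
        """
        if record:
            self.grad_outputs: list[np.ndarray | None] = [None] * len(self.layers)
        for i in range(len(self.layers) - 1, upto - 1, -1):
            if record:
                self.grad_outputs[i] = gout
            gout = self.layers[i].backward(gout, guided=guided)
        return gout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state, strict=True):
            p[...] = s

    def astype(self, dtype) -> "Sequential":
        """Cast all parameters and gradients in place (e.g. for float64 checks)."""
        for layer in self.layers:
            for name in ("W", "b"):
                v = getattr(layer, name, None)
                if v is not None:
                    setattr(layer, name, v.astype(dtype))
            if layer.params:
                layer.params = [getattr(layer, "W")] + (
                    [layer.b] if getattr(layer, "b", None) is not None else []
                )
                layer.grads = [np.zeros_like(p) for p in layer.params]
        return self


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class SGD:
    """Mini-batch gradient descent with classical momentum and norm clipping.

    Clipping the global gradient norm (default 5) guards the conv stack
    against the occasional exploding batch without changing well-behaved
    steps.
    """

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float,
        momentum: float = 0.9,
        clip_norm: float | None = 5.0,
    ):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for p, g, v in zip(self.params, grads, self.velocity, strict=True):
            v *= self.momentum
            v -= self.lr * scale * g
            p += v
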
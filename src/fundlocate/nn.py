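"""Minimal CNN engine: numpy layers with hand-derived backprop.

Implements exactly the layer vocabulary the glaucoma classifier needs —
convolution, ReLU, overlapping max-pooling, local response normalization
(LRN), dropout, dense layers and a fused softmax/cross-entropy head — plus
the Adam optimizer.  Tensors are NCHW ``float32`` by default; every layer
also works in ``float64``, which the gradient-check tests use.

Gradient correctness of each layer is verified against central-difference
numeric gradients in the test suite; nothing here is stochastic except
dropout, which draws from an explicit ``numpy.random.Generator`` so whole
training runs are reproducible under a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2D", "ReLU", "MaxPool2D", "LRN", "Dropout", "Flatten",
    "Dense", "Sequential", "softmax", "softmax_cross_entropy", "Adam",
]


class Layer:
    """Base layer: forward caches whatever backward needs."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    out = (size + 2 * pad - k) // stride + 1
    if out < 1:
        raise ValueError(
            f"spatial size collapses: input {size}, kernel {k}, stride {stride}, pad {pad}"
        )
    return out


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, OH, OW, k, k) strided view of all kxk windows."""
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return view[:, :, ::stride, ::stride, :, :]


class Conv2D(Layer):
    """2-D convolution (cross-correlation) with bias, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.params["W"] = (rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                       size=(out_ch, in_ch, k, k))).astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        oh, ow = _out_size(h, k, s, p), _out_size(w, k, s, p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        # cache as (N, OH, OW, C, k, k) contiguous for both passes
        cols = np.ascontiguousarray(_windows(xp, k, s).transpose(0, 2, 3, 1, 4, 5))
        self._cols, self._xshape, self._ohw = cols, x.shape, (oh, ow)
        out = np.tensordot(cols, self.params["W"], axes=([3, 4, 5], [1, 2, 3]))
        out += self.params["b"]
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, _, h, w = self._xshape
        k, s, p = self.k, self.stride, self.pad
        oh, ow = self._ohw
        do = dout.transpose(0, 2, 3, 1)  # (N, OH, OW, F)
        self.grads["W"] = np.tensordot(do, self._cols, axes=([0, 1, 2], [0, 1, 2]))
        self.grads["b"] = do.sum(axis=(0, 1, 2))
        dcols = np.tensordot(do, self.params["W"], axes=([3], [0]))  # (N,OH,OW,C,k,k)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (N, C, k, k, OH, OW)
        dxp = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[:, :, i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU(Layer):
    """f(x) = max(0, x)."""

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2D(Layer):
    """Max pooling; with stride < window this is overlapping pooling."""

    def __init__(self, window: int = 3, stride: int = 2) -> None:
        super().__init__()
        self.window, self.stride = window, stride

    def forward(self, x, train=False, rng=None):
        k, s = self.window, self.stride
        n, c, h, w = x.shape
        oh, ow = _out_size(h, k, s, 0), _out_size(w, k, s, 0)
        win = _windows(x, k, s).reshape(n, c, oh, ow, k * k)
        self._argmax = win.argmax(axis=-1)
        self._xshape = x.shape
        return win.max(axis=-1)

    def backward(self, dout):
        k, s = self.window, self.stride
        n, c, h, w = self._xshape
        oh, ow = dout.shape[2], dout.shape[3]
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        for pos in range(k * k):
            i, j = divmod(pos, k)
            sel = self._argmax == pos
            if not sel.any():
                continue
            contrib = np.where(sel, dout, 0)
            dx[:, :, i:i + s * oh:s, j:j + s * ow:s] += contrib
        return dx


class LRN(Layer):
    """Local response normalization across channels (lateral inhibition).

    ``y_i = x_i / (k + (alpha / n) * sum_{j in window(i)} x_j^2)^beta`` with
    the window of ``n`` channels centered on ``i`` and clipped at the edges.
    Defaults are the classical k=2, n=5, alpha=1e-4, beta=0.75.
    """

    def __init__(self, n: int = 5, k: float = 2.0, alpha: float = 1e-4,
                 beta: float = 0.75) -> None:
        super().__init__()
        self.n, self.k, self.alpha, self.beta = n, k, alpha, beta

    def _window_sum(self, t: np.ndarray) -> np.ndarray:
        """Sum over the channel window, per channel (axis 1)."""
        c = t.shape[1]
        half = self.n // 2
        cs = np.cumsum(t, axis=1)
        out = np.empty_like(t)
        for i in range(c):
            lo, hi = max(0, i - half), min(c - 1, i + half)
            out[:, i] = cs[:, hi] - (cs[:, lo - 1] if lo > 0 else 0)
        return out

    def forward(self, x, train=False, rng=None):
        d = self.k + (self.alpha / self.n) * self._window_sum(x * x)
        self._x, self._d = x, d
        return x * d ** (-self.beta)

    def backward(self, dout):
        x, d, beta = self._x, self._d, self.beta
        inner = self._window_sum(dout * x * d ** (-beta - 1.0))
        return dout * d ** (-beta) - (2.0 * self.alpha * beta / self.n) * x * inner


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float = 0.5) -> None:
        super().__init__()
        if not (0 <= p < 1):
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.uniform(size=x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in),
                                      size=(n_in, n_out)).astype(dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    """A plain layer stack with explicit forward/backward."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        """Yields (layer_index, name, param, grad) for every trainable tensor."""
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield i, name, p, layer.grads.get(name)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": p.copy() for i, name, p, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, name, p, _ in self.parameters():
            p[...] = state[f"{i}.{name}"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits.

    ``targets`` are integer class indices.  Returns ``(loss, dlogits)``.
    """
    n = logits.shape[0]
    probs = softmax(logits)
    eps = np.finfo(probs.dtype).tiny
    loss = float(-np.log(probs[np.arange(n), targets] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adaptive-moment optimizer with bias correction."""

    def __init__(self, model: Sequential, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        if lr < 0:
            raise ValueError(f"learning rate must be non-negative, got {lr}")
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, name, p, g in self.model.parameters():
            if g is None:
                continue
            key = f"{i}.{name}"
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
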
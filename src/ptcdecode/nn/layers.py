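"""Layers with explicit forward/backward passes, float32 throughout.

Array convention: images are ``(N, C, H, W)``; dense activations are
``(N, features)``.  Each layer caches what its backward pass needs, so a
layer instance serves one forward/backward at a time (single-threaded
training loop).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class _BufferPool:
    """Reusable scratch arrays keyed by tag, resized on shape change.

    Avoids re-allocating (and page-faulting) the large im2col and shift
    buffers on every forward/backward call.
    """

    def __init__(self):
        self._store: dict = {}

    def get(self, tag: str, shape: tuple, zero: bool = False) -> np.ndarray:
        buf = self._store.get(tag)
        if buf is None or buf.shape != shape:
            buf = np.zeros(shape, dtype=DTYPE)
            self._store[tag] = buf
        elif zero:
            buf[...] = 0.0
        return buf


class Conv2d:
    """Stride-1 zero-padded 2-D convolution preserving spatial dims.

    Activations are channels-last ``(N, H, W, C)``; the weight matrix is
    stored as ``(kh*kw*in_channels, out_channels)`` with patch order
    (ky, kx, c), ready for GEMM.

    Two equivalent execution paths are used depending on shape: the usual
    im2col + single GEMM, and — when the layer has many input channels
    but few filters (the dimensionality-reduction conv) — a "fused shift"
    path that runs one GEMM over the padded plane and accumulates the
    kh·kw spatially shifted copies, which avoids materializing an im2col
    buffer kh·kw times the input size.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: tuple[int, int],
                 rng: np.random.Generator, name: str = "conv"):
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.w = Param(rng.normal(0, np.sqrt(2.0 / fan_in), (kh * kw * in_channels, out_channels)),
                       f"{name}.w")
        self.b = Param(np.zeros(out_channels), f"{name}.b")
        self._pool = _BufferPool()
        self._cols: np.ndarray | None = None
        self._xp: np.ndarray | None = None
        self._shape: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    @property
    def _fused(self) -> bool:
        return self.in_channels > 2 * self.out_channels

    def _pad(self, x: np.ndarray, tag: str) -> np.ndarray:
        n, h, w, c = x.shape
        kh, kw = self.kernel
        xp = self._pool.get(tag, (n, h + kh - 1, w + kw - 1, c))
        xp[:, kh // 2 : kh // 2 + h, kw // 2 : kw // 2 + w, :] = x
        return xp

    def _im2col(self, x: np.ndarray, tag: str) -> np.ndarray:
        n, h, w, c = x.shape
        kh, kw = self.kernel
        xp = self._pad(x, tag + ".pad")
        cols = self._pool.get(tag, (n, h, w, kh * kw * c))
        i = 0
        for ky in range(kh):
            for kx in range(kw):
                cols[..., i * c : (i + 1) * c] = xp[:, ky : ky + h, kx : kx + w, :]
                i += 1
        return cols.reshape(n * h * w, kh * kw * c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        kh, kw = self.kernel
        f = self.out_channels
        if self._fused:
            xp = self._pad(x, "fwd.pad.train" if train else "fwd.pad")
            hp, wp = h + kh - 1, w + kw - 1
            q = hp * wp
            # weight viewed as (c, kh*kw*f): one GEMM over every padded
            # position, then accumulate the 9 shifted writes
            wall = self.w.value.reshape(kh * kw, c, f).transpose(1, 0, 2).reshape(c, kh * kw * f)
            z = (xp.reshape(n * q, c) @ wall).reshape(n, q, kh * kw, f)
            yp = self._pool.get("fwd.acc", (n, q, f), zero=True)
            i = 0
            for ky in range(kh):
                for kx in range(kw):
                    off = ky * wp + kx
                    yp[:, : q - off] += z[:, off:, i]
                    i += 1
            y = yp.reshape(n, hp, wp, f)[:, :h, :w, :] + self.b.value
            if train:
                self._xp, self._shape = xp, x.shape
            return np.ascontiguousarray(y)
        cols = self._im2col(x, "fwd.cols.train" if train else "fwd.cols")
        y = cols @ self.w.value + self.b.value
        if train:
            # a training forward is always followed by its backward before
            # the next training forward, so the scratch cols stay valid
            self._cols, self._shape = cols, x.shape
        return y.reshape(n, h, w, f)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        kh, kw = self.kernel
        f = self.out_channels
        dy_r = dy.reshape(-1, f)
        self.b.grad += dy_r.sum(axis=0)
        if self._fused:
            hp, wp = h + kh - 1, w + kw - 1
            q = hp * wp
            # gsh[:, q, i] = dy (embedded in the padded plane) shifted by off_i
            g = self._pool.get("bwd.g", (n, q, f), zero=True)
            g.reshape(n, hp, wp, f)[:, :h, :w, :] = dy
            gsh = self._pool.get("bwd.gsh", (n, q, kh * kw * f), zero=True)
            i = 0
            for ky in range(kh):
                for kx in range(kw):
                    off = ky * wp + kx
                    gsh[:, off:, i * f : (i + 1) * f] = g[:, : q - off]
                    i += 1
            gsh_flat = gsh.reshape(n * q, kh * kw * f)
            dwall = self._xp.reshape(n * q, c).T @ gsh_flat  # (c, kh*kw*f)
            self.w.grad += dwall.reshape(c, kh * kw, f).transpose(1, 0, 2).reshape(
                kh * kw * c, f
            )
            wall = self.w.value.reshape(kh * kw, c, f).transpose(1, 0, 2).reshape(c, kh * kw * f)
            dxp = gsh_flat @ wall.T
            self._xp = None
            ph, pw = kh // 2, kw // 2
            return np.ascontiguousarray(
                dxp.reshape(n, hp, wp, c)[:, ph : ph + h, pw : pw + w, :]
            )
        self.w.grad += self._cols.T @ dy_r
        # dx = same-padded convolution of dy with the flipped, transposed kernel
        w4 = self.w.value.reshape(kh, kw, c, f)
        w2 = np.ascontiguousarray(w4[::-1, ::-1].transpose(0, 1, 3, 2)).reshape(kh * kw * f, c)
        dx = self._im2col(dy, "bwd.cols") @ w2
        self._cols = None
        return dx.reshape(n, h, w, c)


class BatchNorm2d:
    """Per-channel batch normalization over (N, H, W), channels-last."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Normalize ``x``; in train mode ``x`` is normalized in place
        (callers pass freshly computed activations they own)."""
        if train:
            mean = x.mean(axis=(0, 1, 2), dtype=np.float64).astype(DTYPE)
            var = x.var(axis=(0, 1, 2), dtype=np.float64).astype(DTYPE)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        if train:
            x -= mean
            x *= inv_std
            self._cache = (x, inv_std)
            return x * self.gamma.value + self.beta.value
        return (x - mean) * (inv_std * self.gamma.value) + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Consumes ``dy`` (modified in place) and returns dx in its place."""
        xhat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.gamma.grad += np.einsum("nhwc,nhwc->c", dy, xhat)
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dy *= self.gamma.value  # dy is now dxhat
        s1 = dy.sum(axis=(0, 1, 2))
        s2 = np.einsum("nhwc,nhwc->c", dy, xhat)
        dy -= s1 / m
        xhat *= s2 / m
        dy -= xhat
        dy *= inv_std
        self._cache = None
        return dy


class LeakyReLU:
    """Leaky rectifier, y = x for x > 0 else slope·x."""

    def __init__(self, slope: float = 0.3):
        self.slope = slope
        self._neg = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Applied in place in train mode (callers own their input)."""
        neg = x < 0
        if train:
            self._neg = neg
            np.multiply(x, self.slope, out=x, where=neg)
            return x
        return np.where(neg, self.slope * x, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        np.multiply(dy, self.slope, out=dy, where=self._neg)
        self._neg = None
        return dy


class Dense:
    """Fully-connected layer, ``y = x @ W + b``."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        self.w = Param(rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out)), f"{name}.w")
        self.b = Param(np.zeros(n_out), f"{name}.b")
        self._x = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value.T
        self._x = None
        return dx


class Dropout:
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(DTYPE) / (1 - self.p)
        x *= self._mask
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dy *= self._mask
        self._mask = None
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits for integer targets."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, (dlogits / n).astype(DTYPE, copy=False)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
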
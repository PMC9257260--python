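"""Minimal reverse-mode neural-network layers on numpy.

Tensors are channels-last: images are ``(batch, H, W, C)`` and dense
activations ``(batch, features)``.  Every layer caches what its backward
pass needs during ``forward`` and exposes its trainable arrays through
:meth:`Layer.params` as ``Param`` records that the optimizer updates in
place.  All arithmetic is float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

F32 = np.float32


@dataclass
class Param:
    """A trainable array and its gradient."""

    value: np.ndarray
    name: str = ""
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    train: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def set_mode(self, train: bool) -> None:
        self.train = train


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv2d(Layer):
    """Same-padded stride-1 2-D convolution (channels-last).

    Implemented as k*k shifted matrix products: the weight is stored as
    ``(k*k, c_in, c_out)`` and each kernel offset contributes one
    ``(B*H*W, c_in) @ (c_in, c_out)`` BLAS call accumulated into the
    output.  This keeps every copy contiguous, which on small channel
    counts beats a monolithic im2col.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.w = Param(_he_init(rng, (kernel * kernel, c_in, c_out), kernel * kernel * c_in), "conv.w")
        self.b = Param(np.zeros(c_out, dtype=F32), "conv.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _row_block(self, xp: np.ndarray, di: int, h: int, w: int) -> np.ndarray:
        """Contiguous (B*H*W, k*c_in) slab for one row offset: columns are
        the (dj, channel) pairs, which are adjacent in memory, so the copy
        runs in k*c_in-wide chunks."""
        b = xp.shape[0]
        xr = xp[:, di:di + h, :, :]
        s = xr.strides
        v = np.lib.stride_tricks.as_strided(
            xr, shape=(b, h, w, self.k * self.c_in),
            strides=(s[0], s[1], s[3] * self.c_in, s[3]))
        return np.ascontiguousarray(v).reshape(b * h * w, self.k * self.c_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        self._shape = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(np.asarray(x, dtype=F32), ((0, 0), (p, p), (p, p), (0, 0)))
        wr = self.w.value.reshape(k, k * c, self.c_out)
        self._blocks = [self._row_block(xp, di, h, w) for di in range(k)]
        out = np.broadcast_to(self.b.value, (b * h * w, self.c_out)).copy()
        for di in range(k):
            out += self._blocks[di] @ wr[di]
        return out.reshape(b, h, w, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        k, p = self.k, self.k // 2
        g = grad.reshape(b * h * w, self.c_out)
        self.b.grad[...] = g.sum(axis=0)
        gw = self.w.grad.reshape(k, k * c, self.c_out)
        wr = self.w.value.reshape(k, k * c, self.c_out)
        gxp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=F32)
        for di in range(k):
            gw[di] = self._blocks[di].T @ g
            gcol = (g @ wr[di].T).reshape(b, h, w, k, c)
            for dj in range(k):
                gxp[:, di:di + h, dj:dj + w, :] += gcol[:, :, :, dj, :]
        return np.ascontiguousarray(gxp[:, p:p + h, p:p + w, :])


class BatchNorm(Layer):
    """Per-channel batch normalization (last axis), with running stats."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=F32), "bn.gamma")
        self.beta = Param(np.zeros(c, dtype=F32), "bn.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if self.train:
            mean = x.mean(axis=axes)
            xc = x - mean.astype(F32)
            flat = xc.reshape(-1, x.shape[-1])
            var = np.einsum('nc,nc->c', flat, flat) / flat.shape[0]
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
            xc = x - mean.astype(F32)
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xc *= self._istd
        self._xhat = xc
        self._n = x.size // x.shape[-1]
        out = xc * self.gamma.value
        out += self.beta.value
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = tuple(range(grad.ndim - 1))
        self.gamma.grad[...] = (grad * self._xhat).sum(axis=axes)
        self.beta.grad[...] = grad.sum(axis=axes)
        if not self.train:
            return grad * self.gamma.value * self._istd
        gxhat = grad * self.gamma.value
        n = self._n
        return (self._istd / n) * (
            n * gxhat
            - gxhat.sum(axis=axes)
            - self._xhat * (gxhat * self._xhat).sum(axis=axes)
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(_he_init(rng, (n_in, n_out), n_in), "dense.w")
        self.b = Param(np.zeros(n_out, dtype=F32), "dense.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad[...] = self._x.T @ grad
        self.b.grad[...] = grad.sum(axis=0)
        return grad @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def set_mode(self, train: bool) -> None:
        for layer in self.layers:
            layer.set_mode(train)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ResidualBlock(Layer):
    """y = F(x) + shortcut(x) with F = BN(conv2(relu(BN(conv1 x)))).

    The shortcut is the identity when channel counts match and a 1x1
    projection (conv + BN) otherwise.  No activation follows the
    addition, so a block with all-zero conv weights and zero BN scale is
    exactly the identity.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.body = Sequential(
            Conv2d(c_in, c_out, kernel, rng),
            BatchNorm(c_out),
            ReLU(),
            Conv2d(c_out, c_out, kernel, rng),
            BatchNorm(c_out),
        )
        if c_in == c_out:
            self.shortcut: Layer | None = None
        else:
            self.shortcut = Sequential(Conv2d(c_in, c_out, 1, rng), BatchNorm(c_out))

    def params(self) -> list[Param]:
        ps = self.body.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def set_mode(self, train: bool) -> None:
        self.body.set_mode(train)
        if self.shortcut is not None:
            self.shortcut.set_mode(train)

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.body.forward(x)
        s = x if self.shortcut is None else self.shortcut.forward(x)
        return f + s

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = self.body.backward(grad)
        if self.shortcut is None:
            return gx + grad
        return gx + self.shortcut.backward(grad)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
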
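"""Minimal NumPy neural-network engine.

Implements exactly the layer set the defect-inspection network needs —
same-padded 2-D convolution, 2x2/stride-2 transposed convolution, 2x2
max-pooling, batch normalization, ReLU, a fully connected layer — together
with manual reverse-mode gradients, cross-entropy / binary cross-entropy
losses, and plain stochastic gradient descent with coupled L2 weight decay.

Tensors are ``float32`` arrays in ``(N, C, H, W)`` layout. Every layer caches
what its backward pass needs during ``forward``; ``backward`` consumes the
gradient w.r.t. the layer output and returns the gradient w.r.t. the input,
accumulating parameter gradients into ``Param.grad``. All gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DTYPE = np.float32


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: layers expose ``params()`` plus forward/backward."""

    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) patch matrix for stride-1 same conv."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for a in range(k):
        for b in range(k):
            cols[:, :, a, b] = x[:, :, a : a + h, b : b + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, h, w)
    for a in range(k):
        for b in range(k):
            dxp[:, :, a : a + h, b : b + w] += d[:, :, a, b]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Layer):
    """Same-padded, stride-1 convolution.

    ``role`` tags the layer for the architecture census: ``"counted"`` for the
    convolutions the network description enumerates, ``"mask"`` for the
    additional mask projection, ``"proj"``/``"fusion"`` for attention heads.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 role: str = "counted", init_std: float = 0.01):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.pad = kernel // 2
        self.role = role
        self.weight = Param(rng.normal(0.0, init_std, size=(c_out, c_in * kernel * kernel)))
        self.bias = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        cols = _im2col(x, self.kernel, self.pad)
        out = np.matmul(self.weight.value[None], cols)
        out += self.bias.value[None, :, None]
        self._cache = (x.shape, cols)
        return out.reshape(n, self.c_out, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xshape, cols = self._cache
        n, _, h, w = xshape
        d = dout.reshape(n, self.c_out, h * w)
        self.bias.grad += d.sum(axis=(0, 2))
        self.weight.grad += np.einsum("nop,ncp->oc", d, cols, optimize=True)
        dcols = np.matmul(self.weight.value.T[None], d)
        return _col2im(dcols, xshape, self.kernel, self.pad)


class ConvTranspose2d(Layer):
    """2x2, stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 init_std: float = 0.01):
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(rng.normal(0.0, init_std, size=(c_in, c_out, 2, 2)))
        self.bias = Param(np.zeros(c_out))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        y = np.einsum("nchw,cdab->ndhawb", x, self.weight.value, optimize=True)
        y = y.reshape(n, self.c_out, 2 * h, 2 * w)
        y += self.bias.value[None, :, None, None]
        self._x = x
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        d6 = dout.reshape(n, self.c_out, h, 2, w, 2)
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        self.weight.grad += np.einsum("nchw,ndhawb->cdab", x, d6, optimize=True)
        return np.einsum("ndhawb,cdab->nchw", d6, self.weight.value, optimize=True)


class MaxPool2d(Layer):
    """2x2 max-pooling, stride 2; ties route the gradient to the first max."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (n, c, h, w), idx = self._cache
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# batch normalization


@dataclass
class BNState:
    """Per-channel batch-normalization state.

    ``mode`` selects mini-batch statistics (train) or the running estimate of
    the whole training set (eval). Running statistics are an exponential
    moving average of the mini-batch statistics.
    """

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    epsilon: float = 1e-5
    momentum: float = 0.1
    mode: str = "train"

    @classmethod
    def create(cls, channels: int, epsilon: float = 1e-5) -> "BNState":
        return cls(
            gamma=np.ones(channels, dtype=DTYPE),
            beta=np.zeros(channels, dtype=DTYPE),
            running_mean=np.zeros(channels, dtype=DTYPE),
            running_var=np.ones(channels, dtype=DTYPE),
            epsilon=epsilon,
        )


def batch_normalize(batch: np.ndarray, state: BNState) -> np.ndarray:
    """Normalize a mini-batch per channel: x_hat = (x - mu_B)/sqrt(var_B + eps),
    then y = gamma * x_hat + beta.

    ``batch`` is ``(m, C)`` or ``(N, C, H, W)``; statistics are taken over every
    axis except the channel axis, with the biased (1/m) variance. In train mode
    the running statistics are updated; in eval mode the running statistics
    are used instead of the mini-batch ones.
    """
    if batch.ndim == 2:
        axes = (0,)
        expand = (slice(None), slice(None))
        m = batch.shape[0]
    elif batch.ndim == 4:
        axes = (0, 2, 3)
        expand = (None, slice(None), None, None)
        m = batch.shape[0] * batch.shape[2] * batch.shape[3]
    else:
        raise ValueError("batch must be (m, C) or (N, C, H, W)")
    if m == 0:
        raise ValueError("empty mini-batch")

    def per_channel(v):
        if batch.ndim == 2:
            return v[None, :]
        return v[None, :, None, None]

    if state.mode == "train":
        mu = batch.mean(axis=axes)
        var = batch.var(axis=axes)  # biased
        state.running_mean[...] = (1 - state.momentum) * state.running_mean + state.momentum * mu
        state.running_var[...] = (1 - state.momentum) * state.running_var + state.momentum * var
    else:
        mu, var = state.running_mean, state.running_var
    xhat = (batch - per_channel(mu)) / np.sqrt(per_channel(var) + state.epsilon)
    return per_channel(state.gamma) * xhat + per_channel(state.beta)


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) per channel, with learned gamma/beta."""

    def __init__(self, channels: int, epsilon: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.epsilon = epsilon
        self.momentum = momentum
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.epsilon)
        xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd, train, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not train:
            return dxhat * invstd[None, :, None, None]
        # full train-mode gradient (statistics depend on the input)
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


# ---------------------------------------------------------------------------
# pointwise / dense


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(x, 0)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_std: float = 0.01):
        self.n_in, self.n_out = n_in, n_out
        self.weight = Param(rng.normal(0.0, init_std, size=(n_out, n_in)))
        self.bias = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value[None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


# ---------------------------------------------------------------------------
# losses (each returns (loss, grad_wrt_logits))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray,
                          class_axis: int = 1) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over all positions.

    ``logits``: (N, K) with class_axis=1, or (N, K, H, W); ``target``: integer
    class indices of matching spatial shape.
    """
    p = softmax(logits.astype(np.float64), axis=class_axis)
    onehot = np.moveaxis(np.eye(logits.shape[class_axis])[target], -1, class_axis)
    count = target.size
    eps = 1e-12
    loss = -(onehot * np.log(p + eps)).sum() / count
    grad = ((p - onehot) / count).astype(DTYPE)
    return float(loss), grad


def bce_with_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on sigmoid(logits) vs a {0,1} target."""
    z = logits.astype(np.float64)
    # log(1+exp(-|z|)) formulation, numerically stable
    loss = (np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))).mean()
    grad = ((sigmoid(z) - target) / z.size).astype(DTYPE)
    return float(loss), grad


# ---------------------------------------------------------------------------
# optimizer


class SGD:
    """Plain gradient descent (no momentum) with coupled L2 weight decay.

    Weight decay is applied to convolution/linear weights only, not to biases
    or batch-norm scale/shift (``decay_mask`` selects which params decay).
    """

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0,
                 decay_mask: list[bool] | None = None):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.decay_mask = decay_mask if decay_mask is not None else [True] * len(params)

    def step(self) -> None:
        for p, decay in zip(self.params, self.decay_mask):
            g = p.grad
            if self.weight_decay and decay:
                g = g + self.weight_decay * p.value
            p.value -= (self.lr * g).astype(DTYPE)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
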
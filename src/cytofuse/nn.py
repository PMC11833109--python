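"""Minimal feed-forward neural-network core on numpy.

Implements exactly the pieces the CAE classifiers need: stride-1
same-padded 2D/3D convolution, non-overlapping max-pooling, transposed
convolution with kernel == stride (the exact mirror of the pooling
steps), dense layers, ReLU/sigmoid, and Adam.  Every layer caches its
forward inputs and accumulates parameter gradients on ``backward``;
``Sequential`` chains layers.  All initialization is driven by an
explicit ``numpy.random.Generator`` so models are bit-reproducible
given a seed.

Shapes follow the NCHW / NCDHW convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, InputError


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value.astype(np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    params: list[Param]

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "dense"):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(f"{name}.W", rng.normal(0.0, scale, (n_in, n_out)))
        self.b = Param(f"{name}.b", np.zeros(n_out))
        self.params = [self.W, self.b]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Reshape(Layer):
    """Reshape the per-sample part to a fixed shape (inverse of Flatten)."""

    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(grad.shape[0], -1)


class ConvND(Layer):
    """Stride-1 convolution with 'same' zero padding, 2D or 3D."""

    def __init__(self, ndim: int, c_in: int, c_out: int,
                 rng: np.random.Generator, kernel: int = 3,
                 name: str = "conv"):
        super().__init__()
        if kernel % 2 != 1:
            raise ConfigurationError("kernel: same-padding needs odd size")
        self.ndim = ndim
        self.kernel = kernel
        self.pad = kernel // 2
        kshape = (c_out, c_in) + (kernel,) * ndim
        fan_in = c_in * kernel**ndim
        self.W = Param(f"{name}.W",
                       rng.normal(0.0, np.sqrt(2.0 / fan_in), kshape))
        self.b = Param(f"{name}.b", np.zeros(c_out))
        self.params = [self.W, self.b]
        if ndim == 2:
            self._fw = "nchwij,ocij->nohw"
            self._dw = "nchwij,nohw->ocij"
            self._dx = "nohwij,ocij->nchw"
        elif ndim == 3:
            self._fw = "ncdhwijk,ocijk->nodhw"
            self._dw = "ncdhwijk,nodhw->ocijk"
            self._dx = "nodhwijk,ocijk->ncdhw"
        else:
            raise ConfigurationError("ndim: only 2 and 3 supported")

    def _windows(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        pads = [(0, 0), (0, 0)] + [(p, p)] * self.ndim
        xp = np.pad(x, pads)
        axes = tuple(range(2, 2 + self.ndim))
        return sliding_window_view(xp, (self.kernel,) * self.ndim, axis=axes)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._win = self._windows(x)
        out = np.einsum(self._fw, self._win, self.W.value, optimize=True)
        bshape = (1, -1) + (1,) * self.ndim
        return out + self.b.value.reshape(bshape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += np.einsum(self._dw, self._win, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0,) + tuple(range(2, 2 + self.ndim)))
        # full correlation of grad with the flipped kernel
        flip = tuple(slice(None, None, -1) for _ in range(self.ndim))
        Wf = self.W.value[(slice(None), slice(None)) + flip]
        p = self.kernel - 1 - self.pad
        pads = [(0, 0), (0, 0)] + [(p, p)] * self.ndim
        gp = np.pad(grad, pads)
        axes = tuple(range(2, 2 + self.ndim))
        gwin = sliding_window_view(gp, (self.kernel,) * self.ndim, axis=axes)
        return np.einsum(self._dx, gwin, Wf, optimize=True)


def Conv2d(c_in, c_out, rng, kernel=3, name="conv2d"):
    return ConvND(2, c_in, c_out, rng, kernel, name)


def Conv3d(c_in, c_out, rng, kernel=3, name="conv3d"):
    return ConvND(3, c_in, c_out, rng, kernel, name)


class MaxPoolND(Layer):
    """Non-overlapping max pooling with a per-axis factor tuple."""

    def __init__(self, factor: tuple[int, ...]):
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        spatial = x.shape[2:]
        if len(spatial) != len(f):
            raise InputError("pool factor rank does not match input rank")
        for s, k in zip(spatial, f):
            if s % k != 0:
                raise InputError(
                    f"spatial size {s} not divisible by pool factor {k}")
        self._xshape = x.shape
        # split every spatial axis into (blocks, factor)
        newshape = x.shape[:2]
        for s, k in zip(spatial, f):
            newshape += (s // k, k)
        xr = x.reshape(newshape)
        # move all factor axes to the end
        nd = len(spatial)
        block_axes = tuple(2 + 2 * i for i in range(nd))
        factor_axes = tuple(3 + 2 * i for i in range(nd))
        perm = (0, 1) + block_axes + factor_axes
        xt = xr.transpose(perm)
        flat = xt.reshape(xt.shape[:2 + nd] + (-1,))
        self._argmax = flat.argmax(axis=-1)
        self._flat_shape = flat.shape
        return np.take_along_axis(
            flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        nd = len(self.factor)
        gflat = np.zeros(self._flat_shape)
        np.put_along_axis(gflat, self._argmax[..., None],
                          grad[..., None], axis=-1)
        # invert the transpose/reshape of forward
        spatial = self._xshape[2:]
        blocks = tuple(s // k for s, k in zip(spatial, self.factor))
        gt = gflat.reshape(gflat.shape[:2 + nd] + tuple(self.factor))
        # axes currently: n, c, blocks..., factors... -> interleave
        perm = [0, 1]
        for i in range(nd):
            perm += [2 + i, 2 + nd + i]
        g = gt.transpose(perm).reshape(self._xshape)
        return g


class ConvTransposeND(Layer):
    """Transposed convolution with kernel == stride (exact upsampling)."""

    def __init__(self, ndim: int, c_in: int, c_out: int,
                 factor: tuple[int, ...], rng: np.random.Generator,
                 name: str = "convT"):
        super().__init__()
        if len(factor) != ndim:
            raise ConfigurationError("factor: rank must equal ndim")
        self.ndim = ndim
        self.factor = factor
        kshape = (c_in, c_out) + tuple(factor)
        fan_in = c_in
        self.W = Param(f"{name}.W",
                       rng.normal(0.0, np.sqrt(2.0 / fan_in), kshape))
        self.b = Param(f"{name}.b", np.zeros(c_out))
        self.params = [self.W, self.b]
        if ndim == 2:
            self._fw = "nchw,coij->nohiwj"
            self._dx = "nohiwj,coij->nchw"
            self._dw = "nchw,nohiwj->coij"
        else:
            self._fw = "ncdhw,coijk->nodihjwk"
            self._dx = "nodihjwk,coijk->ncdhw"
            self._dw = "ncdhw,nodihjwk->coijk"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.einsum(self._fw, x, self.W.value, optimize=True)
        n, c_out = x.shape[0], self.W.value.shape[1]
        out_spatial = tuple(s * k for s, k in zip(x.shape[2:], self.factor))
        y = y.reshape((n, c_out) + out_spatial)
        bshape = (1, -1) + (1,) * self.ndim
        return y + self.b.value.reshape(bshape)

    def _block_view(self, grad: np.ndarray) -> np.ndarray:
        n, c_out = grad.shape[:2]
        shape = (n, c_out)
        for s, k in zip(self._x.shape[2:], self.factor):
            shape += (s, k)
        return grad.reshape(shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g6 = self._block_view(grad)
        self.W.grad += np.einsum(self._dw, self._x, g6, optimize=True)
        self.b.grad += grad.sum(
            axis=(0,) + tuple(range(2, 2 + self.ndim)))
        return np.einsum(self._dx, g6, self.W.value, optimize=True)


def ConvTranspose2d(c_in, c_out, factor, rng, name="convT2d"):
    return ConvTransposeND(2, c_in, c_out, tuple(factor), rng, name)


def ConvTranspose3d(c_in, c_out, factor, rng, name="convT3d"):
    return ConvTransposeND(3, c_in, c_out, tuple(factor), rng, name)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        self.params = [p for layer in layers for p in layer.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimizer with standard bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
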
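"""Layers and optimiser used by the generator, critic and benchmark CNN.

All parameters are float32 :class:`~tgand._autodiff.Tensor` leaves; layers
are plain objects with a ``__call__`` building the graph and a ``params()``
listing trainable tensors in a stable order (which makes checkpoints and
parameter hashing deterministic).
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor


class Module:
    """Base class: parameter collection and (de)serialisation."""

    def params(self) -> list[Tensor]:
        out = []
        for name in self._param_names():
            out.append(getattr(self, name))
        for child in self._children():
            out.extend(child.params())
        return out

    def _param_names(self):
        return ()

    def _children(self):
        return ()

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays needed to restore the module (params + buffers)."""
        out = [p.data for p in self.params()]
        for child in self._children():
            out.extend(child._buffers())
        out.extend(self._buffers())
        return out

    def _buffers(self):
        return []

    def set_training(self, flag: bool):
        for child in self._children():
            child.set_training(flag)
        self.training = flag


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale: float = 0.02):
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def _param_names(self):
        return ("W", "b")

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.W), self.b)


class Conv2d(Module):
    """Strided convolution, kernel 4, 'half' padding: side -> side/stride."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 4, stride: int = 2, padding: int = 1, scale: float = 0.02):
        self.stride, self.padding = stride, padding
        self.W = Tensor(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)).astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def _param_names(self):
        return ("W", "b")

    def __call__(self, x: Tensor) -> Tensor:
        out = ad.conv2d(x, self.W, self.stride, self.padding)
        return ad.add(out, ad.reshape(self.b, (1, -1, 1, 1)))


class ConvTranspose2d(Module):
    """Stride-2 transposed convolution (kernel 4, padding 1): side -> 2*side.

    Implemented as the adjoint of the matching strided convolution, so its
    weight has the convolution layout (c_in, c_out, k, k).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 4, stride: int = 2, padding: int = 1, scale: float = 0.02):
        self.stride, self.padding, self.kernel = stride, padding, kernel
        self.c_out = c_out
        self.W = Tensor(rng.normal(0.0, scale, size=(c_in, c_out, kernel, kernel)).astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def _param_names(self):
        return ("W", "b")

    def __call__(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        out_shape = (n, self.c_out, h * self.stride, w * self.stride)
        out = ad.conv2d_input_grad(x, self.W, self.stride, self.padding, out_shape)
        return ad.add(out, ad.reshape(self.b, (1, -1, 1, 1)))


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics for eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.training = True

    def _param_names(self):
        return ("gamma", "beta")

    def _buffers(self):
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ad.batch_norm(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.astype(np.float32)
            self.running_var = m * self.running_var + (1 - m) * var.astype(np.float32)
            return out
        mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
        var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        inv = ad.power(ad.add(var, Tensor(np.float32(self.eps))), -0.5)
        xhat = ad.mul(ad.sub(x, mu), inv)
        return ad.add(
            ad.mul(xhat, ad.reshape(self.gamma, (1, -1, 1, 1))),
            ad.reshape(self.beta, (1, -1, 1, 1)),
        )


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator, scale: float = 0.02):
        self.W = Tensor(rng.normal(0.0, scale, size=(n, dim)).astype(np.float32), requires_grad=True)

    def _param_names(self):
        return ("W",)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return ad.index_rows(self.W, idx)


class Sequentialish(Module):
    """Container whose children are listed explicitly by subclasses."""


class RMSprop:
    """RMSprop with the classic 0.9 decay (the WGAN training optimiser)."""

    def __init__(self, params: list[Tensor], lr: float = 5e-5, rho: float = 0.9, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: list[Tensor]):
        for p, v, g in zip(self.params, self.v, grads):
            gd = g.data
            if not np.all(np.isfinite(gd)):
                raise FloatingPointError("non-finite gradient encountered")
            v *= self.rho
            v += (1.0 - self.rho) * gd * gd
            p.data -= (self.lr * gd / (np.sqrt(v) + self.eps)).astype(p.data.dtype)


def count_norm_params(module: Module) -> int:
    """Number of normalisation-layer parameter tensors (census for audits)."""
    n = 0
    stack = [module]
    while stack:
        m = stack.pop()
        if isinstance(m, BatchNorm2d):
            n += 2
        stack.extend(m._children())
    return n


def params_digest(params: list[Tensor]) -> str:
    """Order-sensitive digest of parameter bytes (frozen-network audits)."""
    import hashlib

    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()
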
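"""Minimal neural-network layers with explicit forward/backward passes.

The design is deliberately functional: ``forward`` returns ``(output, cache)``
and ``backward`` consumes that cache, so the same module can be applied several
times within one training step (the contrastive objective re-runs the encoder
on generated images) without caches clobbering each other.  Parameter
gradients accumulate into ``Parameter.grad``; callers zero them between steps.

All arithmetic is float64.  The networks used here are small enough that the
extra precision is cheap, and it makes the finite-difference gradient checks
and the exact-blending guarantees straightforward.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .functional import col2im, conv_out_size, im2col

_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the dtype used for newly created parameters (float64 or float32).

    float64 is the default: the networks here are small and full precision
    keeps gradient checks and exact-blending guarantees trivial.  float32
    roughly halves training time for throwaway experiments.
    """
    global _DEFAULT_DTYPE
    dtype = np.dtype(dtype).type
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE = dtype


def get_default_dtype():
    return _DEFAULT_DTYPE


class Parameter:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: tracks child modules and parameters by attribute name."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data[...] = arr

    def __call__(self, x):
        return self.forward(x)


def normal_init(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return rng.normal(0.0, std, size=shape)


class Conv2d(Module):
    """k x k convolution, stride s, zero padding p (cross-correlation form)."""

    def __init__(self, cin, cout, k, stride, pad, rng, bias=True, init_std=0.02):
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.weight = Parameter(normal_init(rng, (cout, cin * k * k), init_std))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        cols = im2col(x, self.k, self.stride, self.pad)
        y = np.matmul(self.weight.data, cols)
        if self.bias is not None:
            y += self.bias.data[:, None]
        ho = conv_out_size(h, self.k, self.stride, self.pad)
        wo = conv_out_size(w, self.k, self.stride, self.pad)
        y = y.reshape(n, self.cout, ho, wo)
        return y, (x.shape, cols)

    def backward(self, cache, dy):
        x_shape, cols = cache
        n = dy.shape[0]
        dy_flat = dy.reshape(n, self.cout, -1)
        self.weight.grad += np.matmul(dy_flat, cols.transpose(0, 2, 1)).sum(axis=0)
        if self.bias is not None:
            self.bias.grad += dy_flat.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.data.T, dy_flat)
        return col2im(dcols, x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Module):
    """Transposed (fractionally-strided) convolution, the adjoint of Conv2d."""

    def __init__(self, cin, cout, k, stride, pad, rng, bias=True, init_std=0.02):
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        # weight laid out (cin, cout*k*k): forward scatters, backward gathers
        self.weight = Parameter(normal_init(rng, (cin, cout * k * k), init_std))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def out_size(self, size: int) -> int:
        return (size - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        x_flat = x.reshape(n, c, h * w)
        cols = np.matmul(self.weight.data.T, x_flat)
        ho, wo = self.out_size(h), self.out_size(w)
        y = col2im(cols, (n, self.cout, ho, wo), self.k, self.stride, self.pad)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        return y, (x_flat, (n, self.cout, ho, wo))

    def backward(self, cache, dy):
        x_flat, _ = cache
        n = dy.shape[0]
        dcols = im2col(dy, self.k, self.stride, self.pad)
        self.weight.grad += np.matmul(x_flat, dcols.transpose(0, 2, 1)).sum(axis=0)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx_flat = np.matmul(self.weight.data, dcols)
        h = int(round(np.sqrt(x_flat.shape[2])))
        return dx_flat.reshape(n, self.cin, h, x_flat.shape[2] // h)


class InstanceNorm2d(Module):
    """Per-image, per-channel normalization over the spatial axes (no affine)."""

    def __init__(self, channels, eps=1e-5):
        super().__init__()
        self.channels = channels
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        return xhat, (xhat, inv_std)

    def backward(self, cache, dy):
        xhat, inv_std = cache
        m1 = dy.mean(axis=(2, 3), keepdims=True)
        m2 = (dy * xhat).mean(axis=(2, 3), keepdims=True)
        return inv_std * (dy - m1 - xhat * m2)


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, cache, dy):
        return np.where(cache, dy, self.slope * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Module):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, cache, dy):
        return dy * (1.0 - cache * cache)


class Linear(Module):
    def __init__(self, cin, cout, rng, bias=True, init_std=0.02):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.weight = Parameter(normal_init(rng, (cout, cin), init_std))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        y = x @ self.weight.data.T
        if self.bias is not None:
            y = y + self.bias.data
        return y, x

    def backward(self, cache, dy):
        x = cache
        self.weight.grad += dy.reshape(-1, self.cout).T @ x.reshape(-1, self.cin)
        if self.bias is not None:
            self.bias.grad += dy.reshape(-1, self.cout).sum(axis=0)
        return dy @ self.weight.data


class Sequential(Module):
    """A plain chain of modules sharing the (output, cache) protocol."""

    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(c, dy)
        return dy


def count_parameters(module: Module) -> int:
    """Total number of trainable scalar parameters in a module tree."""
    return int(sum(p.size for p in module.parameters()))
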
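"""Neural-network layers on top of :mod:`seamseg.autograd`.

Modules follow the familiar container pattern: parameters are registered by
attribute assignment, ``parameters()`` walks the tree in deterministic
order, and ``state_dict``/``load_state_dict`` move weights as flat
name → ndarray mappings (so checkpoints are plain ``.npz`` files).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class; submodules and parameters register via ``__setattr__``."""

    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- serialization -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_buffers():
            state[name] = m.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{own[name].data.shape} vs {arr.shape}")
                own[name].data = np.array(arr, dtype=own[name].data.dtype)
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected key in state dict: {name}")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")

    def _named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m._named_buffers(prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
        self._layers = layers

    def forward(self, x: Tensor) -> Tensor:
        for layer in self._layers:
            x = layer(x)
        return x


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    """Stride-1 convolution with 'same' padding when padding = k//2."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: int | None = None,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        if padding is None:
            padding = kernel // 2
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel),
                                         fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, padding: int | None = None,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        if padding is None:
            padding = kernel // 2
        self.padding = padding
        self.weight = Parameter(_he_init(rng, (channels, kernel, kernel),
                                         kernel * kernel, dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_init(rng, (out_features, in_features),
                                         in_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.matmul(x, ag.Tensor(self.weight.data.T, requires_grad=False)) \
            if not self.weight.requires_grad else ag.matmul(x, _transpose(self.weight))
        if self.bias is not None:
            out = out + self.bias
        return out


def _transpose(t: Tensor) -> Tensor:
    out = ag.Tensor(t.data.T, requires_grad=t.requires_grad,
                    _parents=(t,) if t.requires_grad else (),
                    _backward=None)
    if t.requires_grad:
        def backward(g):
            t._accumulate(g.T)
        out._backward = backward
    return out


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel with running statistics."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        object.__setattr__(self, "running_mean", np.zeros(channels, dtype=np.float64))
        object.__setattr__(self, "running_var", np.ones(channels, dtype=np.float64))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ag.batchnorm2d(x, self.gamma, self.beta, self.eps)
            self.running_mean[...] = ((1 - self.momentum) * self.running_mean
                                      + self.momentum * mu)
            self.running_var[...] = ((1 - self.momentum) * self.running_var
                                     + self.momentum * var)
            return out
        mu = self.running_mean.astype(x.dtype).reshape(1, -1, 1, 1)
        sd = np.sqrt(self.running_var + self.eps).astype(x.dtype).reshape(1, -1, 1, 1)
        xhat = (x - ag.as_tensor(mu)) * ag.as_tensor(1.0 / sd)
        g = ag.reshape(self.gamma, (1, -1, 1, 1))
        b = ag.reshape(self.beta, (1, -1, 1, 1))
        return xhat * g + b


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.gelu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.maxpool2x2(x)


class UpsampleBilinear2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.upsample_bilinear2x(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
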
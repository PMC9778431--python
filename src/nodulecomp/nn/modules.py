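"""Layer/module abstractions over the autodiff primitives.

Mirrors the usual NN-library surface (``Module``, ``Conv2d``, ``BatchNorm2d``,
``Sequential`` ...) at the minimal size this package needs.  Construction is
deterministic: every parameterized layer draws its initial weights from the
``rng`` it is given.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module", "Identity", "ReLU", "Sigmoid", "Conv2d", "BatchNorm2d",
    "MaxPool2d", "AvgPool2d", "Sequential", "ConvBNReLU", "ConvReLU",
]


class Module:
    """Base class: child tracking, parameter iteration, state dicts."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> Iterator[Tensor]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- serialization --------------------------------------------------------

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for k, v in self._params.items():
            out[prefix + k] = v.data
        for k, v in self._buffers.items():
            out[prefix + k] = v
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self._params.items():
            key = prefix + k
            if key not in state:
                raise KeyError(f"missing parameter {key!r} in checkpoint")
            if state[key].shape != v.data.shape:
                raise ValueError(f"shape mismatch for {key!r}: "
                                 f"{state[key].shape} vs {v.data.shape}")
            v.data = np.asarray(state[key], dtype=v.data.dtype)
        for k in self._buffers:
            key = prefix + k
            buf = np.asarray(state[key])
            self._buffers[k][...] = buf
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Conv2d(Module):
    """He-initialized 2-D convolution."""

    def __init__(self, cin: int, cout: int, kernel, stride=1, padding=0,
                 dilation=1, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        std = np.sqrt(2.0 / (cin * kh * kw))
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, kh, kw))
                             .astype(np.float32), requires_grad=True)
        self.bias = (Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
                     if bias else None)
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride,
                        self.padding, self.dilation)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(c, dtype=np.float32)
        self._buffers["running_var"] = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.gamma, self.beta,
                              self._buffers["running_mean"],
                              self._buffers["running_var"],
                              self.training, self.momentum, self.eps)


class MaxPool2d(Module):
    def __init__(self, kernel, stride=None, padding=0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel, stride=None):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x: Tensor) -> Tensor:
        return F.avg_pool2d(x, self.kernel, self.stride)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, m in enumerate(layers):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.layers:
            x = m(x)
        return x

    def __getitem__(self, i: int) -> Module:
        return self.layers[i]


def _same_padding(kernel, dilation) -> tuple[int, int]:
    kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
    dh, dw = (dilation, dilation) if np.isscalar(dilation) else dilation
    return (dh * (kh - 1) // 2, dw * (kw - 1) // 2)


def ConvBNReLU(cin: int, cout: int, kernel=3, stride=1, padding=None,
               dilation=1, *, rng: np.random.Generator) -> Sequential:
    if padding is None:
        padding = _same_padding(kernel, dilation)
    return Sequential(
        Conv2d(cin, cout, kernel, stride, padding, dilation, bias=False, rng=rng),
        BatchNorm2d(cout),
        ReLU(),
    )


def ConvReLU(cin: int, cout: int, kernel=3, stride=1, padding=None,
             dilation=1, *, rng: np.random.Generator) -> Sequential:
    if padding is None:
        padding = _same_padding(kernel, dilation)
    return Sequential(
        Conv2d(cin, cout, kernel, stride, padding, dilation, bias=True, rng=rng),
        ReLU(),
    )
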
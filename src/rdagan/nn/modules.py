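"""Layer/module abstractions over the autodiff tensors.

Every module takes a ``numpy.random.Generator`` at construction so weight
initialization is fully determined by the caller's seed; there is no global
RNG state anywhere in the package.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import DEFAULT_DTYPE, Tensor


class Parameter(Tensor):
    def __init__(self, data, requires_grad: bool = True):
        super().__init__(np.asarray(data, dtype=DEFAULT_DTYPE),
                         requires_grad=requires_grad)


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, gain: float = np.sqrt(2.0)) -> np.ndarray:
    """He fan-in initialization (std = gain / sqrt(fan_in))."""
    std = gain / np.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape).astype(DEFAULT_DTYPE)


class Module:
    """Minimal container: tracks parameters, buffers and submodules."""

    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # -- state ----------------------------------------------------------------

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: np.asarray(b).copy()
                      for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.data.shape).copy()
        for name, m in self._named_buffer_owners():
            key = "buffer:" + name
            if key in state:
                m._buffers[name.rsplit(".", 1)[-1]][...] = state[key]
                object.__setattr__(m, name.rsplit(".", 1)[-1],
                                   m._buffers[name.rsplit(".", 1)[-1]])

    def _named_buffer_owners(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, self
        for name, m in self._modules.items():
            yield from m._named_buffer_owners(prefix + name + ".")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """3×3-style conv with zero same-padding by default (padding=k//2)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(kaiming_normal(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(kaiming_normal(
            rng, (out_features, in_features), in_features, gain=1.0))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class PReLU(Module):
    """Parametric ReLU with a single shared slope (SRGAN-style)."""

    def __init__(self, init: float = 0.25):
        super().__init__()
        self.slope = Parameter(np.array([init]))

    def forward(self, x: Tensor) -> Tensor:
        pos = F.relu(x)
        neg = F.relu(-x) * self.slope
        return pos - neg


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean",
                             np.zeros(num_features, dtype=DEFAULT_DTYPE))
        self.register_buffer("running_var",
                             np.ones(num_features, dtype=DEFAULT_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var)
            xhat = centered / F.sqrt(var + self.eps)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - mu) / np.sqrt(var + self.eps)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ModuleList(Module):
    def __init__(self, modules: list[Module] = ()):  # noqa: B006
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module):
        self._modules[str(len(self._list))] = module
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, idx: int) -> Module:
        return self._list[idx]


class Lambda(Module):
    """Wrap a stateless function as a module (e.g. activations in Sequential)."""

    def __init__(self, fn):
        super().__init__()
        self.fn = fn

    def forward(self, x: Tensor) -> Tensor:
        return self.fn(x)
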
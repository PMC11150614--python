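"""Neural-network module system built on the autograd tensors."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "manual_seed",
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "ReLU",
    "GELU",
]

_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the generator used for all parameter initialisation."""
    global _rng
    _rng = np.random.default_rng(seed)


def trunc_normal(shape, std: float = 0.02) -> np.ndarray:
    """Normal draw truncated to two standard deviations."""
    x = _rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


def kaiming_normal(shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return _rng.normal(0.0, std, size=shape).astype(np.float32)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: attribute-walking parameter registry, train/eval modes."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self):
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation -------------------------------------------------
    def named_buffers(self, prefix: str = ""):
        buffers = getattr(self, "_buffer_names", ())
        for name in buffers:
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")
        for k, p in own.items():
            p.data = np.asarray(state[k], dtype=np.float32).reshape(p.data.shape)
        for k in bufs:
            obj, attr = self, k
            while "." in attr:
                head, attr = attr.split(".", 1)
                obj = getattr(obj, head)
            setattr(obj, attr, np.asarray(state[k], dtype=np.float32))


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._modules = list(modules)
        for i, m in enumerate(self._modules):
            setattr(self, str(i), m)

    def append(self, module):
        setattr(self, str(len(self._modules)), module)
        self._modules.append(module)

    def __iter__(self):
        return iter(self._modules)

    def __len__(self):
        return len(self._modules)

    def __getitem__(self, i):
        return self._modules[i]


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal((in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        k = kernel_size
        fan_in = in_ch * k * k
        self.weight = Parameter(kaiming_normal((out_ch, in_ch, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._buffer_names = ("running_mean", "running_var")
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = F.batch_norm_train(x, self.weight, self.bias, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            return out
        scale = self.weight.reshape(1, -1, 1, 1) * Tensor(
            1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, -1, 1, 1)
        shift = self.bias.reshape(1, -1, 1, 1) - scale * Tensor(
            self.running_mean).reshape(1, -1, 1, 1)
        return x * scale + shift


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()
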
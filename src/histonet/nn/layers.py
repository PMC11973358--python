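"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

from typing import Dict, Iterator, Tuple

import numpy as np

from .autodiff import Tensor, conv2d, maxpool2d

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Container with PyTorch-like parameter registration and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

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
            p.grad = None

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data
        for name, mod in self._walk():
            for k, v in mod._buffers.items():
                out[(name + "." if name else "") + k] = v
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {}
        for name, mod in self._walk():
            for k in mod._buffers:
                buffers[(name + "." if name else "") + k] = (mod, k)
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = np.asarray(value, dtype=np.float32)
            elif key in buffers:
                mod, k = buffers[key]
                mod.register_buffer(k, np.asarray(value))
            else:
                raise KeyError(f"unexpected key in state dict: {key}")

    def _walk(self, prefix: str = ""):
        yield prefix, self
        for k, m in self._modules.items():
            yield from m._walk(f"{prefix}.{k}" if prefix else k)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both in_channels and out_channels")
        rng = rng or np.random.default_rng(0)
        fan_out = kernel * kernel * out_channels // groups
        std = np.sqrt(2.0 / fan_out)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels // groups, kernel, kernel))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, kernel

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.eps, self.momentum, self.channels = eps, momentum, channels

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            rm = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(-1)
            rv = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            self.register_buffer("running_mean", rm.astype(np.float32))
            self.register_buffer("running_var", rv.astype(np.float32))
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        inv = (var + self.eps) ** -0.5
        xhat = (x - mu) * inv
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None
        self.in_features, self.out_features = in_features, out_features

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1)
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel, self.stride, self.padding)


class GlobalAvgPool(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._order = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._order:
            x = m(x)
        return x
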
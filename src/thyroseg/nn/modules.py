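"""Layer abstractions: parameter registry, train/eval mode, state dicts."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .init import kaiming_normal
from .tensor import Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self):
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

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        d.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        expected = set(params) | {"buffer:" + n for n, _ in self.named_buffers()}
        if set(d) != expected:
            missing = expected - set(d)
            extra = set(d) - expected
            raise ValueError(f"state dict mismatch: missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}")
        for n, p in params.items():
            if p.data.shape != d[n].shape:
                raise ValueError(f"shape mismatch for {n}: {p.data.shape} vs {d[n].shape}")
            p.data[...] = d[n]
        # buffers are registered per-module; walk and assign in place
        for n, b in self.named_buffers():
            b[...] = d["buffer:" + n]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 convolution with 'same' padding by default."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        padding: int | str = "same",
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must divide groups")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        self.weight = Tensor(
            kaiming_normal(rng, (out_channels, in_channels // groups, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        return F.conv2d(
            x, self.weight, self.bias, padding=self.padding, dilation=self.dilation, groups=self.groups
        )


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(num_features), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            y, mu, var = F.batch_norm_train(x, self.weight, self.bias, self.eps)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu
            self.running_var *= 1 - m
            self.running_var += m * var
            return y
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.weight.data * inv).reshape(1, -1, 1, 1)
        shift = (self.bias.data - self.running_mean * self.weight.data * inv).reshape(1, -1, 1, 1)
        return x * Tensor(scale) + Tensor(shift)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Dropout(Module):
    """Dropout with an explicit per-module RNG so runs are reproducible."""

    def __init__(self, p: float = 0.5, seed: int = 0):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.p, self.rng, self.training)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
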
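"""Layer modules: parameter containers with train/eval state and state_dict I/O."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = [
    "Module", "Sequential", "ModuleList", "Identity",
    "Conv2d", "ConvTranspose2d", "Linear", "BatchNorm2d", "ReLU",
]


class Module:
    """Base class; submodules and parameters are discovered via attributes."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal -----------------------------------------------------------

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, value in vars(self).items():
            if isinstance(value, Module):
                sub = f"{prefix}.{name}" if prefix else name
                yield from value.named_modules(sub)

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for mod_name, mod in self.named_modules():
            for name, value in vars(mod).items():
                if isinstance(value, Parameter):
                    yield (f"{mod_name}.{name}" if mod_name else name), value

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- serialization --------------------------------------------------------

    def _named_buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        for mod_name, mod in self.named_modules():
            for name in getattr(mod, "_buffers", ()):
                arr = getattr(mod, name)
                yield (f"{mod_name}.{name}" if mod_name else name), arr

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: np.asarray(buf).copy() for name, buf in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: (mod, attr) for name, (mod, attr) in
                   ((f"{mn}.{a}" if mn else a, (m, a))
                    for mn, m in self.named_modules() for a in getattr(m, "_buffers", ()))}
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]} ...")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.array(state[name], dtype=p.data.dtype)
        for name, (mod, attr) in buffers.items():
            setattr(mod, attr, np.array(state[name]))


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)
        self._n = len(modules)

    def forward(self, x):
        for i in range(self._n):
            x = getattr(self, f"m{i}")(x)
        return x

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._n = 0
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        setattr(self, f"m{self._n}", module)
        self._n += 1

    def __len__(self):
        return self._n

    def __getitem__(self, i: int) -> Module:
        if i < 0:
            i += self._n
        return getattr(self, f"m{i}")

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))


class Identity(Module):
    def forward(self, x):
        return x


def _he_uniform(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    bound = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reset the parameter-initialization stream (reproducible model builds)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    """Stride-1 same-padding convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_he_uniform(
            (out_channels, in_channels, kernel_size, kernel_size), fan_in, _INIT_RNG))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    """Kernel==stride transposed convolution (learned 2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, stride: int = 2,
                 bias: bool = True):
        super().__init__()
        self.stride = stride
        self.weight = Parameter(_he_uniform(
            (in_channels, out_channels, stride, stride), in_channels * stride * stride, _INIT_RNG))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_he_uniform((out_features, in_features), in_features, _INIT_RNG))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval mode."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = np.square(x.data - mean.reshape(1, -1, 1, 1)).mean(axis=(0, 2, 3))
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var * (n / max(n - 1, 1))
            return F.batch_norm(x, self.weight, self.bias, eps=self.eps)
        return F.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, eps=self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()
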
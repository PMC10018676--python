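"""Neural-network building blocks on top of the autodiff engine.

Modules hold :class:`Parameter` leaves; parameter initialization is fully
determined by the NumPy generator passed at construction, so a model built
twice from the same seed is bit-identical.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .autodiff import Tensor, conv2d

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((n, p.data.copy()) for n, p in self.named_parameters())

    def load_state_dict(self, state) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        self._mods = list(modules)

    def append(self, m: Module):
        self._mods.append(m)

    def __iter__(self):
        return iter(self._mods)

    def __len__(self):
        return len(self._mods)

    def __getitem__(self, i):
        return self._mods[i]

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._mods):
            yield from m.named_parameters(f"{prefix}{i}.")


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 dilation: int = 1, bias: bool = True):
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class LayerNorm(Module):
    """Normalizes over the last axis (the channel axis of a token layout)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


def avg_pool2x2(x: Tensor) -> Tensor:
    """2x2 mean pooling of (B, C, H, W); odd trailing rows/cols are cropped."""
    B, C, H, W = x.shape
    H2, W2 = H // 2, W // 2
    x = x[:, :, : 2 * H2, : 2 * W2]
    return x.reshape(B, C, H2, 2, W2, 2).mean(axis=(3, 5))


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    total = 0.0
    params = list(params)
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam optimizer with serializable state (for resumable training)."""

    def __init__(self, named_params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = OrderedDict(named_params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in self.params.items()}
        self.v = {n: np.zeros_like(p.data) for n, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for n, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            m = self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            v = self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": {n: a.copy() for n, a in self.m.items()},
                "v": {n: a.copy() for n, a in self.v.items()}}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for n in self.m:
            self.m[n] = np.asarray(state["m"][n])
            self.v[n] = np.asarray(state["v"][n])
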
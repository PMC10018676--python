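"""Atrous spatial pyramid pooling bottleneck.

Four parallel 3x3 convolutions with dilation rates {1, 6, 12, 18} and padding
equal to the rate (size-preserving), concatenated along channels and projected
by a 1x1 convolution, with a ReLU after the projection.  Dilating a kernel of
size k by rate d gives an effective kernel of k + (k-1)(d-1), so the output
size of a dilated convolution is

    O = floor((i + 2p - (k + (k-1)(d-1))) / s) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .errors import InvalidConfigError
from .nn import Conv2d, Module, ModuleList

DEFAULT_RATES = (1, 6, 12, 18)


@dataclass(frozen=True)
class AsppConfig:
    in_channels: int
    out_channels: int
    rates: tuple = DEFAULT_RATES

    def __post_init__(self):
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise InvalidConfigError("channel counts must be positive")
        if any(r < 1 for r in self.rates):
            raise InvalidConfigError("dilation rates must be >= 1")
        if len(set(self.rates)) != len(self.rates):
            raise InvalidConfigError("dilation rates must be distinct")


def effective_kernel(k: int, d: int) -> int:
    return k + (k - 1) * (d - 1)


def atrous_output_size(i: int, p: int, k: int, d: int, s: int) -> int:
    """Output size of a dilated convolution along one axis."""
    if min(i, k, d, s) < 1 or p < 0:
        raise InvalidConfigError("sizes must be positive (padding may be zero)")
    eff = effective_kernel(k, d)
    if eff > i + 2 * p:
        raise InvalidConfigError(
            f"effective kernel {eff} exceeds padded input {i + 2 * p}")
    return (i + 2 * p - eff) // s + 1


class Aspp(Module):
    def __init__(self, cfg: AsppConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.branches = ModuleList(
            Conv2d(cfg.in_channels, cfg.out_channels, 3, rng, padding=r, dilation=r)
            for r in cfg.rates)
        self.project = Conv2d(len(cfg.rates) * cfg.out_channels, cfg.out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        outs = [branch(x) for branch in self.branches]
        return self.project(concat(outs, axis=1)).relu()
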
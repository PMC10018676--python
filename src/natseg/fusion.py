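"""Gated fusion of three per-modality feature maps.

The three maps are concatenated along channels; a 1x1 convolution with three
output channels followed by a sigmoid produces one spatially varying weight
map per modality.  Each modality's features are scaled by its weight map
(broadcast over channels), the scaled maps are concatenated again, and a 3x3
convolution projects back to the per-modality channel count, followed by a
ReLU.  Output shape equals each input's shape.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .errors import ShapeError
from .nn import Conv2d, Module


class GatedFusion(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.gate_conv = Conv2d(3 * channels, 3, 1, rng)
        self.fuse_conv = Conv2d(3 * channels, channels, 3, rng, padding=1)

    def forward(self, f1: Tensor, f2: Tensor, f3: Tensor,
                return_gates: bool = False):
        for idx, f in enumerate((f2, f3), start=2):
            if f.shape != f1.shape:
                raise ShapeError(
                    f"modality {idx} features {f.shape} do not match modality 1 {f1.shape}")
        if f1.shape[1] != self.channels:
            raise ShapeError(f"expected {self.channels} channels, got {f1.shape[1]}")
        stacked = concat([f1, f2, f3], axis=1)
        gates = self.gate_conv(stacked).sigmoid()          # (B, 3, H, W)
        weighted = concat([f1 * gates[:, 0:1], f2 * gates[:, 1:2], f3 * gates[:, 2:3]],
                          axis=1)
        fused = self.fuse_conv(weighted).relu()
        if return_gates:
            return fused, gates.data
        return fused


class ConcatFusion(Module):
    """Plain concatenation + 1x1 projection (the fusion ablation arm)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.proj = Conv2d(3 * channels, channels, 1, rng)

    def forward(self, f1: Tensor, f2: Tensor, f3: Tensor) -> Tensor:
        for idx, f in enumerate((f2, f3), start=2):
            if f.shape != f1.shape:
                raise ShapeError(
                    f"modality {idx} features {f.shape} do not match modality 1 {f1.shape}")
        return self.proj(concat([f1, f2, f3], axis=1)).relu()
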
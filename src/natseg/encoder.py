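"""Hierarchical transformer encoder for one image modality.

A convolutional tokenizer (two stride-2 3x3 convolutions) brings the input to
1/4 resolution, then three stages of attention blocks run at 1/4, 1/8 and
1/16 resolution.  Each block is pre-norm residual: ``x + NA(LN(x))`` followed
by ``+ MLP(LN(.))``; between stages a single stride-2 convolution halves the
spatial size and doubles the channel count, so stage ``c`` carries
``embed_dim * 2**(c-1)`` channels.

The attention window is clamped per stage to the largest odd size that fits
the stage's feature map, so one configuration serves both full-resolution and
desk-scale inputs.  Setting ``use_attention=False`` swaps every block for a
plain two-convolution residual block (the convolutional ablation arm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .errors import ShapeError
from .na import AttentionConfig, MultiHeadNeighborhoodAttention
from .nn import Conv2d, LayerNorm, Mlp, Module, ModuleList


@dataclass(frozen=True)
class EncoderConfig:
    in_channels: int = 1
    embed_dim: int = 32
    depths: tuple = (2, 2, 2)
    num_heads: tuple = (2, 4, 8)
    neighborhood_size: int = 7
    mlp_ratio: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if len(self.depths) != 3 or len(self.num_heads) != 3:
            raise ValueError("exactly three stages are required")
        for c, h in enumerate(self.num_heads):
            if self.stage_channels(c + 1) % h != 0:
                raise ValueError(f"stage {c + 1} channels not divisible by {h} heads")

    def stage_channels(self, stage: int) -> int:
        return self.embed_dim * 2 ** (stage - 1)


@dataclass
class FeaturePyramid:
    """Per-stage feature maps at 1/4, 1/8 and 1/16 of the input resolution."""

    f4: Tensor
    f8: Tensor
    f16: Tensor

    def levels(self):
        return (self.f4, self.f8, self.f16)


def _check_divisible(H: int, W: int, factor: int) -> None:
    if H % factor:
        raise ShapeError(f"height {H} not divisible by {factor}")
    if W % factor:
        raise ShapeError(f"width {W} not divisible by {factor}")


class ConvTokenizer(Module):
    """Two consecutive 3x3/stride-2 convolutions: (B, Cin, H, W) -> (B, E, H/4, W/4)."""

    def __init__(self, in_channels: int, embed_dim: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_channels, embed_dim, 3, rng, stride=2, padding=1)
        self.conv2 = Conv2d(embed_dim, embed_dim, 3, rng, stride=2, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        _check_divisible(x.shape[2], x.shape[3], 4)
        return self.conv2(self.conv1(x).relu())


class NVTBlock(Module):
    """Pre-norm residual transformer block: attention then MLP, each with a skip."""

    def __init__(self, dim: int, num_heads: int, neighborhood_size: int,
                 mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadNeighborhoodAttention(
            AttentionConfig(dim, num_heads, neighborhood_size), rng, auto_shrink=True)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(round(dim * mlp_ratio)), rng)
        self.dim = dim

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        tok = x.transpose(0, 2, 3, 1)
        t1 = self.norm1(tok).transpose(0, 3, 1, 2)
        tok = tok + self.attn(t1).transpose(0, 2, 3, 1)
        tok = tok + self.mlp(self.norm2(tok))
        return tok.transpose(0, 3, 1, 2)


class ConvBlock(Module):
    """Residual block of two 3x3 convolutions + ReLU (attention-free ablation arm)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.conv1 = Conv2d(dim, dim, 3, rng, padding=1)
        self.conv2 = Conv2d(dim, dim, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x).relu()).relu()


class Downsample(Module):
    """Stride-2 convolution halving the spatial size and doubling the channels."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.conv = Conv2d(dim, 2 * dim, 3, rng, stride=2, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if H % 2:
            raise ShapeError(f"height {H} must be even to downsample")
        if W % 2:
            raise ShapeError(f"width {W} must be even to downsample")
        return self.conv(x)


class Encoder(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | None = None,
                 use_attention: bool = True):
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.tokenizer = ConvTokenizer(cfg.in_channels, cfg.embed_dim, rng)
        self.stages = ModuleList()
        self.downsamples = ModuleList()
        for s in range(3):
            dim = cfg.stage_channels(s + 1)
            blocks = ModuleList()
            for _ in range(cfg.depths[s]):
                if use_attention:
                    blocks.append(NVTBlock(dim, cfg.num_heads[s], cfg.neighborhood_size,
                                           cfg.mlp_ratio, rng))
                else:
                    blocks.append(ConvBlock(dim, rng))
            self.stages.append(blocks)
            if s < 2:
                self.downsamples.append(Downsample(dim, rng))

    def forward(self, x: Tensor) -> FeaturePyramid:
        _check_divisible(x.shape[2], x.shape[3], 16)
        feats = []
        h = self.tokenizer(x)
        for s in range(3):
            for block in self.stages[s]:
                h = block(h)
            feats.append(h)
            if s < 2:
                h = self.downsamples[s](h)
        return FeaturePyramid(*feats)
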
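"""Compound segmentation loss: multi-scale SSIM + focal + Tversky.

The total loss is ``w_msssim * L_msssim + w_focal * L_focal + w_tversky *
L_tversky``; by default the mixing weights are (5, 3, 1) — the structural term
carries weight 5 and the focal weight is three times the Tversky weight.

All three components operate on softmax probability maps.  The structural and
Tversky terms are computed per foreground-class map and averaged over the
foreground classes; the focal term sums over all classes of the one-hot
target (reducing to cross-entropy when its focusing exponent is zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, conv2d
from .errors import InvalidConfigError, ShapeError
from .nn import avg_pool2x2

__all__ = [
    "LossWeights", "MsSsimConfig", "FocalConfig", "TverskyConfig",
    "ms_ssim_loss", "focal_loss", "tversky_loss", "mixed_loss", "one_hot",
]

_EPS_LOG = 1e-7


@dataclass(frozen=True)
class LossWeights:
    w_msssim: float = 5.0
    w_focal: float = 3.0
    w_tversky: float = 1.0

    def __post_init__(self):
        if min(self.w_msssim, self.w_focal, self.w_tversky) < 0:
            raise InvalidConfigError("loss weights must be non-negative")
        if self.w_msssim == self.w_focal == self.w_tversky == 0:
            raise InvalidConfigError("at least one loss weight must be positive")


@dataclass(frozen=True)
class MsSsimConfig:
    num_scales: int = 3
    window_size: int = 11
    c1: float = 0.01 ** 2
    c2: float = 0.03 ** 2
    c3: float | None = None     # defaults to c2 / 2
    alpha: float = 1.0          # luminance exponent (coarsest scale)
    beta: float = 1.0           # contrast exponent (all scales)
    gamma: float = 1.0          # structure exponent (all scales)

    def __post_init__(self):
        if self.num_scales < 1:
            raise InvalidConfigError("num_scales must be >= 1")
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise InvalidConfigError("window_size must be odd and >= 1")

    @property
    def c3_value(self) -> float:
        return self.c2 / 2.0 if self.c3 is None else self.c3


@dataclass(frozen=True)
class FocalConfig:
    gamma: float = 2.0          # focusing parameter
    reduction: str = "mean"     # "mean" or "sum" over pixels

    def __post_init__(self):
        if self.gamma < 0:
            raise InvalidConfigError("focusing parameter must be >= 0")
        if self.reduction not in ("mean", "sum"):
            raise InvalidConfigError("reduction must be 'mean' or 'sum'")


@dataclass(frozen=True)
class TverskyConfig:
    alpha: float = 0.3          # false-positive weight; beta = 1 - alpha

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise InvalidConfigError("alpha must lie in (0, 1)")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _window_mean(x: Tensor, n: int) -> Tensor:
    """Mean over every fully-inside N x N window of (B, 1, H, W) maps."""
    dt = x.dtype if x.dtype.kind == "f" else np.float64
    krow = Tensor(np.full((1, 1, 1, n), 1.0 / n, dtype=dt))
    kcol = Tensor(np.full((1, 1, n, 1), 1.0 / n, dtype=dt))
    return conv2d(conv2d(x, krow), kcol)


def _pow(t: Tensor, e: float) -> Tensor:
    return t if e == 1.0 else t ** e


def max_feasible_scales(h: int, w: int, window: int) -> int:
    m = 0
    while min(h, w) >= window:
        m += 1
        h //= 2
        w //= 2
    return m


def ms_ssim_loss(p, t, cfg: MsSsimConfig = MsSsimConfig()) -> Tensor:
    """1 - MS-SSIM between a probability map and its target, both in [0, 1].

    Accepts (H, W), (B, H, W) or (B, 1, H, W) maps.  Local statistics use a
    uniform N x N window (population normalization); contrast and structure
    terms enter at every scale, luminance only at the coarsest, each averaged
    over window positions before the across-scale product.  Scales are linked
    by 2x2 mean pooling.
    """
    p, t = _as_tensor(p), _as_tensor(t)
    if p.shape != t.shape:
        raise ShapeError(f"prediction {p.shape} vs target {t.shape}")
    if p.ndim == 2:
        p, t = p.reshape(1, 1, *p.shape), t.reshape(1, 1, *t.shape)
    elif p.ndim == 3:
        p = p.reshape(p.shape[0], 1, *p.shape[1:])
        t = t.reshape(t.shape[0], 1, *t.shape[1:])
    H, W = p.shape[2], p.shape[3]
    n = cfg.window_size
    feasible = max_feasible_scales(H, W, n)
    if cfg.num_scales > feasible:
        raise InvalidConfigError(
            f"{cfg.num_scales} scales need a larger image; at most {feasible} feasible "
            f"for {H}x{W} with window {n}")
    c1, c2, c3 = cfg.c1, cfg.c2, cfg.c3_value
    total = None
    for m in range(cfg.num_scales):
        mu_p = _window_mean(p, n)
        mu_t = _window_mean(t, n)
        var_p = (_window_mean(p * p, n) - mu_p * mu_p).clamp(lo=0.0)
        var_t = (_window_mean(t * t, n) - mu_t * mu_t).clamp(lo=0.0)
        cov = _window_mean(p * t, n) - mu_p * mu_t
        sd_p = (var_p + 1e-12).sqrt()
        sd_t = (var_t + 1e-12).sqrt()
        contrast = (2.0 * sd_p * sd_t + c2) / (var_p + var_t + c2)
        structure = (cov + c3) / (sd_p * sd_t + c3)
        term = _pow(contrast, cfg.beta) * _pow(structure, cfg.gamma)
        if m == cfg.num_scales - 1:
            lum = (2.0 * mu_p * mu_t + c1) / (mu_p * mu_p + mu_t * mu_t + c1)
            term = term * _pow(lum, cfg.alpha)
        scale_mean = term.mean()
        total = scale_mean if total is None else total * scale_mean
        if m < cfg.num_scales - 1:
            p = avg_pool2x2(p)
            t = avg_pool2x2(t)
    return 1.0 - total


def focal_loss(probs, target_onehot, cfg: FocalConfig = FocalConfig()) -> Tensor:
    """Focal loss -sum Yt (1-Yp)^gamma log(Yp) over classes, reduced over pixels.

    `probs` and `target_onehot` are (B, K, H, W); the per-pixel sum over the
    one-hot class axis is reduced over pixels by mean (default) or sum, then
    averaged over the batch.
    """
    probs, target = _as_tensor(probs), _as_tensor(target_onehot)
    if probs.shape != target.shape:
        raise ShapeError(f"probs {probs.shape} vs target {target.shape}")
    p = probs.clamp(lo=_EPS_LOG, hi=1.0)
    modulator = _pow(1.0 - p, cfg.gamma)
    pixel = -(target * modulator * p.log()).sum(axis=1)  # (B, H, W)
    per_case = pixel.mean(axis=(1, 2)) if cfg.reduction == "mean" else pixel.sum(axis=(1, 2))
    return per_case.mean()


def tversky_loss(probs, target, cfg: TverskyConfig = TverskyConfig()) -> Tensor:
    """Tversky loss of one class map, with the additive +1 smoothing as printed:

        1 - (1 + TP) / (1 + TP + alpha * FP + beta * FN)

    where TP/FP/FN are soft sums over all elements of the map.
    """
    p, t = _as_tensor(probs), _as_tensor(target)
    if p.shape != t.shape:
        raise ShapeError(f"probs {p.shape} vs target {t.shape}")
    tp = (t * p).sum()
    fp = ((1.0 - t) * p).sum()
    fn = (t * (1.0 - p)).sum()
    return 1.0 - (1.0 + tp) / (1.0 + tp + cfg.alpha * fp + cfg.beta * fn)


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """(B, H, W) integer labels -> (B, K, H, W) one-hot float32."""
    labels = np.asarray(labels)
    out = np.zeros((labels.shape[0], num_classes) + labels.shape[1:], dtype=np.float32)
    for k in range(num_classes):
        out[:, k] = labels == k
    return out


@dataclass
class MixedLossConfig:
    weights: LossWeights = field(default_factory=LossWeights)
    msssim: MsSsimConfig = field(default_factory=MsSsimConfig)
    focal: FocalConfig = field(default_factory=FocalConfig)
    tversky: TverskyConfig = field(default_factory=TverskyConfig)
    use_msssim: bool = True
    use_focal: bool = True
    use_tversky: bool = True


def mixed_loss(probs, target_onehot, cfg: MixedLossConfig = None):
    """Weighted sum of the three components on (B, K, H, W) probabilities.

    The structural and Tversky terms are averaged over foreground classes
    (class 0 is background).  Returns ``(total, breakdown)`` where breakdown
    maps component names to their unweighted float values.
    """
    cfg = cfg or MixedLossConfig()
    probs, target = _as_tensor(probs), _as_tensor(target_onehot)
    if probs.shape != target.shape:
        raise ShapeError(f"probs {probs.shape} vs target {target.shape}")
    K = probs.shape[1]
    zero = Tensor(np.zeros((), dtype=probs.dtype if probs.dtype.kind == "f" else np.float64))
    l_ms, l_tv = zero, zero
    n_fg = K - 1
    if cfg.use_msssim and cfg.weights.w_msssim > 0:
        terms = [ms_ssim_loss(probs[:, k], target[:, k], cfg.msssim) for k in range(1, K)]
        l_ms = sum(terms[1:], terms[0]) * (1.0 / n_fg)
    if cfg.use_tversky and cfg.weights.w_tversky > 0:
        terms = [tversky_loss(probs[:, k], target[:, k], cfg.tversky) for k in range(1, K)]
        l_tv = sum(terms[1:], terms[0]) * (1.0 / n_fg)
    l_f = focal_loss(probs, target, cfg.focal) if (cfg.use_focal and cfg.weights.w_focal > 0) else zero
    total = (cfg.weights.w_msssim * l_ms + cfg.weights.w_focal * l_f
             + cfg.weights.w_tversky * l_tv)
    breakdown = {"msssim": float(l_ms.data), "focal": float(l_f.data),
                 "tversky": float(l_tv.data)}
    return total, breakdown
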
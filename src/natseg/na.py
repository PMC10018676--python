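"""Multi-head neighborhood attention.

Each query pixel attends to the S x S window of pixels centred on it, with the
window shifted inward at image borders so that it always contains exactly S^2
real pixels.  Per head, the attention logits are

    (q_i . k_j + B[dr, dc]) / scale

for each neighbor j at offset (dr, dc) from the query, softmaxed over the S^2
neighbors; the output is the weighted sum of neighbor values, heads
concatenated and linearly projected.  ``B`` is a learned relative-position
bias table of shape (heads, 2S-1, 2S-1).

Two deliberately slow, loop-based references live alongside the vectorized
operator: a per-pixel loop with identical semantics, and a dense full
self-attention that neighborhood attention must match when the window covers
the whole image.  Both are written in plain NumPy, independent of the
autodiff path, and are used for equivalence testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .autodiff import Tensor
from .errors import InvalidConfigError, ShapeError
from .nn import Linear, Module, Parameter

__all__ = [
    "AttentionConfig",
    "neighborhood_indices",
    "MultiHeadNeighborhoodAttention",
    "multi_head_neighborhood_attention",
    "na_loop_oracle",
    "full_self_attention_oracle",
    "na_operation_count",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Shape and scaling hyperparameters of the attention operator.

    scale defaults to sqrt(head_dim); the bias is added to the raw dot
    product *before* the division by scale.
    """

    embed_dim: int
    num_heads: int
    neighborhood_size: int
    scale: float | None = None

    def __post_init__(self):
        if self.embed_dim <= 0 or self.num_heads <= 0:
            raise InvalidConfigError("embed_dim and num_heads must be positive")
        if self.embed_dim % self.num_heads != 0:
            raise InvalidConfigError(
                f"embed_dim {self.embed_dim} not divisible by num_heads {self.num_heads}")
        s = self.neighborhood_size
        if s < 1 or s % 2 == 0:
            raise InvalidConfigError(f"neighborhood_size must be odd and >= 1, got {s}")
        if self.scale is not None and self.scale <= 0:
            raise InvalidConfigError("scale must be positive")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads

    @property
    def effective_scale(self) -> float:
        return float(self.scale) if self.scale is not None else float(np.sqrt(self.head_dim))


def neighborhood_indices(i: int, j: int, S: int, H: int, W: int) -> list[tuple[int, int]]:
    """The S x S window centred at (i, j), clamped inside the image.

    Row-major order; always exactly S^2 distinct in-bounds pixels.
    """
    if S > H or S > W:
        raise InvalidConfigError(f"window size {S} exceeds image ({H}x{W})")
    if not (0 <= i < H and 0 <= j < W):
        raise ShapeError(f"pixel ({i},{j}) outside {H}x{W} image")
    r0 = min(max(i - S // 2, 0), H - S)
    c0 = min(max(j - S // 2, 0), W - S)
    return [(r, c) for r in range(r0, r0 + S) for c in range(c0, c0 + S)]


class _Plan:
    """Precomputed gather/scatter indexing for one (H, W, S, table_S) geometry."""

    def __init__(self, H: int, W: int, S: int, table_S: int):
        ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        r0 = np.clip(ii - S // 2, 0, H - S)
        c0 = np.clip(jj - S // 2, 0, W - S)
        dr = np.arange(S)
        rows = r0[..., None, None] + dr[None, None, :, None]   # (H, W, S, 1)
        cols = c0[..., None, None] + dr[None, None, None, :]   # (H, W, 1, S)
        nbr = (rows * W + cols).reshape(H * W, S * S)
        d_row = rows - ii[..., None, None]
        d_col = cols - jj[..., None, None]
        off = ((d_row + table_S - 1) * (2 * table_S - 1) + (d_col + table_S - 1))
        self.nbr = np.ascontiguousarray(nbr.astype(np.intp))
        self.off = np.ascontiguousarray(
            np.broadcast_to(off, (H, W, S, S)).reshape(H * W, S * S).astype(np.intp))
        flat = self.nbr.ravel()
        self.order = np.argsort(flat, kind="stable")
        # every token lies in its own window, so all N segments are non-empty
        self.seg_starts = np.searchsorted(flat[self.order], np.arange(H * W))


@lru_cache(maxsize=64)
def _plan(H: int, W: int, S: int, table_S: int) -> _Plan:
    return _Plan(H, W, S, table_S)


def _scatter_tokens(g_windows: np.ndarray, plan: _Plan, n_tokens: int) -> np.ndarray:
    """Sum (B, h, N, S2, d) window grads back onto their source tokens -> (B, h, N, d)."""
    B, nh, N, S2, d = g_windows.shape
    flat = g_windows.reshape(B, nh, N * S2, d)[:, :, plan.order, :]
    return np.add.reduceat(flat, plan.seg_starts, axis=2)


def _window_logits(q: Tensor, k: Tensor, plan: _Plan) -> Tensor:
    """logits[b,h,n,m] = q[b,h,n,:] . k[b,h,nbr[n,m],:]"""
    k_nb = k.data[:, :, plan.nbr, :]                     # (B, h, N, S2, d)
    out = np.einsum("bhnd,bhnmd->bhnm", q.data, k_nb)

    def backward(g):
        if q.requires_grad:
            q.accumulate(np.einsum("bhnm,bhnmd->bhnd", g, k_nb))
        if k.requires_grad:
            gk_win = np.einsum("bhnm,bhnd->bhnmd", g, q.data)
            k.accumulate(_scatter_tokens(gk_win, plan, k.shape[2]))

    return q._new(out, (q, k), backward)


def _window_combine(w: Tensor, v: Tensor, plan: _Plan) -> Tensor:
    """out[b,h,n,:] = sum_m w[b,h,n,m] * v[b,h,nbr[n,m],:]"""
    v_nb = v.data[:, :, plan.nbr, :]
    out = np.einsum("bhnm,bhnmd->bhnd", w.data, v_nb)

    def backward(g):
        if w.requires_grad:
            w.accumulate(np.einsum("bhnd,bhnmd->bhnm", g, v_nb))
        if v.requires_grad:
            gv_win = np.einsum("bhnm,bhnd->bhnmd", w.data, g)
            v.accumulate(_scatter_tokens(gv_win, plan, v.shape[2]))

    return w._new(out, (w, v), backward)


def _gather_bias(table: Tensor, off: np.ndarray) -> Tensor:
    """(h, T) bias table gathered to (h, N, S2) by flat offset index."""
    out = table.data[:, off]

    def backward(g):
        gt = np.zeros_like(table.data, dtype=g.dtype)
        np.add.at(gt, np.s_[:, off], g)
        table.accumulate(gt)

    return table._new(out, (table,), backward)


class MultiHeadNeighborhoodAttention(Module):
    """The neighborhood attention operator as a trainable module.

    When ``auto_shrink`` is set, a window larger than the feature map is
    quietly reduced to the largest odd size that fits (the bias table covers
    the reduced offsets exactly); otherwise such inputs raise
    :class:`InvalidConfigError`.
    """

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator,
                 auto_shrink: bool = False):
        self.cfg = cfg
        self.auto_shrink = auto_shrink
        C = cfg.embed_dim
        self.q = Linear(C, C, rng)
        self.k = Linear(C, C, rng)
        self.v = Linear(C, C, rng)
        self.proj = Linear(C, C, rng)
        S = cfg.neighborhood_size
        self.bias = Parameter(rng.normal(0.0, 0.02, size=(cfg.num_heads, 2 * S - 1, 2 * S - 1)))

    def _effective_window(self, H: int, W: int) -> int:
        S = self.cfg.neighborhood_size
        if S <= min(H, W):
            return S
        if not self.auto_shrink:
            raise InvalidConfigError(
                f"neighborhood_size {S} exceeds feature map {H}x{W}")
        s = min(H, W)
        return s if s % 2 == 1 else s - 1

    def forward(self, x: Tensor, return_weights: bool = False):
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite values in attention input")
        B, C, H, W = x.shape
        cfg = self.cfg
        if C != cfg.embed_dim:
            raise ShapeError(f"expected {cfg.embed_dim} channels, got {C}")
        S = self._effective_window(H, W)
        plan = _plan(H, W, S, cfg.neighborhood_size)
        N, nh, hd = H * W, cfg.num_heads, cfg.head_dim

        tok = x.transpose(0, 2, 3, 1).reshape(B, N, C)

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, N, nh, hd).transpose(0, 2, 1, 3)

        q = heads(self.q(tok))
        k = heads(self.k(tok))
        v = heads(self.v(tok))

        logits = _window_logits(q, k, plan)
        bias_flat = self.bias.reshape(nh, (2 * cfg.neighborhood_size - 1) ** 2)
        logits = (logits + _gather_bias(bias_flat, plan.off)) * (1.0 / cfg.effective_scale)
        weights = logits.softmax(axis=-1)
        out = _window_combine(weights, v, plan)
        out = out.transpose(0, 2, 1, 3).reshape(B, N, C)
        out = self.proj(out).reshape(B, H, W, C).transpose(0, 3, 1, 2)
        if return_weights:
            return out, weights.data
        return out

    # parameter export for the NumPy reference implementations
    def export_params(self) -> dict:
        return {
            "wq": self.q.weight.data, "bq": self.q.bias.data,
            "wk": self.k.weight.data, "bk": self.k.bias.data,
            "wv": self.v.weight.data, "bv": self.v.bias.data,
            "wo": self.proj.weight.data, "bo": self.proj.bias.data,
            "bias": self.bias.data,
        }

    def load_params(self, params: dict) -> None:
        self.q.weight.data = np.asarray(params["wq"], dtype=self.q.weight.dtype)
        self.q.bias.data = np.asarray(params["bq"], dtype=self.q.bias.dtype)
        self.k.weight.data = np.asarray(params["wk"], dtype=self.k.weight.dtype)
        self.k.bias.data = np.asarray(params["bk"], dtype=self.k.bias.dtype)
        self.v.weight.data = np.asarray(params["wv"], dtype=self.v.weight.dtype)
        self.v.bias.data = np.asarray(params["bv"], dtype=self.v.bias.dtype)
        self.proj.weight.data = np.asarray(params["wo"], dtype=self.proj.weight.dtype)
        self.proj.bias.data = np.asarray(params["bo"], dtype=self.proj.bias.dtype)
        self.bias.data = np.asarray(params["bias"], dtype=self.bias.dtype)


def multi_head_neighborhood_attention(x: np.ndarray, cfg: AttentionConfig,
                                      params: dict) -> np.ndarray:
    """Functional entry point: vectorized NA on a NumPy array with given params."""
    module = MultiHeadNeighborhoodAttention(cfg, np.random.default_rng(0))
    module.load_params(params)
    return module(Tensor(np.asarray(x))).data


def _project(tok: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    return tok @ w + b


def na_loop_oracle(x: np.ndarray, cfg: AttentionConfig, params: dict) -> np.ndarray:
    """Per-pixel loop reference for neighborhood attention (slow, small inputs)."""
    x = np.asarray(x, dtype=np.float64)
    B, C, H, W = x.shape
    S = cfg.neighborhood_size
    nh, hd = cfg.num_heads, cfg.head_dim
    scale = cfg.effective_scale
    tok = x.transpose(0, 2, 3, 1).reshape(B, H * W, C)
    q = _project(tok, params["wq"], params["bq"]).reshape(B, H, W, nh, hd)
    k = _project(tok, params["wk"], params["bk"]).reshape(B, H, W, nh, hd)
    v = _project(tok, params["wv"], params["bv"]).reshape(B, H, W, nh, hd)
    bias = np.asarray(params["bias"], dtype=np.float64)
    out = np.zeros((B, H, W, nh, hd))
    for b in range(B):
        for i in range(H):
            for j in range(W):
                window = neighborhood_indices(i, j, S, H, W)
                for h in range(nh):
                    logits = np.empty(len(window))
                    for m, (r, c) in enumerate(window):
                        bterm = bias[h, r - i + S - 1, c - j + S - 1]
                        logits[m] = (q[b, i, j, h] @ k[b, r, c, h] + bterm) / scale
                    logits -= logits.max()
                    wgt = np.exp(logits)
                    wgt /= wgt.sum()
                    acc = np.zeros(hd)
                    for m, (r, c) in enumerate(window):
                        acc += wgt[m] * v[b, r, c, h]
                    out[b, i, j, h] = acc
    out = out.reshape(B, H * W, nh * hd)
    out = _project(out, params["wo"], params["bo"])
    return out.reshape(B, H, W, C).transpose(0, 3, 1, 2)


def full_self_attention_oracle(x: np.ndarray, cfg: AttentionConfig, params: dict) -> np.ndarray:
    """Dense softmax attention over all pixels, bias applied within (2S-1)^2 offsets.

    Small inputs only (H * W <= 1024); the localized operator must agree with
    this when the window covers the whole image.
    """
    x = np.asarray(x, dtype=np.float64)
    B, C, H, W = x.shape
    if H * W > 1024:
        raise InvalidConfigError("dense reference restricted to H*W <= 1024")
    S = cfg.neighborhood_size
    nh, hd = cfg.num_heads, cfg.head_dim
    scale = cfg.effective_scale
    N = H * W
    tok = x.transpose(0, 2, 3, 1).reshape(B, N, C)
    q = _project(tok, params["wq"], params["bq"]).reshape(B, N, nh, hd).transpose(0, 2, 1, 3)
    k = _project(tok, params["wk"], params["bk"]).reshape(B, N, nh, hd).transpose(0, 2, 1, 3)
    v = _project(tok, params["wv"], params["bv"]).reshape(B, N, nh, hd).transpose(0, 2, 1, 3)
    bias = np.asarray(params["bias"], dtype=np.float64)
    ii = np.arange(N) // W
    jj = np.arange(N) % W
    # offset of the key pixel (second index) relative to the query (first index)
    dr = ii[None, :] - ii[:, None]
    dc = jj[None, :] - jj[:, None]
    inside = (np.abs(dr) <= S - 1) & (np.abs(dc) <= S - 1)
    bmat = np.zeros((nh, N, N))
    r_idx = np.clip(dr + S - 1, 0, 2 * S - 2)
    c_idx = np.clip(dc + S - 1, 0, 2 * S - 2)
    for h in range(nh):
        bmat[h] = np.where(inside, bias[h][r_idx, c_idx], 0.0)
    logits = (np.einsum("bhnd,bhmd->bhnm", q, k) + bmat[None]) / scale
    logits -= logits.max(axis=-1, keepdims=True)
    wgt = np.exp(logits)
    wgt /= wgt.sum(axis=-1, keepdims=True)
    out = np.einsum("bhnm,bhmd->bhnd", wgt, v)
    out = out.transpose(0, 2, 1, 3).reshape(B, N, C)
    out = _project(out, params["wo"], params["bo"])
    return out.reshape(B, H, W, C).transpose(0, 3, 1, 2)


def na_operation_count(H: int, W: int, S: int, embed_dim: int, num_heads: int) -> int:
    """Multiply-accumulate proxy for one NA pass: linear in H*W at fixed S."""
    hd = embed_dim // num_heads
    per_pixel = num_heads * (S * S) * (2 * hd + 1)  # logits + weighted sum + softmax
    proj = 4 * embed_dim * embed_dim               # q, k, v, output projections
    return H * W * (per_pixel + proj)
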
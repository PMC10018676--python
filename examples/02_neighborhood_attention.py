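"""Neighborhood attention versus dense self-attention on a small image.

Shows (a) that each pixel's attention weights over its S x S window form a
probability distribution, and (b) that when the window covers the whole
image, the localized operator coincides with dense self-attention.
"""

import numpy as np

from natseg import AttentionConfig, MultiHeadNeighborhoodAttention, Tensor
from natseg.na import full_self_attention_oracle, na_operation_count

rng = np.random.default_rng(0)
cfg = AttentionConfig(embed_dim=8, num_heads=2, neighborhood_size=5)
attn = MultiHeadNeighborhoodAttention(cfg, np.random.default_rng(1))

x = rng.standard_normal((1, 8, 5, 5)).astype(np.float32)
out, weights = attn(Tensor(x), return_weights=True)
print(f"input {x.shape} -> output {out.shape}")
print(f"attention weights per pixel sum to {weights.sum(axis=-1).mean():.6f} "
      f"(softmax over S^2 = {cfg.neighborhood_size ** 2} neighbors)")

dense = full_self_attention_oracle(x, cfg, attn.export_params())
print(f"max |NA - dense SA| with a window covering the image: "
      f"{np.abs(out.data - dense).max():.2e}  (NA is a localization of SA)")

c64 = na_operation_count(64, 64, 5, 8, 2)
c128 = na_operation_count(128, 128, 5, 8, 2)
print(f"operation count grows {c128 / c64:.1f}x when pixels grow 4x "
      f"(linear in H*W at fixed window)")
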
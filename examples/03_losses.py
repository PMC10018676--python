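"""The compound training loss and its closed-form sanity checks.

Evaluates the three components (multi-scale SSIM, focal, Tversky) on a toy
prediction and shows the limits that pin down their semantics: a perfect
prediction scores zero everywhere, and the total is the (5, 3, 1)-weighted
sum of the parts.
"""

import numpy as np

from natseg import (FocalConfig, MixedLossConfig, MsSsimConfig, TverskyConfig,
                    focal_loss, mixed_loss, ms_ssim_loss, one_hot, tversky_loss)

rng = np.random.default_rng(0)
labels = np.zeros((1, 48, 48), dtype=int)
labels[0, 12:30, 12:30] = 1
target = one_hot(labels, 2)

noisy = np.clip(target + 0.2 * rng.standard_normal(target.shape), 1e-6, 1.0)
noisy /= noisy.sum(axis=1, keepdims=True)

cfg = MixedLossConfig(msssim=MsSsimConfig(num_scales=2))
total, parts = mixed_loss(noisy, target, cfg)
print(f"noisy prediction: total {float(total.data):.4f} "
      f"= 5*{parts['msssim']:.4f} + 3*{parts['focal']:.4f} + 1*{parts['tversky']:.4f}")

perfect, perfect_parts = mixed_loss(target, target, cfg)
print(f"perfect prediction: total {float(perfect.data):.6f} (all components vanish)")

p = np.full((1, 1), 0.5)
t = np.ones((1, 1))
print(f"\nfocal single pixel, Yp=0.5, gamma=2: "
      f"{float(focal_loss(np.stack([p, 1 - p])[None].reshape(1, 2, 1, 1), np.stack([t, 1 - t])[None].reshape(1, 2, 1, 1), FocalConfig(gamma=2)).data):.6f}"
      f"  (hand value (1-0.5)^2 * -log 0.5 = {0.25 * -np.log(0.5):.6f})")

tv = tversky_loss(np.r_[1, 1, 0, 0, 1, 1, 0, 0, 0, 0.],
                  np.r_[1, 1, 1, 1, 0, 0, 0, 0, 0, 0.], TverskyConfig(alpha=0.5))
print(f"Tversky TP=2 FP=2 FN=2, alpha=beta=0.5: {float(tv.data):.3f} (hand value 0.4)")
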
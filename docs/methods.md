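# Methods

## Network

Three identical-architecture encoders (independent weights) process the
bSSFP-like, LGE-like and T2-like channels. The tokenizer is two 3×3
stride-2 convolutions with a ReLU between them; stages run at 1/4, 1/8 and
1/16 resolution with `embed_dim · 2^(stage−1)` channels. Blocks use pre-norm
residual ordering (`x + NA(LN(x))`, then `+ MLP(LN(·))`); the MLP expands by
`mlp_ratio` (default 3) with GELU. Between stages a single 3×3 stride-2
convolution halves space and doubles channels.

**Neighborhood attention.** Windows are clamped (shifted inward) at image
borders so the softmax is always over exactly S² real pixels; this keeps the
operator well defined at borders without zero-padding artifacts. Under
clamping, relative offsets reach ±(S−1) per axis, which the
(2S−1)×(2S−1) bias table covers exactly; the bias is added to the raw dot
product *before* division by `scale` (default √head_dim). Q, K, V and the
output projection are learned linear maps. Default S = 7, exposed in
config. When a stage's feature map is smaller than the configured window
(which happens at 1/16 resolution for desk-scale inputs), the encoder
shrinks the window for that stage to the largest odd size that fits; the
standalone attention operator treats an oversized window as a configuration
error instead.

**Gated fusion.** The gate convolution is 1×1 with exactly 3 output channels
(one spatially varying weight map per modality, broadcast across that
modality's feature channels); the fusion convolution is 3×3. Within one
stage all three inputs share resolution, so no resampling is needed. Fusion
blocks are instantiated independently at each of the three stages.

**ASPP.** Four parallel 3×3 convolutions at dilation rates {1, 6, 12, 18}
with padding equal to the rate (size-preserving by the dilated-convolution
size formula), concatenated and projected 1×1, ReLU after the projection. The
rate-1 branch is a plain 3×3 convolution — there is no 1×1 or image-pooling
branch. No normalization inside branches at desk scale.

**Decoder.** The coarsest fused level (after ASPP) is upsampled ×2
(bilinear, half-pixel centers) three times; the first two upsamplings
concatenate the fused skip of the matching resolution before a 3×3
convolution + ReLU; above 1/4 resolution no skip exists, so two plain
upsample+conv blocks recover full resolution, followed by a 1×1 class head.
Fused (not per-modality) skips feed the decoder.

**Ablation switches.** `use_nvt=False` replaces each attention block with a
residual pair of 3×3 convolutions; `use_mgf=False` replaces gated fusion
with concatenation + 1×1 projection; `use_aspp=False` replaces the
bottleneck with a single 3×3 convolution. All 8 combinations are exercised
in tests.

## Losses

All components consume softmax probabilities. The structural and Tversky
terms are computed per foreground-class map and averaged over the five
foreground classes; the focal term sums over the one-hot class axis per
pixel (so at focusing exponent 0 it is exactly cross-entropy) and averages
over pixels and batch by default.

**MS-SSIM.** Local statistics use a uniform N×N window (N = 11 default),
population (biased) normalization, computed only at fully-interior window
positions; constants C₁ = 0.01², C₂ = 0.03², C₃ = C₂/2 assume inputs in
[0, 1]. Contrast and structure terms enter at every scale and luminance only
at the coarsest; the per-position products are averaged per scale and the
scale averages multiplied, so at M = 1 the value is exactly single-scale
SSIM with a uniform window (verified against an independent reference
implementation to 1e-5). Scales are linked by 2×2 mean pooling; M = 3 by
default so 72×72 maps and larger survive the downsampling chain, and an
image too small for the requested M raises an error naming the feasible
maximum. The loss is 1 − MS-SSIM, so identical maps score 0. Standard-
deviation terms use √(max(var, 0) + 1e-12) for gradient stability.

**Focal.** Probabilities are clamped to [1e-7, 1] inside the log. Default
focusing exponent 2.

**Tversky.** `1 − (1 + TP)/(1 + TP + α FP + β FN)` with the additive 1
exactly as the smoothing term; α = 0.3, β = 1 − α by default (penalizing
false negatives harder suits small lesions). At α = β = 0.5 it reduces to
soft Dice with unit smoothing.

**Mixing.** Total = 5·L_MS-SSIM + 3·L_focal + 1·L_Tversky. Only the
structural weight (5) and the ratio η = 3θ are prescribed; θ = 1 is this
package's normalization choice.

## Synthetic phantoms

Each case draws a geometry from seeded ranges: LV disc radius 0.10–0.14 of
the image side, myocardial annulus thickness 0.05–0.08, an RV crescent
formed by a disc hugging the epicardium with the LV region subtracted, an
infarct sector of 50–120° inside the annulus, and an edema margin of
12–30° flanking the infarct within the annulus. Intensities come from a
3-modality × 6-class contrast table encoding the clinically meaningful
orderings (LGE brightest in infarct, T2 brightest in edema, bSSFP maximizing
myocardium/blood contrast); a Gaussian blur (σ = 1.5 px) of the
class-intensity map creates the fuzzy boundaries that make the task
non-trivial, and i.i.d. Gaussian noise (σ = 0.05) is added and the result
clipped to [0, 1].

What the phantoms do **not** emulate: real anatomical shape variation,
through-plane effects, coil-profile bias fields, modality misregistration,
and pathology whose contrast violates the canonical orderings. Passing the
phantom experiments therefore demonstrates that the architecture, losses,
optimization and evaluation machinery work and that the network can exploit
modality-specific contrast — it does not predict Dice on clinical data.

Augmentation follows the standard chain: non-rigid warping by a bilinearly
upsampled 8×8×2 displacement grid drawn uniformly in [−a, +a] (image
resampled bilinearly, labels nearest-neighbor, edge-clamped), then a
rotation drawn uniformly from {90°, 180°, 270°}. Center cropping (low-side
bias on odd margins, no padding) handles oversized inputs.

## Training protocol

Two named profiles:

| | desk | paper-scale |
|---|---|---|
| image size | 96 | 288 |
| embed_dim / depths / heads | 16 / (1,1,1) / (2,4,8) | 32 / (2,2,2) / (2,4,8) |
| optimizer | Adam, lr 1e-3, cosine decay to lr/10 | Adam, lr 1e-4, constant |
| epochs × passes/epoch | 20 × 4 augmented passes | 200 × 1 |
| batch size | 1 | 4 |
| warp amplitude | 1.5 px | 4 px |

The desk profile is sized so a full experiment (25 phantoms, 4:1 split)
finishes in minutes on one CPU. Its choices compensate for the short
optimization budget: batch 1 with four augmented passes over the training
set per epoch gives 1600 gradient steps in 20 epochs; cosine decay
stabilizes the late epochs; the warp amplitude is scaled down roughly with
the image side (1.5 px at 96 px vs 4 px at 288 px) so the deformation
magnitude relative to structure size matches. The paper-scale profile keeps
the conventional settings (Adam 1e-4, batch 4, 200 epochs, amplitude 4).

The single-case overfitting probe (`overfit_single_case`, 200 steps on one
case) uses its own stabilized schedule: twice the profile learning rate with
a 20-step linear warmup and global gradient-norm clipping at 1.0. At a
200-step budget the compound loss produces large early gradients, and
without clipping the probe's outcome varies strongly with initialization;
with it the probe reaches foreground Dice ≥ 0.95 reliably.

Model parameters are initialized Kaiming-normal from a generator seeded by
the config; the data split, augmentation draws and batch order derive from
the run seed, so identical configs reproduce bit-identical logs on one
thread. Checkpoints are .npz parameter archives with a YAML sidecar carrying
the model config and its hash (verified on load); the last checkpoint also
stores optimizer moments and the generator state, making runs resumable
with bit-identical continuation.

## Evaluation

Dice uses the convention empty/empty → 1, half-empty → 0. Hausdorff is the
exact max-of-min between boundary point sets (boundary = mask pixel with a
background 4-neighbor), Euclidean, scaled by pixel spacing when a NIfTI
header provides it; an empty mask yields +inf plus a warning record, never a
silent 0. Volumes are evaluated slice-wise in 2-D. Group definitions:
MI = {infarction}, MI+ME = {edema, infarction}, plus the three anatomy
classes. In dataset-level reports, a group with no truth foreground is
reported as NaN (not applicable) rather than 0, and aggregate mean/std rows
exclude non-finite values.

## Numerical notes and limitations

- The autodiff engine is dense, CPU-only float32 (float64 in tests);
  convolution uses im2col with slice-based scatter in backward, attention
  gathers use a sorted segment-sum. Determinism holds per-machine on one
  thread (BLAS reduction order is fixed for a fixed thread count).
- Argmax ties break toward the lower class index.
- The 1/16-stage attention window shrinks below the configured S for inputs
  smaller than 112 px; this is a deliberate degenerate-input policy (see
  above) rather than an error.
- 2-D slices only; no 3-D context, no deep supervision, no test-time
  augmentation, no semi-supervised use of unlabeled data.
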
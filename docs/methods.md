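# Methods

This note records the modelling assumptions, pinned constants and design
choices behind the package, in the order data flows through it.

## Input geometry and normalisation

Native AFB frames are 720×720 RGB with a circular scan area of radius
≈352 px.  The input chain is centre-crop to 704×704 (8-px margins),
bilinear downsample by exactly ×1/2 to H = 352 (so 704 = 2H and
H = 11·32, keeping the deepest feature grid an integer 11×11), then
per-channel standardisation with the ImageNet statistics
(mean 0.485/0.456/0.406, std 0.229/0.224/0.225) — the encoder is designed
around ImageNet-pretrained weights, so inputs are normalised to that
distribution even when training from random init.  Frames that are not
720-sized (e.g. public polyp sets) skip the crop and resize directly: the
crop exists to trim the scan border, not as a general policy.

Masks follow the same geometry with nearest-neighbour resampling
(binarity-preserving).  The inverse map — ×2 nearest upsample of the
352-mask to 704 plus an 8-px zero-pad border — makes the
crop/downsample/upsample cycle self-consistent; a round-trip preserves
Dice ≥ 0.9 for regions at or above the 800-px significant-lesion scale
(verified in tests).  The downsample kernel at other scales is the same
half-pixel-centre bilinear map; at the exact ×1/2 factor it coincides with
2×2 block averaging.

## Encoder

The backbone is the hierarchical Mix Transformer in its three published
scales.  Widths are B0 = (32, 64, 160, 256) and B2/B4 = (64, 128, 320, 512).
Depths, head counts and reduction ratios are pinned to the reference
configuration: depths B0 = (2,2,2,2), B2 = (3,4,6,3), B4 = (3,8,27,3);
heads (1,2,5,8); spatial-reduction ratios (8,4,2,1); FFN expansion 4;
stage-1 patch embedding 7×7/stride 4/pad 3 and 3×3/stride 2/pad 1
thereafter.  These constants are corroborated by the parameter-count
targets: any other assignment misses the published totals.  Positional
information enters only through the Mix-FFN depth-wise 3×3 convolution (no
positional encodings).  Attention keys/values are computed on a grid
reduced by an R×R strided convolution followed by layer norm; R = 1
recovers plain multi-head attention.

Initialisation: truncated normal (σ = 0.02, ±2σ) for dense weights,
Kaiming fan-out for convolutions, zeros/ones for biases and norms.
Loading the published checkpoint key layout is supported (the fused kv
projection is split, dense weights transposed); all tests run from random
init so the build needs no downloads.  Encoder weights are fine-tuned by
default during training; `freeze_encoder` restricts the optimiser to the
decoder, since the choice is application-dependent and neither option is
canonical.

## Decoder

`Linear_Layer` is a per-location channel-preserving linear projection
(C_i → C_i), `ConvModule` is 1×1 convolution + batch norm + ReLU, and the
multi-stage fusion block is the minimal reduction consistent with the
published complexity budget: a single 1×1 convolution from C_1+C_2+C_3+C_4
channels to one logit channel.  A heavier fusion stack (e.g. an
intermediate C_1-wide ConvModule) overshoots the published parameter total
for the B2 variant by ~0.07 M, so the minimal stack is the one the budget
admits.  Feature upsampling is bilinear (half-pixel centres); binarised
masks always use nearest neighbour to stay binary.  In deployment the
0.5-threshold is applied before the ×4 upsample, following the listed
operation order; because nearest upsampling commutes with thresholding
this only fixes the (otherwise ambiguous) boundary behaviour.

Ablation variants mirror the published component grid: `mf` (fusion of the
raw pyramid), `bp+mf`, `bp+af+mf`, `af+ap+mf` and `full`.  A dropped
layer's consumers read the rawest available map for the stage; only these
five graphs are constructible.  Ablation tests assert structure (shapes,
parameter budgets, finiteness), not performance ordering — the published
ordering is a trained-model property outside desk scale.

## Loss

The training loss is the boundary-weighted IoU + BCE sum.  Pixel weights
are `w = 1 + 5·|meanpool_k(G) − G|` with k = 31, stride 1 and zero padding
counted in the window (the construction of the loss the training recipe
names; k is the conventional window and is configurable).  The weighted
BCE term is `Σ w·bce / Σ w` per sample; the weighted IoU term is
`1 − (I + 1)/(U − I + 1)` with `I = Σ w·σ(x)·G` and `U = Σ w·(σ(x)+G)`;
both are averaged over the batch.  The implementation is cross-checked
against an independent scalar reference (integral-image pooling, explicit
per-pixel BCE) on random masks.

## Training recipe

Adam with lr 1e-4, β₁ = 0.9, β₂ = 0.999, no schedule and no gradient
clipping (none are part of the recipe); 200 epochs of
⌈dataset/16⌉ batches by default at the 352-px scale; model selection keeps
the epoch maximising validation mean Dice.  Case-exclusive train/val
splits are enforced with a hard error.

**Sampler.**  The published recipe draws frames with replacement under
class sampling weights 1.43 (normal) and 4.95 (lesion) and states that
this yields 8 lesion + 8 normal frames per 16-frame batch.  Those two
statements conflict: flat per-frame weighted sampling on the published
97-lesion/223-normal training index has lesion probability
97·4.95/(97·4.95 + 223·1.43) = 0.601, i.e. ≈9.6 lesions per batch.  The
default sampler therefore realises the stated training condition directly:
each slot draws the class 50/50 and then a frame within the class with
probability proportional to its weight (equal expected counts by
construction, binomial ±2 per batch).  `stratify=False` restores the flat
weighted draw, whose ≈9.6 expectation is unit-tested.  The weights
themselves do not follow from inverse class frequency of the published
split; they are kept verbatim as defaults and act only within class under
the default sampler.

**Augmentation.**  Magnitudes are not part of the published recipe and are
package defaults: horizontal/vertical flips (p = 0.5 each), right-angle
rotation (uniform k·90°), fine rotation ±15° (bilinear frame, nearest
mask), brightness and contrast jitter factors U(0.6, 1.4).  Geometric ops
hit frame and mask identically; photometric ops touch only the frame.

## Synthetic data

The generator emulates the *geometry and class structure* of circular-scan
AFB video, not its appearance: dark exterior; circular scan area of radius
352 px (π·352² ≈ 389 k px, verified within 1%); green-dominant smooth
texture (Gaussian-filtered noise, σ = 40 px) with a radial vignette;
lesions as star-convex blobs (smooth periodic radial perturbation, ±30%)
tinted reddish-brown with soft edges, areas log-uniform inside the
800–290,000-px envelope reported for real exams (the upper tail is
geometrically capped at ≈π·(346/1.3)² ≈ 220 k px because a blob must fit
inside the scan circle; requesting a minimum above that cap is an error).
Frames default to 70% single-lesion / 30% two-lesion; datasets default to
a 30% lesion-frame mix, mirroring the imbalance of a real exam archive.
Per-case frame counts are uniform (real per-case counts are unpublished).

What passing tests on this data does **not** show: segmentation accuracy
on real bronchoscopy (no specularities, bubbles, motion blur, instrument
shadows, or anatomical structure), nor the published benchmark scores,
which require GPU-scale training on the real datasets.  The synthetic
suite validates plumbing, geometry, optimisation behaviour and the
evaluation protocol.

## Evaluation protocol

Metrics are computed at the 352-px model scale against the resized ground
truth (native-scale evaluation is available through the mask
reconstruction).  Dice/IoU/MAE are unweighted means over frames;
detection recall/precision pool region counts across frames.  Conventions
pinned for reproducibility: 8-connectivity for components; the
significant-region-size filter (default 400 px, the published default;
100/800 for sensitivity sweeps) applies to predictions only; a
both-empty mask pair scores Dice = IoU = 1 (normal frames are otherwise
undefined), configurable; zero-denominator recall/precision are 1.0; a
single prediction overlapping two ground-truth regions counts two TPs
(ground-truth-centric counting, matching the published region
arithmetic: 110 detected of 117 regions → recall 0.940).

## Complexity accounting

Parameters are exact sums over trainable arrays and are checked against
closed-form per-layer formulas for both encoder and decoder.  FLOPs follow
the convention of the standard operation-count profilers: one fused
multiply-add in any matrix product (convolutions, dense layers, attention
products) counts as one operation; layer normalisation costs 5 ops per
element, inference-mode batch normalisation 2 per element, bilinear
resampling 4 per output element; bias additions, activations and softmax
are uncounted and are listed in the report.  Under this convention the
three variants report 3.5 M/1.4 G, 25.0 M/9.3 G and 61.7 M/23.9 G for a
3×352×352 forward pass.

## Numerical engine and problem sizes

All computation runs on a small reverse-mode autodiff engine over float32
numpy arrays (im2col convolutions, fused norm/attention backward passes);
every op is validated against central finite differences.  Determinism:
all randomness flows through explicit `numpy` generators, so same seed →
bitwise-identical synthesis, sampling, initialisation and training.

CPU-scale sanity runs use reduced problem sizes chosen once: the overfit
check trains the tiny variant on 8 synthetic frames at a 64-px grid for
300 steps (the architecture accepts any side divisible by 32), which
drives the loss from ≈8.9 to <0.1 and training mDice above 0.95 — small
enough for a laptop CPU, large enough to exercise every layer's gradient.
Short end-to-end training tests run at 32 px.

## Known limitations

* No GPU path and no mixed precision; wall-clock throughput is far from
  the published frame rates, which were measured with a CUDA runtime.
* Pretrained encoder weights are supported but not bundled, so headline
  benchmark accuracy is not reproducible offline at desk scale.
* The structural-similarity and enhanced-alignment metrics used by some
  polyp benchmarks are out of scope (defined in external work).
* Bilinear resampling uses dense interpolation matrices per (in, out) size
  pair — fine at these scales, wasteful for very large images.
* Video-level (temporal) analysis is out of scope; the model is
  single-frame.
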
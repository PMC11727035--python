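# Methods

## The model

`gavit` implements a hybrid CNN–ViT classifier for radiograph-like images.
A batch of `(B, S, S, 3)` images in `[0, 1]` (side `S = 224` by default)
flows through:

1. **Component blocks.** Each block is a convolutional backbone followed by
   patch embedding and a stack of pre-norm transformer encoder layers.  The
   backbone is a contract (any callable producing a spatial feature map);
   the built-in `stub` backbone is three stride-2 3×3 convolutions with
   ReLU (224 → 28, channels 8/16/32), so the library runs end to end with
   no pretrained weights.  The feature map is bilinearly resized to a fixed
   side (default 56), cut into non-overlapping 8×8 patches row-major,
   linearly projected to the hidden width (default 32) and given learned
   position embeddings.  Encoder layers are pre-norm: `x + MHA(LN(x))`,
   then `y + MLP(LN(y))`, with 2 heads, MLP width 64, GELU, and dropout
   (default 0.5) after each MLP dense layer.  No class token is used —
   downstream stages consume the full token grid spatially.
2. **Attention gate.** Block token sequences are concatenated along the
   feature dimension (all blocks must share one token grid) and refined by
   three independent multiplicative attention branches, each emitting
   weights in (0, 1): channel-wise (token-axis average+max pooling →
   tanh/sigmoid MLP with reduction ratio 8, broadcast over tokens),
   element-wise (per-token affine map `We·x + be` → tanh/sigmoid MLP, one
   weight per entry), and spatial (grid reshape, channel-axis average+max
   planes, 7×7 convolution + sigmoid, broadcast over channels).  The three
   attended maps are concatenated — output width is 3× the input.
3. **Multi-scale fusion (MSFM).** The gated tokens, reshaped onto their
   `(Hp, Wp)` grid, pass four parallel same-padded branches — 1×1, 3×3 and
   5×5 convolutions, and hybrid pooling followed by a 1×1 convolution —
   each ReLU-activated and concatenated along channels (4 × branch width,
   default 64 per branch).
4. **Head.** Flatten, Dense 1024 + ReLU + dropout, Dense 128 + ReLU +
   dropout, Dense `num_classes` + softmax.

### Hartley spectral pooling

The discrete Hartley transform `H(u,v) = Σ f(x,y)·cas(2π(ux/M + vy/N))`
with `cas t = cos t + sin t` is real-to-real and self-inverse up to a
`1/(MN)` scale.  It is computed as `Re(FFT) − Im(FFT)` and validated in
the tests against a direct cas-sum oracle.  Spectral pooling keeps the
centered low-frequency block of side `⌈ρM⌉ × ⌈ρN⌉` (DC rotated to the
array center before cropping; even block sides keep the extra row/column
on the low-index side) and zeroes everything else, then inverts.  Because
branch outputs are concatenated along channels, the filter is
shape-preserving (zeroing high frequencies) rather than size-reducing.
Default retain fraction ρ = 0.5 and max-pool window 3: halving the
retained bandwidth per axis mirrors the information budget of a 2× pool.
Hybrid pooling concatenates the stride-1 max-pooled and the low-passed map
along channels (`sum`/`mean` are available as configurable alternatives);
the 1×1 convolution of MSFM branch 4 folds the doubled channel count back
to the branch width.  The low-pass operator is linear and self-adjoint
(symmetric transform matrix, diagonal mask), so its autodiff backward pass
applies the same filter to the incoming gradient.

### Numeric engine

No deep-learning framework is used: `gavit._tensor` is a small
reverse-mode autodiff over float64 NumPy arrays with exactly the
primitives the architecture needs (broadcasted arithmetic, batched matmul,
reductions, same-padded strided convolution via im2col, stride-1 max pool,
bilinear resize as a precomputed linear operator, Hartley low-pass,
dropout, softmax/log-sum-exp).  Gradients are verified against central
finite differences in the test suite.

### Initialization and optimization

Dense/conv weights use Glorot-uniform; ReLU-facing layers use He-uniform;
biases start at zero; position embeddings are truncated-normal (σ = 0.02);
the two residual-branch output projections of every encoder layer (MHA
output projection and second MLP dense) are scaled by 0.1 so each layer
starts near the identity — without this, small stacks occasionally start
"dead" (uniform logits) at high learning rates and never recover.  All
initialization derives from a single model seed; identical config + seed
reproduces bit-identical weights.

Training is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with categorical
cross-entropy, initial learning rate 1e−5 by default, and a
reduce-on-plateau schedule: if the validation loss has not strictly
improved for 5 consecutive epochs, the learning rate is multiplied by 0.1
(floor 1e−8).  Gradients are clipped to global norm 5.  The weights with
the best validation loss are restored at the end of training
(`restore_best`, on by default) — late-run optimization excursions at
elevated learning rates otherwise discard a converged solution.  One run
seed fans out to independent streams for shuffling, dropout and
augmentation.  Default epochs 51 and batch 32 are the intended real-data
settings; the desk-scale smoke configuration overrides them (below).

### Augmentation

CutMix draws λ ~ Beta(α, α) (α = 1), cuts a `√(1−λ)`-sided rectangle at a
uniform center (clipped at borders), pastes the partner's pixels, and
re-mixes one-hot labels by the exact pixel-area fraction, so mixed labels
are convex with weights equal to areas.  RandAugment applies N = 2
uniformly chosen transforms at magnitude M = 9 on a 0–30 scale from a
grayscale-safe pool (rotate ±30°·M/30, translate ±0.3·side·M/30, shear
±0.3·M/30, contrast/brightness/sharpness factor 1 ± 0.9·M/30, posterize,
equalize, autocontrast); color-specific operations are excluded because
inputs are replicated-grayscale radiographs.  Augmentation applies to
training batches only and each mode is independently toggleable.

## Metrics

Evaluation derives per-class one-vs-rest TP/TN/FP/FN from the multi-class
confusion matrix and computes accuracy `(TP+TN)/total`, precision
`TP/(TP+FP)`, recall `TP/(TP+FN)` and F1 `2PR/(P+R)`.  Any 0/0 case
returns 0 and the class is listed under `degenerate_classes` in the
report, so the convention is deterministic and visible.

## Synthetic data

The generator emulates 4-class chest-radiograph-like grayscale images on a
deterministic anatomical template (two bright elliptical lung fields on a
dark thorax with a border vignette): `clear_field` is the bare template;
`focal_opacity` adds 4 Gaussian blobs (σ = 6 % of the side, 70 gray
levels) inside the lung ellipses; `diffuse_haze` adds a smooth random
field (6×6 coarse grid upsampled, 45 levels) over the lungs;
`nodular_speckle` adds sparse σ = 1 px Gaussian nodules (1 % center
density, 90 levels) — nodules span a couple of pixels so they survive
backbone downsampling while remaining high-frequency.  Additive Gaussian
pixel noise (σ = 8 levels) is applied everywhere.  Classes therefore
differ in both spatial layout (exercising the spatial-attention path) and
frequency content (exercising the spectral-pooling path), and a trivial
pixel-mean threshold already separates clear from focal fields.

What this does **not** emulate: anatomical variability, acquisition
physics, annotation noise, class imbalance, or inter-dataset domain shift.
Passing tests on this data show that the architecture, gradients and
training loop work and that the pathways carry discriminative signal —
they say nothing about clinical performance on real radiographs.

## Desk-scale smoke configuration

`gavit.train_eval.run_smoke` trains a deliberately small configuration on
one CPU in about half a minute: 64×64 images, 100 per class split
60/20/20, two stub-backbone blocks with grid side 24 (3×3 tokens of width
32), 2 encoder layers, dropout 0.1, MSFM branch width 16, head (128, 32),
Adam at 1e−3 for 30 epochs, batch 16, no augmentation.  These sizes are
the package's own scaling choice for a fast end-to-end check; with a fixed
seed the run reaches ≥ 90 % test accuracy (about 0.94 on average across
seeds, with run-to-run scatter of a few points from 80 test samples and
training stochasticity).

## Known limitations

* The pretrained-backbone names (`efficientnet_b3`, `densenet121`,
  `mobilenet`) are reserved registry keys; users must plug in their own
  implementations to use them.
* The gate operates once on the concatenation of all block features; a
  per-block-gate wiring is not implemented.
* Batched training is O(n) in memory per batch through the autodiff graph;
  the engine targets correctness and desk-scale sizes, not throughput.
* ReLU 0/0 subgradient is 0; max-pool ties split gradient equally.
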
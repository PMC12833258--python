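# Methods

## Model

The model is an encoder–decoder segmenter for single-channel 2-D slices
with `C` classes (default 3: background, organ, lesion).

### Frozen backbone with low-rank and adapter insertions

The encoder is a pre-norm ViT: patch embedding (patch size 16, learned
positional embedding), then `L` blocks of multi-head self-attention and
a GELU MLP, each with a residual connection. All backbone weights are
frozen. Two kinds of small trainable insertions are added:

- **Low-rank updates** on the query and value projections only:
  `W_q x + B_q A_q x` and `W_v x + B_v A_v x`, rank `r` (default 4).
  The down-projections `A` are drawn from N(0, 0.02²); the
  up-projections `B` start at zero, so the update is inactive at
  initialisation. The key projection is left plain.
- **Bottleneck adapters** after the MLP: down-project to `b` channels
  (default 64; 16 in the tiny preset), ReLU, up-project back, with the
  up-projection zero-initialised. The default wiring is
  `y = x + mlp(ln(x)) + adapter(mlp(ln(x)))`; an alternative
  `adapter_variant="serial_adapter"` wiring `y = adapter(mlp(ln(x))) + x`
  is provided for comparison, and is also an identity insertion at
  initialisation.

Because both insertions vanish at initialisation, the whole encoder is
numerically identical to the vanilla backbone before training. This is
verified against an independent per-head loop implementation to 1e-5
(measured gap ~4e-15).

Freezing is enforced by name: parameters whose names contain
`lora_down`, `lora_up`, `adapter_down` or `adapter_up` are trainable,
every other encoder parameter has `requires_grad=False`. The autodiff
engine never allocates gradients for frozen leaves, and the optimiser
refuses to accept them, so frozen weights are bit-identical after any
number of steps (verified over 50 and 200 steps).

Features are tapped after blocks 3, 6, 9 and 12 and reshaped from token
sequences to `(B, D, H/16, W/16)` grids.

### Multi-scale hypercolumn processing (MHPM)

Each tap `Y` is processed as:

1. 1x1 convolution reducing `D` to `D/4` channels, with batch norm;
2. four parallel branches — 1x1 (dilation 1), 3x3 (dilation 1), 3x3
   (dilation 2), 3x3 (dilation 3) — each with batch norm, concatenated
   and aggregated by a 1x1 convolution back to `D` channels, plus a
   residual connection from `Y`;
3. channel attention `h' = h * (1 + sigmoid(conv1x1(GAP(h))))`, which
   scales each channel into the range `(h, 2h)`;
4. a transposed convolution (kernel = stride) for upsampling, then a
   3x3 convolution with batch norm producing the hypercolumn map `M`.

### Progressive hierarchical fusion decoder (PHFD)

Stages run from the deepest tap to the shallowest. Stage 1 refines a
1x1-projected `M_deepest`; stage `k > 1` concatenates `[M_k; F_{k-1}]`,
compresses with a 1x1 convolution, and refines with the hierarchical
fusion module (HFM). The HFM combines three branches over input `d`:

- global: `d * (1 + sigmoid(W_g GAP(d)))` over all channels;
- regional: the channels are split into `k = 4` groups, each with its
  own gate of the same form, concatenated back in order;
- local: a 1x1 convolution of `d`;

and fuses the concatenated `3C` channels with a final 1x1 convolution.

Each stage has a 1x1 classification head; stage logits are bilinearly
upsampled to image resolution (half-pixel-centre convention, exact
adjoint in the backward pass) and a final 1x1 convolution over the
concatenated `4C` stage logits produces the fused prediction.
Predictions are the per-pixel argmax, ties broken toward the lowest
class index.

### Loss and metrics

The loss is mean per-pixel softmax cross-entropy. For two classes this
reduces exactly to the sigmoid binary cross-entropy of the logit margin
`z = s_1 - s_0`, i.e. `mean(log(1 + e^z) - g z)`; the implementation is
verified against that closed form to 1e-10. Deep supervision sums the
cross-entropy over the four stage heads and the fused head with
configurable weights (default all 1).

Dice `2|A∩B| / (|A|+|B|)` and IoU `|A∩B| / |A∪B|` are computed from
pixel-set cardinalities per class and per image, then macro-averaged
over foreground classes by default. An empty class in both masks scores
1.0. The identity `dice = 2 iou / (1 + iou)` holds to machine
precision and is property-tested.

## Training

AdamW with decoupled weight decay 0.1, base learning rate 1e-3 dropped
10x every 20 epochs, 50 epochs, batch size 16 (defaults). Only
trainable parameters enter the optimiser. Random state fans out from a
single seed via `SeedSequence.spawn`, giving one stream for shuffling
and one per-epoch stream for augmentation, so runs are bit-reproducible.

## Ablation ladder

Presets A–G each add one component: A linear head on the frozen
encoder; B +LoRA; C +adapters; D +decoder; E +HFM; F +MHPM; G +deep
supervision. In variant D the HFM is replaced by a plain convolutional
bottleneck (3x3 to C/4, ReLU, 1x1 back to C) so that enabling the HFM
in E strictly adds parameters; G adds supervision terms but no
parameters. Tiny-preset trainable counts: 291 / 18 723 / 56 931 /
87 507 / 98 803 / 470 803 / 470 803.

## Phantom generator

`generate_phantom` renders: a rotated elliptical organ; one or two
lesions as Fourier-perturbed blobs (harmonics 2–4, radial wobble
clipped to [0.3, 1.7]) intersected with the organ; class intensity
offsets scaled by a `contrast` parameter; additive Gaussian noise; and
quantisation to 16-bit grayscale. Masks are written as paletted 8-bit
PNGs with a TSV manifest; the round trip is lossless. NIfTI volumes can
be sliced into the same layout. The generator is a controlled testbed,
not an imaging simulator: it has no partial-volume effects, no bias
fields, and no anatomical realism beyond "dim lesion inside organ".

## Numerical choices

- **Pure-NumPy autodiff.** The training stack is a tape-based
  reverse-mode engine (`hfseg.nn`); convolutions loop over kernel
  offsets with einsum contractions, bilinear upsampling is a separable
  linear map with an exact adjoint, and batch norm keeps unbiased
  running statistics for evaluation mode.
- **Head small-initialisation.** The stage heads and final fusion
  weights are scaled by 0.01 at initialisation. Without this the
  randomly combined multi-stage logits start with per-pixel losses in
  the tens and the first optimiser steps are spent undoing them.
- **Tiny-preset deconvolution stride 4.** At width 96 with 64x64 inputs
  the taps are 4x4. A stride-2 deconvolution gives an 8x8 decoder grid
  whose bilinear-upsampling basis cannot represent typical phantom
  masks beyond mDice ≈ 0.84 (computed by least-squares projection of
  one-hot masks onto the upsampling basis, independent of any
  training); stride 4 gives a 16x16 grid with a ceiling ≈ 0.95+. The
  base preset keeps stride 2, where taps are already 14x14.
- **Overfit-recovery recipe.** The memorisation check uses a constant
  learning rate (`lr_drop_every=200` over 200 steps): the default
  20-epoch decay is calibrated to multi-step epochs, and with one step
  per epoch it would cut the rate 100x before convergence.

## Limitations

- CPU-only and small-scale: the base preset builds but is not intended
  for large-image training in this implementation.
- 2-D slices only; volumes are handled by slicing.
- No pretrained backbone weights ship with the package;
  `load_pretrained` can import a compatible `.npz` by name mapping.
- The phantom generator covers geometry/contrast/noise axes only;
  conclusions about real clinical data require real data.
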
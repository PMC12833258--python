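# hfseg

Hierarchical-fusion segmentation of low-contrast lesions with a frozen
vision-transformer backbone, implemented in pure NumPy.

The scientific problem: lesions in soft-tissue imaging (the motivating
case is rectal-lesion segmentation in CT/MR slices) sit inside an organ
at very low intensity contrast, so a segmentation model needs both
global context to find the organ and fine multi-scale detail to trace
the lesion boundary. Training a large backbone from scratch on small
clinical datasets overfits, so this package follows the
parameter-efficient fine-tuning recipe: keep a ViT encoder frozen and
train only small low-rank and adapter insertions plus a lightweight
multi-scale decoder.

## Architecture

- **Encoder** (`hfseg.encoder`): pre-norm ViT. Each block's Q and V
  projections carry low-rank (LoRA) updates `W + B A` with the up
  projection `B` zero-initialised; a bottleneck adapter
  (down-project, ReLU, up-project, zero-initialised up) follows the MLP.
  Everything else is frozen, so at initialisation the network is exactly
  the vanilla backbone. Feature maps are tapped at blocks 3, 6, 9, 12.
- **MHPM** (`hfseg.mhpm`): each tap is channel-reduced, passed through
  four parallel dilated-convolution branches (dilations 1, 1, 2, 3),
  re-aggregated with a residual connection, gated by channel attention
  `h * (1 + sigmoid(conv(GAP(h))))`, and upsampled by a transposed
  convolution into a hypercolumn map.
- **Decoder** (`hfseg.decoder`): progressive hierarchical fusion from
  the deepest tap to the shallowest. Each stage concatenates the current
  hypermap with the previous fused feature, compresses with a 1x1
  convolution and refines with the hierarchical fusion module (HFM):
  a global channel gate, grouped regional gates, and a local 1x1 branch
  fused by one more 1x1 convolution.
- **Supervision** (`hfseg.losses`, `hfseg.metrics`): softmax
  cross-entropy at every stage head plus the fused head (deep
  supervision); Dice and IoU computed per class from set cardinalities.
- **Data** (`hfseg.phantoms`): a seeded synthetic phantom generator
  (elliptical organ, irregular Fourier-perturbed lesions, tunable
  contrast and noise), PNG/TSV dataset round-trip, and NIfTI slicing.

No deep-learning framework is required: `hfseg.nn` is a small
reverse-mode automatic-differentiation engine over NumPy arrays with
the convolution, normalisation and optimiser primitives the model needs.

## Worked example

`examples/02_train_and_evaluate.py` trains the tiny preset (12 blocks,
width 96, 64x64 inputs) on eight synthetic phantoms for 200 steps —
about two minutes on one CPU core:

```text
module  frozen   trainable
encoder 1368288  56640
mhpms   0        384416
decoder 0        29747
total   1368288  470803
loss: 5.520 -> 0.034 over 200 steps
class   dice    iou
1       0.989   0.979
2       0.971   0.944
mDice 0.980  mIoU 0.961
```

The frozen encoder (1.37 M parameters) never changes; only the 0.47 M
inserted parameters train. The same workflow is available from the
command line:

```bash
hfseg generate --n 8 --size 64 --seed 0 --out data/
hfseg train --data data/ --preset tiny --out run/
hfseg eval --data data/ --checkpoint run/checkpoint.npz
hfseg params --preset tiny
hfseg ablate --data data/ --out run/ --variants A,B,C,D,E,F,G
```

The component ladder A-G (`examples/03_ablation_ladder.py`) adds one
component per rung — linear head only, +LoRA, +adapters, +decoder,
+HFM, +MHPM, +deep supervision — with trainable counts 291, 18 723,
56 931, 87 507, 98 803, 470 803, 470 803.

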
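# Methods

## Problem

Fluorescence (FISH) photographs show bright, roughly elliptical cells on a
dark background.  Cells cluster and adhere: neighbouring contours touch or
overlap, and segmentation models without an explicit attention mechanism
tend to merge adjacent cells into one region.  `seamseg` implements a
nested-U-Net contour segmenter whose final decoder features are re-weighted
by a SEAM attention block, together with everything needed to study it
end-to-end on synthetic data: a scene generator with exact ground truth, an
augmentation pipeline, the metric suite, and a training/comparison harness.

## Models

**UNet++ grid.**  Convolutional nodes `X[i][j]` sit on a triangular grid
(encoder depth `i`, skip stage `j`, `i + j ≤ D − 1`; `D(D+1)/2` nodes in
total).  Column `j = 0` is a plain encoder (two 3×3 conv → batch-norm →
ReLU stages per node, 2×2 max-pool between rows).  Every later node
concatenates all earlier nodes of its row with a bilinearly upsampled,
1×1-projected neighbour from the row below and applies the same
double-conv block:

    X[i][j] = ConvBlock( [ X[i][0], …, X[i][j−1], up(X[i+1][j−1]) ] )

The last top-row node feeds a 1×1 convolution and a sigmoid, giving a
per-pixel foreground probability.  The plain U-Net baseline shares the
encoder column and block definitions but uses a single decoder path with
one skip per level, so the two baselines differ exactly by the dense skip
pathways.

**SEAM attention.**  SEAM-UNet++ inserts one SEAM block between the final
top-row node and the head (and nothing else differs — substituting the
identity for the block reproduces stock UNet++ bit-for-bit, which is a
test).  The block:

1. runs `n_branches = 3` CSMMs in parallel — each a depthwise convolution
   of kernel (patch size) 7, a pointwise 1×1 convolution, a GELU, and a
   residual connection;
2. average-pools each branch over space to a per-channel descriptor and
   averages the branches;
3. gates the pooled descriptor through a two-layer MLP
   (`C → max(C/4, 8) → C`) with a sigmoid, giving `g ∈ (0, 1)` per
   (batch, channel);
4. outputs `x ⊙ exp(g)`, so every channel is scaled by a factor in
   `[1, e]`.

The exponential acts on the gate itself.  The source description of this
step is ambiguous — the re-weighting could also be read as exponentiating
the gate multiplied by the (unbounded) pooled descriptor — but only the
gate-only reading is consistent with the stated `[1, e]` multiplier range,
so it is the default; the product variant is available as
`SeamConfig(gate_times_pooled=True)` for ablation, with no range guarantee.
Two further choices the source leaves open: the MLP bottleneck ratio
(default 4 with a hidden-width floor of 8, since the attachment point is
narrow) and the branch activation (GELU; configurable).

**Loss.**  `loss = 0.5 · BCE(p, t) + 1.0 · (1 − softDice(p, t))` with
`softDice = (2Σpt + ε)/(Σp + Σt + ε)`, ε = 1e−5, probabilities clipped to
`[1e−7, 1 − 1e−7]` inside the BCE term.  The 0.5/1 weighting is the
published protocol.

**Metrics.**  Precision, recall, accuracy, IoU and Dice from per-pixel
confusion counts; datasets aggregate by summing counts before taking
ratios (micro-averaging).  Conventions for degenerate denominators:
precision/recall return 0 with a warning; IoU/Dice return 1 when both
masks are empty (nothing to find, nothing found).  Evaluation binarizes at
0.5 (configurable).  The identity `Dice = 2·IoU/(1+IoU)` holds exactly on
shared counts and is property-tested.

## Synthetic scenes

The generator emulates the features of FISH photographs that matter for
this architecture: dark background (level 0.06), bright elliptical cells
(peak intensity 0.55–1.0 with a smooth radial falloff `(1 − ρ²)^0.35`),
clustering/adhesion, Gaussian optical blur (σ = 1 px) and sensor noise
(σ = 0.02 on the [0, 1] scale).  Placement is sequential: with probability
`adhesion_level` (default 0.5) a new cell is planted against a random
existing cell at a center distance below the sum of semi-major axes,
otherwise it is rejection-sampled so its bounding circle cannot intersect
any placed cell.  At adhesion 0 all cells are provably disjoint; the
touching fraction and mean pairwise overlap rise with the level
(property-tested over seeds).  Masks and instance labels come from the
geometry, not from the rendered image: the mask is the union of ellipse
interiors on the pixel lattice, and overlapping pixels belong to the cell
with the nearest center (ties to the lower id).  Images are quantized to
8-bit levels at render time so PNG round-trips are bit-exact.

What the generator does **not** model: irregular (non-elliptical) cell
shapes, intra-nuclear probe spots, multi-channel staining, realistic PSFs,
uneven illumination, or annotation noise.  Passing tests on this data
therefore demonstrate that the implementation is correct and that the
architecture can separate adherent elliptical blobs; they say nothing
about accuracy on real micrographs.

## Data preparation

Labelme polygons rasterize with an even-odd fill evaluated at pixel
centers (pixel `(r, c)` covered iff `(r+0.5, c+0.5)` is inside), verified
against a shapely oracle.  Augmentation is restricted to the five
published operations.  Choices where the source is silent: rotation is
limited to right angles (lossless on masks); "raising the gray value" is
gamma correction with γ < 1 (default 0.7) — monotone, bounded, and
matching the stated intent of stretching the dynamic range; noise defaults
to σ = 0.03.  The published per-operation counts (371/199/199/769/769,
total 2307) are reproduced by `paper_plan()`; its "flipping" and
"mirroring" entries are mapped to vertical and horizontal flips
respectively.  Tiling anchors the final row/column flush with the image
edge rather than padding, so no pixels are invented.

## Numerical engine

The networks run on a small reverse-mode automatic-differentiation engine
over NumPy arrays (`seamseg.autograd`).  Convolutions are stride-1 with
zero padding and are computed as sums over kernel offsets (each tap a
channel matmul against a shifted view), which keeps the arithmetic in BLAS
without large im2col buffers; their gradients are themselves shift-and-add
convolutions and match finite differences to ~1e−9 on float64 instances.
Batch normalization is a fused op with the closed-form backward through
the batch statistics.  Max-pool ties route the gradient to the first
maximum.  Bilinear upsampling uses fixed half-pixel interpolation matrices
(exactly linear; transposed for the backward pass).  Models default to
float32; float64 is used in gradient tests.  Everything is seeded through
explicit `numpy.random.Generator` objects — no global state — so training
runs are bit-reproducible on a given platform.

## Training protocol and presets

SGD with momentum 0.9 and weight decay 1e−4 on the BCE+Dice loss; 80/20
train/test split (train size = round-half-up, so 2307 → 1846/461); model
selection by maximum test-set IoU with earlier epochs winning ties (this
mirrors the published "maximum results after convergence" protocol and is
deliberately test-set selection; treat the selected score accordingly).
No learning-rate schedule (only an initial rate is published).

* **paper preset**: depth 5, widths 32–512, 256×256×3 inputs, lr 0.001,
  200 epochs, batch 16 — the full published protocol (the original
  246-image dataset is private, so only the protocol is reproduced).
* **desk preset**: depth 3, widths 8/16/32, 64×64 synthetic scenes with
  3–7 cells of semi-major axis 5–10 px, 50 images (40/10 split), 30
  epochs, batch 8, lr 0.05.  This is the configuration the test suite and
  the acceptance script run; the sizes are chosen so a full three-model
  comparison completes in minutes on one CPU core.  The larger constant
  learning rate compensates for the ~40× shorter schedule; with the
  published 0.001 the desk schedule would end far from convergence.

The comparison harness trains every named model on byte-identical splits
and schedules and reports Accuracy, Loss (test-set BCE+Dice of the
selected checkpoint), IoU, Recall, Precision and Dice, plus a supplement
restricted to pixels within 3 px (Chebyshev) of an inter-cell boundary —
the region where adherent contours are hardest and where the attention
mechanism is supposed to help.

## Known limitations

* Synthetic-only validation; the published full-scale scores are not
  reproducible without the private data and are not targets here.
* CPU-bound: the full-scale `paper` preset is supported but slow (hours).
* Single-channel (binary) segmentation only; no instance-level metrics.
* Deep supervision is implemented as an averaged multi-head output but is
  off by default and lightly exercised.
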
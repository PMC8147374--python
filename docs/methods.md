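# Methods

This note documents the models, numerical choices, and study conditions
behind `saseg`, in the package's own terms.

## The segmentation model

The per-slice unit is an encoder–decoder with four resolution steps.
Every encoder level applies two 3×3 convolutions, each followed by batch
normalization (BN) and ReLU; levels are separated by 2×2 max pooling
(stride 2), so the bottleneck sits at 1/16 of the input resolution.
Every decoder step upsamples 2× (nearest neighbour), concatenates the
equal-resolution encoder map, and applies two 2×2 convolutions with
BN/ReLU; the even 2×2 kernel keeps spatial size through asymmetric
padding (one extra row/column on the bottom/right). A 1×1 convolution
with a sigmoid produces the per-pixel foreground probability;
predictions are binarized at 0.5. Convolutions followed by BN carry no
bias (the BN shift subsumes it); only the output 1×1 convolution has
one.

**Recurrence.** The unit input is two channels: the current normalized
slice and the previous slice's predicted probability map. The sweep runs
along ascending z (inferior → superior) in a single direction, with an
all-zeros map at the first slice — the least-informative
initialization. Exactly one previous map is fed (no longer history).
During training the recurrence is unrolled over windows of U = 4
consecutive slices with shared weights and truncated backpropagation
through the window; the previous-map input inside a window is the
model's own prediction (matching test time — no teacher forcing).

**Prior path (PSFE).** An auxiliary encoder reads a 1-channel slice of
the voxelized mean mandible shape: one 3×3 stride-2 convolution block
(BN, ReLU), then two residual blocks, each holding two depthwise
separable convolutions (DSConv: per-channel 3×3, then 1×1 channel
fusion) with BN, a ReLU after the residual sum, a 1×1 projection on the
skip when widths change, and 2×2 max pooling. The stride-2 entry plus
one pool per block reaches 1/8 resolution; one extra 2×2 max pool after
the second block aligns the output with the 1/16 encoder bottleneck.
The prior features are concatenated onto the bottleneck between its two
convolutions, so the bottleneck's second 3×3 convolution consumes the
widened stack and fuses image and prior features before decoding.

At inference the PSFE input for axial position z is the mean-shape slice
at the same *relative* depth (z/depth), resampled in-plane to the
network input size; the prior is deliberately not registered per patient
— it acts as a soft spatial prior, not an atlas.

## Channel-schedule calibration

Published descriptions of this architecture family report exact network
sizes but not per-stage widths. The default schedule was therefore
calibrated once by exact parameter counting against three anchors — the
prior path at 149,440 trainable parameters, the full network at 3.80 M,
and the plain (single-slice, no-prior) baseline at 3.35 M — via integer
search over the structure described above. The frozen result:

* encoder: (24, 48, 96, 188, 380)
* PSFE: (107, 220, 87)

which yields exactly 149,440 / 3,796,109 (3.80 M) / 3,348,913 (3.35 M),
a prior-path increment of 447,196 ≈ 0.45 M. No monotone-width PSFE
schedule is jointly consistent with all three anchors under this block
structure; the compressing last stage (220 → 87) is retained and reads
naturally as a compact shape embedding next to the 380-channel image
bottleneck. Parameter counting sums every trainable scalar: conv
kernels, the single output bias, and BN scale/shift (running statistics
are buffers, not parameters).

DSConv accounting used throughout: parameters 9·C_in + C_in·C_out
(+ C_in + C_out with biases); multiply–accumulate cost relative to a
standard 3×3 convolution is 1/C_out + 1/9, independent of the feature
map size and input width.

## Mean-shape pipeline

Training masks are turned into a mean shape in five stages:

1. **Iso-surface extraction** — marching cubes at the 0.5 level of the
   mask indicator, lightly smoothed (Gaussian, σ = 0.7 voxel) before
   contouring; the smoothing removes the ~10 % area overestimate of a
   staircase surface while keeping the surface centred on the voxel
   boundary (mask → surface → voxels round-trips at Dice ≈ 0.99 on
   smooth shapes).
2. **Remeshing** towards a uniform target edge length (default 1 mm):
   the surface is rasterized on an auxiliary grid with pitch equal to
   the target edge, smoothed (σ = 0.6 voxel), and re-extracted; median
   edge lands at ≈ 1.0 pitch, enclosed volume changes < 5 %.
3. **Correspondence** — the training shape with the median vertex count
   seeds the landmarks; every other shape is mapped by rigid ICP
   (Kabsch updates on nearest-vertex matches), nearest-surface-point
   projection, and five Laplacian smoothing sweeps of the
   *displacement field* over the reference mesh adjacency (smoothing
   displacements rather than positions keeps the identity map exact),
   with a final re-projection onto the target surface. This is a
   deliberate simplification of elastic surface registration — adequate
   for averaging a family of smooth, topologically identical shapes,
   not a general anatomical registration.
4. **Generalized Procrustes alignment** — iterative superposition onto
   the evolving mean removes translation, rotation, and scale; aligned
   shapes are centred with unit centroid size, and the iteration stops
   when the mean moves < 1e−12.
5. **Mean and voxelization** — the per-landmark arithmetic mean, meshed
   with the reference connectivity, rescaled to the population's mean
   centroid size (a unit-size mean cannot live in a patient grid), and
   rasterized on a cubic grid at the median training spacing with a
   4 mm margin. Voxelization uses an even–odd z-column parity
   rasterizer: a voxel is foreground iff its centre lies inside the
   closed surface. Ray columns are jittered by distinct sub-voxel
   offsets per axis so that rays never pass through vertices, edges, or
   face diagonals (equal jitters would leave x = y diagonals
   degenerate and double-count shared-edge crossings).

## Losses and metrics

The combo loss is the weighted sum of mean binary cross-entropy and soft
Dice with ω₁ = ω₂ = 1. Probabilities are clipped to [ε, 1−ε] (ε = 1e−7)
before logs. The Dice term carries smoothing s = 1 in numerator and
denominator, defining the empty/empty case (otherwise 0/0) and keeping
all-background windows stable. The per-window training loss is the mean
over the U unrolled slices.

Evaluation metrics operate on boundary-voxel surfaces: a boundary voxel
is a foreground voxel with at least one 6-connected background
neighbour, with the grid border counting as background; boundary voxel
centres scaled by the spacing form mm point sets. ASD is the symmetric
mean of directed nearest-neighbour distances; HD the symmetric maximum;
95HD uses the inclusive ⌈0.95·n⌉-th smallest directed distance before
the maximum, which discards the largest 5 % of directed distances — the
outlier-robust variant. Two empty masks score Dice 1.0 by convention;
surface distances involving an empty mask are reported as NaN with a
warning. These voxel-centre definitions are exactly reproducible by an
O(|A|·|B|) all-pairs computation, which the tests use as the oracle.

## Synthetic phantoms

A phantom mask is the union of a half-torus body (the dental arch), two
tapered, slightly tilted cylinders (rami), and condylar/coronoid
ellipsoids, drawn from per-subject parameter distributions on a
96×96×64 grid at 0.4 mm (the fine end of clinical dental CBCT
spacing). The intensity volume is soft tissue (120) + bone (420) on the
mask, smoothed (σ = 0.6 voxel) and degraded with Gaussian noise
(σ = 40). Metal corruption places small, very bright (1500) ellipsoids
along the superior anterior arch rim with alternating bright/dark
streaks radiating through each insert in-plane, plus local blur —
an image-space emulation of reconstruction artifacts, not a physical
projection simulation.

The geometric spreads are calibrated so a generated population is
coherent but clearly varying: pairwise Dice after rigid alignment stays
within [0.5, 0.95] (measured 0.57–0.93 over eight seeds). Everything is
deterministic given the seed; population draws use spawned seed
sequences.

What the phantoms do *not* emulate: dentition and individual teeth, the
maxilla and other neighbouring bones, beam hardening/scatter physics,
patient pose variation within the grid, and anisotropic spacing.
Passing phantom tests therefore demonstrates that the machinery learns,
that the prior suppresses artifact-driven false positives, and that the
pipeline is internally consistent — not clinical-grade accuracy.

## Training protocol and study conditions

The optimization protocol follows the published setting: Adam,
batch size 3, up to 50 epochs, learning rate 1e−4, and early stopping
when the validation loss has not improved for 5 consecutive epochs
(best-validation weights are restored). Training batches are windows of
U consecutive slices from random cases and positions; windows with no
foreground are kept with probability 0.25 so the thin target is not
drowned out. Validation loss is computed in evaluation mode on a fixed,
seeded set of windows.

The desk-scale experiments in the test suite run deliberately reduced
conditions, chosen once: small channel schedules (encoder (8, 16, 24,
32, 48), PSFE (8, 16, 16)), slices resampled to 32–64 px in-plane, 200–
300 optimizer steps, and learning rate 1e−2 — at a few hundred steps
with batch 3 the full-scale rate cannot move a freshly initialized
network measurably, so the fixtures use a rate appropriate to their
budget. The ablation benchmark (recurrence/prior and loss variants,
3 seeds on identical splits) runs on *heavily* corrupted phantoms (10
inserts, streak amplitude 450, 10 streaks per insert): under mild
corruption every variant segments the phantom essentially perfectly and
surface-distance differences fall below the one-voxel measurement
floor, whereas the mechanisms of interest — the prior suppressing
false positives away from the mandible, the Dice term suppressing
stray-false-positive 95HD outliers — act exactly when the images are
badly degraded, which is the regime the method targets.

## Known limitations

* The correspondence stage assumes smooth, topologically identical
  surfaces; it is not an elastic registration and will mis-correspond
  strongly dissimilar anatomies.
* The parity voxelizer requires watertight meshes and rejects open ones
  rather than repairing them.
* The prior is aligned by relative axial depth only; scans whose
  anatomy sits very differently in the field of view would need a
  registration step the package intentionally omits.
* The NumPy network layer is single-threaded BLAS-bound; it is sized
  for desk-scale experiments, not full-resolution clinical training.
* `unet` and `segunet` spec variants share one implementation (the
  non-recurrent unit); SegNet- and attention-style baselines are out of
  scope.
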
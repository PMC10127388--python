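# Methods

`rapecount` estimates the number of rape (oilseed/canola) flower clusters in
nadir RGB images of field plots. Counting is cast as density-map regression:
a convolutional network maps an RGB image to a non-negative grid `D` at 1/8
of the input resolution, and the predicted count is `sum(D)`. Supervision is
point-level — one dot per cluster centroid — through a Bayesian
label-assignment loss rather than a rasterized Gaussian density target.

## The Bayesian point-supervision loss

Given annotations `z_1..z_N` (centroids, in density-grid units) and grid
cell centers `x_1..x_M`, each annotation induces an isotropic 2-D Gaussian
likelihood

    p(x_m | y_n) = N(x_m; z_n, sigma^2 I).

With equal priors over annotations, the posterior that the density at cell
`x_m` belongs to annotation `y_n` is the column-normalized likelihood
matrix. The expected count claimed by annotation `n` is
`E_n = sum_m p(y_n | x_m) D(x_m)`, and the loss penalizes its deviation from
one:

    L_Bayes = sum_n F(1 - E_n),      F(v) = |v| by default.

The background-augmented variant (Bayes+) adds a dummy label `y_0`. For
each cell, the virtual background point sits at a fixed margin `d` beyond
the cell's nearest annotation along the ray from that annotation through
the cell; the background likelihood reduces to a 1-D Gaussian in the
distance to the nearest annotation, peaked at `d` (note its `1/(sqrt(2 pi)
sigma)` normalizer — one-dimensional by construction, unlike the 2-D
per-annotation likelihoods). Density assigned to the background label is
driven to a target count of zero:

    L_Bayes+ = sum_{n>=1} F(1 - E_n) + F(0 - E_0).

Because the posterior columns sum to one, `sum_{n>=0} E_n` equals the total
density mass exactly; this conservation is asserted in the tests at 1e-9.

Numerical choices:

- All posterior arithmetic is in log space with a per-column max shift.
  `sigma = 0.1` grid cells on a 32x32 grid underflows float64 Gaussians by
  hundreds of orders of magnitude; the log-space path is exact there.
- `F` is the absolute value (the loss's source convention); it is a config
  field.
- The margin is generated as `d = background_ratio * min(tile_h, tile_w) /
  stride` (grid units), so a ratio in [0, 1] spans "no margin" to "the
  tile's shorter side"; an absolute override exists.
- An image with no annotations contributes `F(0 - sum D)`, pushing the
  network toward an empty map.
- A cell that coincides exactly with an annotation has no defined
  background direction; the annotation itself is returned (logged, not
  fatal).

## Architecture

RapeNet is six pyramidal-convolution blocks. Each block runs parallel
convolutions with distinct odd kernels (drawn from {3, 5, 7, 9}) on the same
input and concatenates the outputs along channels, followed by batch
normalization and ReLU. The number of pyramid levels rises then falls over
the six blocks — (2, 3, 4, 4, 3, 2) — and blocks 1-3 downsample by 2,
giving output stride 8. Channel widths default to (64, 128, 256, 256, 128,
64); larger kernels use grouped convolutions (target groups 1/4/8/16 for
k = 3/5/7/9, clipped to divide the channel counts), which keeps the default
capacity at 6.1 MB of float32 parameters — the published models in this
family are 4.9-5.6 MB, and the source material does not pin exact widths,
kernel sets, or group counts, so all concrete numbers here are declared
package conventions at that scale.

The regression head is a 1x1 convolution to one channel through an
absolute-value rectification. `|x|` rather than ReLU is deliberate: with a
count-targeting l1 loss, a ReLU head can be pushed into the all-negative
regime early in training, where its gradient vanishes globally and the
model permanently emits zero (observed, not hypothetical). The absolute
value keeps the output non-negative while passing a subgradient everywhere.

RapeNet+ inserts a coordinate-attention branch after blocks 2 and 4.
Features are mean-pooled along width and along height to two 1-D
descriptors, concatenated and passed through a shared 1x1 bottleneck
(reduction 8, BN + ReLU), split back, expanded per direction by 1x1
convolutions, and squashed by a sigmoid into row gates `g_h(c, i)` and
column gates `g_w(c, j)`; the output is `x * g_h * g_w`. With all branch
parameters zero both gates are exactly 0.5, so the module scales its input
by 1/4 — the tests use this as an analytic probe of the composition.

`width_multiplier` scales every channel count (minimum 4); 0.25 is the
CPU-scale profile used throughout the tests. Normalization uses per-image
batch statistics during training (batch size is 1) and stored running
statistics at evaluation, so evaluation is deterministic.

The layer substrate (grouped conv via im2col + BLAS matmul, batch norm,
activations, momentum SGD) is implemented in NumPy with hand-written
backward passes, gradient-checked against central finite differences in the
test suite.

## Inference

Plot images are standardized to a 512 (h) x 1024 (w) canvas by bilinear
resampling (with 90-degree auto-rotation if the input orientation is
portrait), then split into a non-overlapping 2x4 grid of 256x256 tiles —
eight sub-images. Each tile is predicted independently and the tile density
maps are reassembled at their origins, so the canvas count equals the sum
of tile counts exactly (disjoint sums). Annotation coordinates are rescaled
by the same per-axis factors; points pushed out of bounds by rounding are
clamped to the border so the ground-truth count N survives any resize.
Images smaller than a tile (the 128x128 desk profile) are predicted as a
single tile. Heat-map overlays upsample the density bilinearly, map it
through a matplotlib colormap, and alpha-blend with per-pixel weight
proportional to normalized density, so an empty map leaves the image
untouched.

## Evaluation metrics

Seven statistics over paired per-image manual counts `M_i` and inferred
counts `I_i`: Acc (one minus mean relative absolute error), MAE,
rMAE = sqrt(MAE), rMSE, rrMSE = 100 * rMSE / mean(M), and R². Two
conventions in this family are intentionally preserved rather than
"corrected": rMAE is the square root of MAE (not a separate mean), and the
default R² normalizes by the spread of the *inferred* counts,
`1 - sum (M_i - I_i)^2 / sum (I_i - I_bar)^2`. The textbook
manual-denominator R² is available via `r2_denominator="manual"` and is
what the synthetic recovery study reports, since it is the stricter and
more interpretable of the two. Images with `M_i = 0` are excluded from Acc
(which divides by `M_i`) and kept for all other metrics. Counts are
real-valued density sums; `round_counts` rounds them first if integer
comparison is wanted.

## Synthetic scenes

The generator emulates the counting structure of plot imagery: a textured
green canopy (smooth multiplicative noise field), `k` soft-edged yellow
elliptical blobs (radius 4-11 px at plot scale, mild eccentricity, jittered
color, Gaussian-profile edges), optional clustered placement
(`occlusion_prob`) with a minimum center distance, and additive sensor
noise. Default scene 512x1024 with counts uniform on 8-686 (the box-labeled
dataset's printed range); the desk profile is 128x128 with 5-40 blobs,
radius 3-7 px. Blobs may overlap; annotations always count placed blobs, as
dot labels do. The brightness/contrast augmentation works in HSV: value
channel scaled by `1 + b`, then contrast about the value mean by `1 + c`,
clipped; the ±10% setting mimics illumination variation across acquisition
days. Exact contrast semantics are not standardized anywhere, so the
mean-anchored scaling is the documented convention, and 8-bit color-space
round-trips are compared at ±1 level.

What the generator does not model: leaf geometry, shadows, perspective,
bloom phenology, real spectral distributions. Passing the recovery study
therefore shows that the network + loss + pipeline can learn to count
compact colored blobs on clutter from dot supervision — not field accuracy.

## Training protocol

The published recipe is kept as the `TrainConfig` default: SGD, lr 1e-5,
1000 epochs, batch size 1, 15% test split, train:val 9:1 within the
remainder, sigma in [0.1, 10] and background ratio in [0, 1] as the search
ranges. Since the chosen sigma/ratio behind the published tables are not
stated, the defaults sit mid-range (8.0 and 0.15).

The desk-scale protocol (`desk_protocol`) is the package's own calibration
for CPU-sized synthetic runs: quarter-width RapeNet, 100 epochs on 128x128
scenes, lr 3e-4 with momentum 0.9 and a cosine decay to zero, sigma 0.5
grid cells (4 input pixels — the scale of a blob), background ratio 0.3.
Two of these choices came out of failure analysis worth recording:

- With a constant lr, the l1 count loss makes background cells oscillate
  around zero and the |x| head rectifies that oscillation into a positive
  count floor proportional to lr; the cosine decay collapses the floor.
- With sigma of a full grid cell or more, a cell one unit from its
  annotation already has majority background posterior, so any spatial
  spread of predicted density inflates the count; sigma 0.5 keeps the
  assignment sharp and removes a systematic ~25% overcount.

Checkpoint selection is by lowest validation MAE, measured every few
epochs; the snapshot includes the normalization running statistics, not
just the weights (restoring weights alone against later-epoch statistics
silently corrupts predictions — also observed the hard way).

Per-sample posterior matrices depend only on annotation geometry and the
loss settings, so they are precomputed once and reused every epoch. Canvas
images train as their eight tiles (annotations assigned by centroid);
128x128 scenes train whole.

## Problem sizes used by the test suite and acceptance script

The synthetic recovery study uses 100 scenes (77 train / 8 val / 15 test
after the 85/15 and 9:1 splits), 100 epochs at quarter width — about five
minutes of single-core CPU time — and asserts held-out relative MAE <= 20%
and manual-denominator R² >= 0.7. Loss-oracle and posterior tests run on
grids up to 16x16 with up to 6 points against naive double-loop references.

The resolution-robustness check follows the inference pipeline: a held-out
scene is downsampled to 0.8x (a lower-resolution acquisition of the same
plot) and then passed through the pipeline, whose first step standardizes
the input back to the working resolution — the canvas for plot images, the
native size for desk scenes. Robustness to the acquisition factor is a
property of this standardizing pipeline (the counter never sees the reduced
grid directly), and the check asserts the median relative count deviation
against the native-resolution prediction is <= 25%; measured values are a
few percent. `predict_count_at_scale(..., standardize=False)` exposes the
harder non-pipeline variant, where the model reads the reduced grid
directly; the desk-scale model's counts there drift by ~25-30% at 0.8x,
which is the expected cost of evaluating a single-scale-trained reduced
model off its training resolution. A count-preserving multi-scale training
augmentation (`TrainConfig.scale_factors`) exists for that regime, but it
is off in the desk protocol: within a 100-epoch budget the step dilution
it causes costs more accuracy than the invariance it buys.

## Known limitations

- No GPU path; full-width 1000-epoch training at canvas scale is out of
  CPU reach. The architecture and loss are the full method; only the
  problem sizes are reduced.
- The synthetic generator's simplicity means reported synthetic metrics
  overstate field performance by construction.
- Box annotations are consumed via centroid conversion only; box geometry
  beyond the midpoint is unused.
- `sigma` and `background_ratio` interact with scene scale; the desk values
  are calibrated for stride-8 grids and blob radii of a few pixels and will
  need re-tuning for other regimes.
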
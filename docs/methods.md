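# Methods

## Polar contour representation

An instance mask is encoded as a center plus `n_rays` distances to the
boundary at uniform angular steps. Conventions, fixed throughout:

- x = column, y = row, 0-based, pixel centers at integer coordinates.
  Because screen y grows downward, increasing angle is clockwise on screen.
- Ray `a` (1-based) points at `theta_a = (a-1) * 2*pi / n_rays` from the +x
  axis. `n_rays` defaults to 36 (one ray per 10 degrees), configurable.
- The canonical center is the instance centroid (mean foreground
  coordinate). Any center inside the image is legal; rays are then measured
  from that point.
- A ray's length is the distance to the **farthest** sampled position whose
  nearest pixel is foreground. Scanning uses 0.25-px steps out to the image
  diagonal: sub-pixel steps reduce staircase error at negligible cost, and
  the farthest-hit rule means concavities or holes along a ray do not
  truncate it (for star-convex shapes about the center the rule coincides
  with the boundary distance). The scan resolution bounds the encoder error
  by one step per ray, which the tests verify against an independent
  exhaustive scan.
- Decoding maps ray `a` to the vertex `(cos(theta_a)*l_a + x_cen,
  sin(theta_a)*l_a + y_cen)`; vertices are connected in ray order and
  rasterized with an even-odd fill (boundary pixels included as resolved by
  the scan-line rasterizer). A zero-area polygon rasterizes to an empty
  mask with a warning.

**Polar center-ness** is `min(rays) / max(rays)`, defined as 0 when all
rays are zero. For a disc of radius R encoded about a center offset by d it
equals `(R-d)/(R+d)` — the law the acceptance tests check — so it penalizes
off-center encodings smoothly.

With 36 rays, convex shapes of radius >= 20 px reconstruct to pixel IoU
>= 0.95. Reconstruction quality saturates in the ray count: the measured
mean IoU over random convex shapes rises sharply from 9 to 18 to 36 rays
and only marginally from 36 to 72, which is why 36 is the default.

## Losses

- **Polar IoU (discrete)**: `sum min(l, l*)^2 / sum max(l, l*)^2` with
  uniform angular weights (rays are evenly spaced, so the `Delta theta`
  factors cancel). Symmetric, in (0, 1], scale-invariant; cross-checked in
  tests against the pixel IoU of the rasterized decoded contours (within
  0.05 for convex ray vectors sharing a center).
- **Polar IoU loss**: `log(sum max / sum min)` — the negative log of the
  polar IoU with the squares dropped. Its gradient w.r.t. a predicted ray
  is `+1/sum_max` where the prediction exceeds the target, `-1/sum_min`
  where it falls short (at a tie, the sum of both, since both sums then
  move together). This sign-like gradient is bounded and scale-free; plain
  gradient descent with a fixed step recovers a random 36-ray target to
  < 0.5 px. Rays must be positive: zero-length encoder output is clamped to
  1e-6 before entering the loss.
- **Focal classification loss** with alpha = 0.25, gamma = 2 (the standard
  recommendation; the values are exposed in `LossConfig`), summed over all
  locations of all pyramid levels and divided by the number of positive
  samples (at least 1).
- **Center-ness loss**: binary cross-entropy at positive locations against
  the min/max ratio of the location's target rays, scaled by a balance
  coefficient (default 1.0, configurable). Note that BCE against a soft
  target t has an irreducible floor H(t) > 0, so this term converges to its
  entropy floor rather than to zero.
- **Total**: unit-weighted sum of the three terms (the balance coefficient
  folded into the center-ness term).

## Network

Built on a small in-repo reverse-mode autodiff engine over numpy (float64,
CPU-only, finite-difference-tested). This keeps the model fully
deterministic and dependency-light; it is not fast, which is why the
training experiments are deliberately toy-scale.

- **Backbone**: stride-2 stem, then three stages of [1×1 transition to
  4k channels + 2×2 average pool, dense block]. Each dense-block layer is a
  3×3 convolution receiving the concatenation of all previous layer
  outputs in its block (so a block with L layers and growth k widens its
  input by L·k channels). Outputs C1/C2/C3 at strides 4/8/16. Convolutions
  are paired with GroupNorm (8 groups): the dense-connectivity design this
  follows is normalized throughout, and without normalization the
  from-scratch reduced model trains far slower.
- **Feature pyramid**: 1×1 laterals fused top-down with 2× nearest
  upsampling give P1..P3; P4 and P5 are two further 2×2 downsamplings of
  P3. Uniform width (default 32; 24 in the toy configuration).
- **Criss-cross attention**, applied once per pyramid level (single
  recurrence): each position attends over its own row and column — H+W-1
  positions, the self position masked out of the row branch so it is
  counted once — with softmax weights from query/key projections
  (channels/8), and the value aggregate is added residually. Zeroing the
  value projection makes it the identity, a tested contract.
- **Head**, shared across levels: a 3×3 conv trunk, then 1×1 heads for
  classification (sigmoid, bias initialized to -2 for a low foreground
  prior), center-ness (sigmoid), and rays (`exp(raw) * stride`, so lengths
  are positive and level-scaled).
- **Region proposals** (optional, off by default): a 3×3 + two 1×1 conv
  head emits 2·9 objectness and 4·9 regression channels per cell over 9
  anchors (areas 16², 64², 128²; ratios 1:1, 1:2, 2:1; a ratio-r anchor of
  area s² has width s·sqrt(r)). Proposals are delta-decoded anchors ranked
  by foreground softmax score. The dense head does not depend on them; they
  exist as an ROI-restriction stage for cluttered scenes.

### Target assignment

Each instance goes to the pyramid level whose scale range contains its
maximum ray from the centroid; ranges are stride-proportional with
boundaries at 4× each stride (0–16, 16–32, 32–64, 64–128, 128–inf for
strides 4..64). Within the level, cells whose centers lie within 1.5
strides of the centroid are positive (the nearest cell always is; the
positive-region extent is a free parameter of the method and configurable).
Ray targets are re-extracted about each positive cell's own position, and
its center-ness target is their min/max ratio. When two instances claim a
cell, the one with the smaller maximum ray wins.

### Optimization

SGD with momentum 0.9 and weight decay 1e-4; default learning rate 0.0025
(the transfer-learning setting this family of models trains with at full
scale; 24 epochs, checkpoints each epoch). Runs are bitwise deterministic
given the seed. Divergence (non-finite loss) aborts with the offending
term values.

The **toy configuration** used by the tests and the acceptance script — 64
synthetic 128×128 scenes, 200 steps, batch 4, growth 8, 2 layers/block,
pyramid width 24 — trains from scratch, for which the transfer-learning
rate is too conservative: it uses lr 0.04 with a 20-step linear warmup.
Under these settings the mean total loss of the last 10 steps falls below
half that of the first 10, and all three terms decrease (the center-ness
term only modestly, due to its entropy floor). Images fed to the network
must be multiples of 64 on each side; the CLI pads bottom/right (edge
values for images, background for masks), which leaves pixel coordinates
unchanged.

## Synthetic scenes

The generator emulates the structure of orchard imagery of green fruit:
quasi-elliptical instances (radius 18–55 px at the default 400×600
working size, axis ratio up to 1.4), pairwise overlap (probability 0.6),
branch-like occluding stripes (probability 0.5 per instance, width 6–14 px)
that subtract from the *visible* masks used as training targets (the full
pre-occlusion masks are retained for diagnostics), fruit and background
greens drawn within 15/255 per channel of each other over a smooth texture
field, a global brightness factor in [0.4, 1.2] emulating backlit and
night shots, and Gaussian sensor noise. Everything is deterministic in the
seed, and annotations are written as COCO RLE.

What it does **not** emulate: leaf geometry, specular highlights,
raindrops, motion blur, perspective-varying fruit density. Passing tests
therefore demonstrate the correctness of the encoding, losses, training
machinery and evaluation — not field accuracy on real orchard photographs.

## Evaluation

COCO-protocol greedy matching per category and IoU threshold (prediction
order by confidence; ties at threshold accepted; ignored ground truth —
outside the area bucket — absorbs matches without counting, and unmatched
predictions outside the bucket are not false positives). AP is 101-point
interpolated; mAP averages thresholds 0.50:0.05:0.95; area buckets are the
standard 32²/96² boundaries. A category/bucket with no ground truth
reports NaN (printed as absent), never 0. On the constructed
one-true-positive/one-false-positive case the 101-point AP@0.5 is 51/101 =
0.50495…, i.e. 0.50 at printed precision — the tests pin the exact
hand-enumerated value. Mean per-image inference time is reported alongside
and labeled hardware-dependent.

## Known limitations

- Star-convex representation: 36 rays cannot represent boundaries that a
  ray from the center crosses more than once (the farthest-hit rule then
  overestimates); disconnected visible regions of one occluded instance are
  encoded as one star shape.
- The autodiff engine is clarity-first numpy; training beyond toy scale is
  impractical, and no pretrained weights are provided or loadable.
- The center-ness BCE has a soft-target entropy floor, so its loss value is
  not comparable to zero-floor terms when reading training curves.
- RLE here is the uncompressed COCO variant; compressed (LEB128) RLE
  strings are not parsed.
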
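# polarseg

Anchor-free instance segmentation of **homo-chromatic fruit** — green fruit
on green foliage — via **polar contour regression**, with a synthetic
orchard-scene generator so the whole pipeline is testable without any image
downloads.

Detecting unripe fruit for yield estimation and robotic picking is hard
precisely because the target matches its background: color cues fail,
instances overlap, and branches occlude them. Instead of predicting a
free-form mask, this package reduces instance segmentation to a dense
regression problem: each instance boundary is described by its center
$(x_{cen}, y_{cen})$ and $n = 36$ ray lengths $\{l_1, \dots, l_n\}$ sampled
every $10^\circ$ (clockwise on screen, polar axis along $+x$). A
fully-convolutional head predicts, at every location of a feature pyramid,

- a classification score $cl_{x,y}$,
- a **polar center-ness** $\min_a l_a / \max_a l_a \in [0, 1]$, which
  down-weights off-center predictions, and
- the 36 ray lengths, decoded to a polygon via
  $x_a = \cos\theta_a \, l_a + x_{cen}$, $y_a = \sin\theta_a \, l_a + y_{cen}$.

The rays are trained *as a whole* with the **polar IoU loss**. For ray
vectors $l, l^*$ the discrete polar IoU is
$\sum_a \min(l_a, l_a^*)^2 / \sum_a \max(l_a, l_a^*)^2$, and the regression
loss is its simplified negative logarithm

$$L_{mask} = \log \frac{\sum_a \max(l_a, l_a^*)}{\sum_a \min(l_a, l_a^*)},$$

which is non-negative, zero only at a perfect match, scale-invariant, and
differentiable. The total objective is $L = L_{cls} + L_{cen} + L_{mask}$
(focal loss, binary cross-entropy, polar IoU), normalized by the number of
positive samples.

The trainable model is a densely-connected backbone (three dense blocks of
3×3 convolutions, 1×1 transitions with $4k$ channels for growth rate $k$),
a feature pyramid $P_1..P_5$ with criss-cross attention applied per level,
and an optional region-proposal stage (9 anchors per cell: areas
$\{16^2, 64^2, 128^2\}$ × ratios $\{1{:}1, 1{:}2, 2{:}1\}$), all running on
a small in-repo numpy autodiff engine — CPU-only and deterministic.
Final instances come from confidence = classification × center-ness,
a 0.05 score threshold, top-1000 per level, and mask NMS at IoU 0.5.
Evaluation is COCO-protocol mask/box mAP (10 IoU thresholds 0.50–0.95,
101-point interpolation, small/medium/large area buckets).

## Worked example

```python
import numpy as np
from polarseg import *

mask, exact = make_analytic_shape("ellipse", {"center": (80, 70), "semi_axes": (32, 22)}, (160, 160))
center = compute_centroid(mask)
contour = extract_rays(mask, center, n_rays=36)
print(f"center          : ({center[0]:.2f}, {center[1]:.2f})")
print(f"first 6 rays    : {np.round(contour.ray_lengths[:6], 2)}")
print(f"center-ness     : {polar_centerness(contour):.3f}  (b/a = {22/32:.3f})")
rec = rasterize_polygon(decode_contour(contour), 160, 160)
print(f"round-trip IoU  : {mask_iou(mask, rec):.3f}")
```

prints

```
center          : (80.00, 70.00)
first 6 rays    : [32.5  31.5  30.25 28.25 26.75 25.25]
center-ness     : 0.669  (b/a = 0.688)
round-trip IoU  : 0.995
```

The rays start at the semi-major axis (32) and shrink toward the minor
axis; the center-ness of an ellipse encoded at its center is close to its
axis ratio $b/a$; re-rasterizing the decoded 36-gon recovers 99.5 % of the
mask (IoU).

## Command line

```bash
polarseg generate --n 100 --seed 7 --out data/        # synthetic COCO dataset
polarseg encode   --coco data/annotations.json --n-rays 36 --out polar.json
polarseg train    --data data/ --out run/ --seed 0
polarseg predict  --ckpt run/ckpt_final.npz --images data/images \
                  --score-thr 0.05 --nms-thr 0.5 --out pred.json
polarseg evaluate --pred pred.json --gt data/annotations.json
polarseg config   --dump
```

The scene generator emulates the orchard conditions the method targets:
quasi-elliptical fruit in near-background greens (channel means within
15/255), frequent overlap, branch-like occluding stripes, brightness
scaling for backlit/night shots, and sensor noise — with exact per-instance
masks and COCO annotations.

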
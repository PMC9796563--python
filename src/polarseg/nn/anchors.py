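"""Region-proposal machinery: anchor grids, the RPN head, proposal decoding.

Nine anchors per grid cell -- area scales 16x16, 64x64, 128x128 crossed
with aspect ratios 1:1, 1:2, 2:1 -- are scored by a small convolutional
head emitting 2 objectness scores and 4 box deltas per anchor (18- and
36-channel maps).  Proposals are the delta-decoded anchors ranked by
foreground score.  In this package the proposal stage is an optional
region-of-interest restriction for the dense head, disabled by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .layers import Conv2d, Module

__all__ = ["AnchorSet", "generate_anchors", "RPNHead", "rpn_propose"]

ANCHOR_SCALES = (16.0, 64.0, 128.0)  # side of the square-area anchor
ANCHOR_RATIOS = (1.0, 0.5, 2.0)  # width : height


@dataclass(frozen=True)
class AnchorSet:
    """Anchor boxes (grid_h, grid_w, 9, 4) as (cx, cy, w, h) in image pixels."""

    boxes: np.ndarray
    stride: int

    @property
    def n_per_cell(self) -> int:
        return self.boxes.shape[2]


def generate_anchors(
    grid_h: int,
    grid_w: int,
    stride: int,
    scales=ANCHOR_SCALES,
    ratios=ANCHOR_RATIOS,
) -> AnchorSet:
    """The 9 = |scales| x |ratios| anchors centered on every grid cell.

    A ratio-r anchor of area ``s^2`` has width ``s*sqrt(r)`` and height
    ``s/sqrt(r)``, preserving the area.
    """
    if grid_h < 1 or grid_w < 1 or stride < 1:
        raise ValueError("grid dimensions and stride must be positive")
    shapes = np.array(
        [(s * np.sqrt(r), s / np.sqrt(r)) for s in scales for r in ratios]
    )  # (9, 2)
    cx = (np.arange(grid_w) + 0.5) * stride
    cy = (np.arange(grid_h) + 0.5) * stride
    boxes = np.zeros((grid_h, grid_w, len(shapes), 4))
    boxes[..., 0] = cx[None, :, None]
    boxes[..., 1] = cy[:, None, None]
    boxes[..., 2] = shapes[None, None, :, 0]
    boxes[..., 3] = shapes[None, None, :, 1]
    return AnchorSet(boxes, stride)


class RPNHead(Module):
    """3x3 conv trunk + two 1x1 convs: 2*9 objectness and 4*9 regression maps."""

    def __init__(self, in_channels: int, rng, n_anchors: int = 9):
        self.trunk = Conv2d(in_channels, in_channels, 3, rng)
        self.obj = Conv2d(in_channels, 2 * n_anchors, 1, rng, padding=0)
        self.reg = Conv2d(in_channels, 4 * n_anchors, 1, rng, padding=0)
        self.n_anchors = n_anchors

    def __call__(self, feat: Tensor) -> tuple[Tensor, Tensor]:
        t = self.trunk(feat).relu()
        return self.obj(t), self.reg(t)


def rpn_propose(
    objectness: np.ndarray,
    regression: np.ndarray,
    anchors: AnchorSet,
    top_k: int = 1000,
) -> np.ndarray:
    """Decode and rank proposals; returns (m, 5) rows (cx, cy, w, h, score).

    ``objectness``: (2*A, H, W) background/foreground logit pairs;
    ``regression``: (4*A, H, W) deltas (dx, dy, dw, dh) in the standard
    parameterization ``cx' = cx + dx*w``, ``w' = w*exp(dw)``.  Zero
    regression output leaves the anchors unchanged.
    """
    a = anchors.n_per_cell
    h, w = anchors.boxes.shape[:2]
    if objectness.shape != (2 * a, h, w):
        raise ValueError(f"objectness must be ({2 * a}, {h}, {w}), got {objectness.shape}")
    if regression.shape != (4 * a, h, w):
        raise ValueError(f"regression must be ({4 * a}, {h}, {w}), got {regression.shape}")
    logits = objectness.reshape(a, 2, h, w)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    fg = (e[:, 1] / e.sum(axis=1))  # (A, H, W)
    deltas = regression.reshape(a, 4, h, w).transpose(2, 3, 0, 1)  # (H, W, A, 4)
    boxes = anchors.boxes.copy()
    boxes[..., 0] += deltas[..., 0] * boxes[..., 2]
    boxes[..., 1] += deltas[..., 1] * boxes[..., 3]
    boxes[..., 2] *= np.exp(deltas[..., 2])
    boxes[..., 3] *= np.exp(deltas[..., 3])
    flat_boxes = boxes.reshape(-1, 4)
    flat_scores = fg.transpose(1, 2, 0).reshape(-1)
    order = np.argsort(-flat_scores, kind="stable")[:top_k]
    return np.concatenate([flat_boxes[order], flat_scores[order, None]], axis=1)
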
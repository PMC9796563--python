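"""The full segmentation model: backbone + pyramid + attention + dense head.

The head is anchor-free and shared across pyramid levels: at every grid
location of every level it predicts a per-category classification score, a
center-ness score, and ``n_rays`` ray lengths describing the instance
contour in polar coordinates about that location.  Ray outputs pass through
``exp`` and are scaled by the level stride so they are positive and
roughly scale-matched to the level.  An optional region-proposal head
(see :mod:`polarseg.nn.anchors`) can restrict where the dense head is
sampled; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .layers import (
    FPN,
    BackboneConfig,
    Conv2d,
    ConvNorm,
    CrissCrossAttention,
    DenseBackbone,
    Module,
)

__all__ = ["ModelConfig", "DensePrediction", "PolarNet"]


@dataclass
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    fpn_width: int = 32
    n_classes: int = 1
    n_rays: int = 36
    head_convs: int = 1
    use_cca: bool = True
    use_rpn: bool = False
    cls_bias_init: float = -2.0  # start with a low foreground prior
    seed: int = 0


@dataclass
class DensePrediction:
    """Per-location head outputs at one pyramid level (numpy, single image)."""

    cls_prob: np.ndarray  # (n_classes, H, W), in (0,1)
    centerness: np.ndarray  # (H, W), in (0,1)
    ray_lengths: np.ndarray  # (n_rays, H, W), positive
    stride: int


class PolarNet(Module):
    """Dense polar-contour prediction network."""

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.backbone = DenseBackbone(config.backbone, rng)
        self.fpn = FPN(self.backbone.out_channels, config.fpn_width, rng)
        self.cca = CrissCrossAttention(config.fpn_width, rng) if config.use_cca else None
        w = config.fpn_width
        self.trunk = [ConvNorm(w, w, 3, rng) for _ in range(config.head_convs)]
        self.cls_head = Conv2d(w, config.n_classes, 1, rng, padding=0,
                               bias_init=config.cls_bias_init)
        self.cen_head = Conv2d(w, 1, 1, rng, padding=0)
        self.ray_head = Conv2d(w, config.n_rays, 1, rng, padding=0)
        if config.use_rpn:
            from .anchors import RPNHead

            self.rpn = RPNHead(w, rng)
        else:
            self.rpn = None
        self.strides = self.fpn.strides

    def forward(self, images: np.ndarray) -> list[dict]:
        """Raw head outputs per level for a batch.

        ``images``: (N, 3, H, W) float array, H and W divisible by 64.
        Returns one dict per pyramid level with Tensors ``cls_logits``
        (N, n_classes, h, w), ``cen_logits`` (N, 1, h, w), ``ray_lengths``
        (N, n_rays, h, w) and the integer ``stride``.
        """
        x = Tensor(np.asarray(images, dtype=np.float64))
        levels = self.fpn(self.backbone(x))
        outputs = []
        for feat, stride in zip(levels, self.strides):
            if self.cca is not None:
                feat = self.cca(feat)
            t = feat
            for conv in self.trunk:
                t = conv(t).relu()
            rays = self.ray_head(t).exp() * float(stride)
            outputs.append(
                {
                    "cls_logits": self.cls_head(t),
                    "cen_logits": self.cen_head(t),
                    "ray_lengths": rays,
                    "stride": stride,
                    "feature": feat,
                }
            )
        return outputs

    def predict_image(self, image: np.ndarray) -> list[DensePrediction]:
        """Dense predictions for one (H, W, 3) image, as numpy arrays."""
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) image")
        arr = pad_to_multiple(arr)
        batch = normalize_image(arr)[None].transpose(0, 3, 1, 2)
        outs = self.forward(batch)
        preds = []
        for o in outs:
            cls = _sigmoid(o["cls_logits"].data[0])
            cen = _sigmoid(o["cen_logits"].data[0, 0])
            preds.append(
                DensePrediction(
                    cls_prob=cls,
                    centerness=cen,
                    ray_lengths=o["ray_lengths"].data[0],
                    stride=o["stride"],
                )
            )
        return preds


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def pad_to_multiple(image: np.ndarray, multiple: int = 64, mode: str = "edge") -> np.ndarray:
    """Pad an (H, W, ...) array at the bottom/right to a size multiple.

    Padding on those sides keeps pixel coordinates unchanged, so targets and
    decoded contours computed on the padded frame are valid in the original.
    Use ``mode="constant"`` for masks (padding stays background).
    """
    h, w = image.shape[:2]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return image
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode=mode)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Scale to [0,1] and center; the model's fixed input normalization."""
    return image / 255.0 - 0.5
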
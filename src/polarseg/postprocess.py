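"""From dense predictions to final instances: score, threshold, top-k, NMS.

The confidence of a location is its classification probability multiplied
by its center-ness, so off-center (low min/max ray ratio) predictions are
down-weighted before suppression.  Candidates below the confidence
threshold (default 0.05) are dropped per pyramid level, the top 1000 per
level are kept, levels are merged, and greedy non-maximum suppression at
mask IoU 0.5 produces the final instance set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import PolarContour, decode_contour, mask_iou, rasterize_polygon

__all__ = [
    "InstanceCandidate",
    "score_candidates",
    "filter_candidates",
    "mask_nms",
    "predict_instances",
]


@dataclass
class InstanceCandidate:
    confidence: float
    category: int
    contour: PolarContour
    level: int

    def sort_key(self) -> tuple:
        """Descending confidence; ties broken by ray sum then center (x, y)."""
        return (
            -self.confidence,
            -float(self.contour.ray_lengths.sum()),
            self.contour.center,
        )


def score_candidates(pred, level: int = 0, min_cls: float = 0.0) -> list[InstanceCandidate]:
    """Candidates from one level's dense prediction.

    ``pred`` is a :class:`polarseg.nn.model.DensePrediction`; every grid
    location yields one candidate per category with confidence
    ``cls_prob * centerness`` and a contour decoded about the location's
    image-plane position.  ``min_cls`` lets callers pre-drop near-zero
    classification scores cheaply.
    """
    n_classes, gh, gw = pred.cls_prob.shape
    s = pred.stride
    out = []
    conf_all = pred.cls_prob * pred.centerness[None]
    for c in range(n_classes):
        keep = pred.cls_prob[c] >= min_cls
        for i, j in zip(*np.nonzero(keep)):
            cx = j * s + s / 2.0
            cy = i * s + s / 2.0
            contour = PolarContour((cx, cy), pred.ray_lengths[:, i, j].copy())
            out.append(
                InstanceCandidate(
                    confidence=float(conf_all[c, i, j]),
                    category=c + 1,
                    contour=contour,
                    level=level,
                )
            )
    return out


def filter_candidates(
    candidates: list[InstanceCandidate],
    score_thr: float = 0.05,
    top_k: int = 1000,
) -> list[InstanceCandidate]:
    """Per-level confidence threshold + top-k, then merge levels."""
    by_level: dict[int, list[InstanceCandidate]] = {}
    for c in candidates:
        if c.confidence >= score_thr:
            by_level.setdefault(c.level, []).append(c)
    merged: list[InstanceCandidate] = []
    for level in sorted(by_level):
        cands = sorted(by_level[level], key=InstanceCandidate.sort_key)
        merged.extend(cands[:top_k])
    return sorted(merged, key=InstanceCandidate.sort_key)


def mask_nms(
    candidates: list[InstanceCandidate],
    iou_thr: float = 0.5,
    image_size: tuple[int, int] | None = None,
) -> list[tuple[InstanceCandidate, np.ndarray]]:
    """Greedy suppression on rasterized decoded contours.

    Returns the surviving candidates in descending confidence, each with
    its rasterized mask.  ``image_size`` (height, width) defaults to the
    tight bound over all decoded contours.
    """
    if not 0.0 < iou_thr < 1.0:
        raise ValueError("iou_thr must lie in (0, 1)")
    if not candidates:
        return []
    polys = [decode_contour(c.contour).vertices for c in candidates]
    if image_size is None:
        hi = np.max([p.max(axis=0) for p in polys], axis=0)
        image_size = (int(np.ceil(hi[1])) + 2, int(np.ceil(hi[0])) + 2)
    h, w = image_size
    order = sorted(range(len(candidates)), key=lambda i: candidates[i].sort_key())
    masks = {i: rasterize_polygon(polys[i], h, w) for i in order}
    survivors: list[int] = []
    for i in order:
        if any(
            candidates[j].category == candidates[i].category
            and mask_iou(masks[j], masks[i]) >= iou_thr
            for j in survivors
        ):
            continue
        survivors.append(i)
    return [(candidates[i], masks[i]) for i in survivors]


def predict_instances(
    model,
    image: np.ndarray,
    score_thr: float = 0.05,
    top_k: int = 1000,
    nms_thr: float = 0.5,
    min_cls: float = 0.02,
) -> list[tuple[InstanceCandidate, np.ndarray]]:
    """Full inference pipeline for one image: dense head -> score -> NMS."""
    preds = model.predict_image(image)
    candidates: list[InstanceCandidate] = []
    for level, p in enumerate(preds):
        candidates.extend(score_candidates(p, level=level, min_cls=min_cls))
    kept = filter_candidates(candidates, score_thr=score_thr, top_k=top_k)
    return mask_nms(kept, iou_thr=nms_thr, image_size=image.shape[:2])
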
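"""COCO-protocol mask/box average precision.

Matching follows the standard COCO evaluation: per category and IoU
threshold, predictions are taken in descending confidence and greedily
matched to the unmatched ground-truth instance of highest IoU at or above
the threshold.  AP is the 101-point interpolated area under the
precision-recall curve; mAP averages AP over the ten thresholds
0.50, 0.55, ..., 0.95.  Size-stratified mAP uses the standard area buckets
[0, 32^2), [32^2, 96^2), [96^2, inf): ground truth outside the bucket is
ignored, predictions matched to ignored ground truth are dropped, and
unmatched predictions outside the bucket do not count as false positives.

AP is undefined (reported as NaN, printed as absent) for a category/bucket
with no ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coco import annotation_to_mask
from .contours import mask_iou

__all__ = ["EvalReport", "evaluate_masks", "evaluate_boxes", "IOU_THRESHOLDS", "AREA_RANGES"]

IOU_THRESHOLDS = np.round(np.arange(0.5, 1.0, 0.05), 2)  # 10 thresholds
RECALL_POINTS = np.linspace(0.0, 1.0, 101)
AREA_RANGES = {
    "all": (0.0, float("inf")),
    "small": (0.0, 32.0**2),
    "medium": (32.0**2, 96.0**2),
    "large": (96.0**2, float("inf")),
}


@dataclass
class EvalReport:
    """COCO-style metric table for one prediction set."""

    ap_per_threshold: dict[float, float]  # over area 'all'
    map: float  # mean over the 10 thresholds
    ap50: float
    ap75: float
    map_small: float
    map_medium: float
    map_large: float
    mean_time_per_image: float | None = None
    iou_type: str = "segm"
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        tag = {"segm": "mask", "bbox": "box"}[self.iou_type]

        def fmt(v: float) -> str:
            return "   --" if np.isnan(v) else f"{100 * v:5.1f}"

        lines = [
            f"[{tag}] mAP   = {fmt(self.map)}%",
            f"[{tag}] AP50  = {fmt(self.ap50)}%",
            f"[{tag}] AP75  = {fmt(self.ap75)}%",
            f"[{tag}] mAP_s = {fmt(self.map_small)}%",
            f"[{tag}] mAP_m = {fmt(self.map_medium)}%",
            f"[{tag}] mAP_l = {fmt(self.map_large)}%",
        ]
        if self.mean_time_per_image is not None:
            lines.append(f"[{tag}] mean time per image = {self.mean_time_per_image:.3f} s")
        return "\n".join(lines)


def _box_iou(a: np.ndarray, b: np.ndarray) -> float:
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix0, iy0 = max(ax0, bx0), max(ay0, by0)
    ix1, iy1 = min(ax0 + aw, bx0 + bw), min(ay0 + ah, by0 + bh)
    iw, ih = max(0.0, ix1 - ix0), max(0.0, iy1 - iy0)
    inter = iw * ih
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def _instance_ious(preds, gts, image_info, iou_type):
    """IoU matrix (n_pred, n_gt) for one image+category."""
    n_p, n_g = len(preds), len(gts)
    ious = np.zeros((n_p, n_g))
    if iou_type == "segm":
        h, w = image_info["height"], image_info["width"]
        pmasks = [annotation_to_mask(p, h, w) for p in preds]
        gmasks = [annotation_to_mask(g, h, w) for g in gts]
        for i, pm in enumerate(pmasks):
            for j, gm in enumerate(gmasks):
                ious[i, j] = mask_iou(pm, gm)
    else:
        for i, p in enumerate(preds):
            for j, g in enumerate(gts):
                ious[i, j] = _box_iou(np.asarray(p["bbox"]), np.asarray(g["bbox"]))
    return ious


def _match_category(pred_by_img, gt_by_img, img_info, iou_type, thr, area_range):
    """Greedy COCO matching; returns (scores, tp_flags, ignore_flags, n_gt)."""
    lo, hi = area_range
    scores, tps, ignores = [], [], []
    n_gt = 0
    for image_id, gts in gt_by_img.items():
        preds = sorted(pred_by_img.get(image_id, []), key=lambda p: -p["score"])
        gt_ignore = [not (lo <= g["area"] < hi) for g in gts]
        n_gt += sum(1 for ig in gt_ignore if not ig)
        if not preds:
            continue
        ious = _instance_ious(preds, gts, img_info[image_id], iou_type)
        matched = [False] * len(gts)
        order = sorted(range(len(gts)), key=lambda j: gt_ignore[j])  # real GT first
        for i, p in enumerate(preds):
            best_j, best_iou = -1, thr
            for j in order:
                if matched[j]:
                    continue
                # once a real match exists, never trade it for an ignored one
                if best_j >= 0 and not gt_ignore[best_j] and gt_ignore[j]:
                    break
                if ious[i, j] < best_iou:
                    continue
                best_j, best_iou = j, ious[i, j]
            scores.append(p["score"])
            if best_j >= 0:
                matched[best_j] = True
                tps.append(not gt_ignore[best_j])
                ignores.append(gt_ignore[best_j])
            else:
                p_area = p.get("area")
                if p_area is None:
                    p_area = float(p["bbox"][2] * p["bbox"][3]) if "bbox" in p else 0.0
                out_of_range = not (lo <= p_area < hi)
                tps.append(False)
                ignores.append(out_of_range)
    # predictions on images with no GT of this category are false positives
    for image_id, preds in pred_by_img.items():
        if image_id in gt_by_img:
            continue
        for p in preds:
            p_area = p.get("area", 0.0) or 0.0
            scores.append(p["score"])
            tps.append(False)
            ignores.append(not (lo <= p_area < hi))
    return np.asarray(scores), np.asarray(tps, bool), np.asarray(ignores, bool), n_gt


def _average_precision(scores, tps, ignores, n_gt) -> float:
    if n_gt == 0:
        return float("nan")
    keep = ~ignores
    scores, tps = scores[keep], tps[keep]
    if scores.size == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tps = tps[order]
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(~tps)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # monotone envelope from the right, then 101-point interpolation
    for i in range(precision.size - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    interp = np.zeros_like(RECALL_POINTS)
    idx = np.searchsorted(recall, RECALL_POINTS, side="left")
    valid = idx < precision.size
    interp[valid] = precision[idx[valid]]
    return float(interp.mean())


def _evaluate(predictions, gt, iou_type) -> EvalReport:
    img_info = {im["id"]: im for im in gt["images"]}
    cat_ids = sorted({c["id"] for c in gt["categories"]})

    def group(records):
        by_cat: dict[int, dict[int, list]] = {}
        for r in records:
            by_cat.setdefault(r["category_id"], {}).setdefault(r["image_id"], []).append(r)
        return by_cat

    gt_by_cat = group(a for a in gt["annotations"] if not a.get("iscrowd", 0))
    pred_by_cat = group(predictions)

    for p in predictions:
        if "area" not in p and isinstance(p.get("segmentation"), (list, dict)):
            info = img_info[p["image_id"]]
            p["area"] = float(
                annotation_to_mask(p, info["height"], info["width"]).sum()
            )

    ap = {}  # (thr, range_name) -> list of per-category APs
    for thr in IOU_THRESHOLDS:
        for rname, rng in AREA_RANGES.items():
            vals = []
            for cid in cat_ids:
                if cid not in gt_by_cat:
                    continue
                s, t, ig, n = _match_category(
                    pred_by_cat.get(cid, {}), gt_by_cat[cid], img_info, iou_type, thr, rng
                )
                vals.append(_average_precision(s, t, ig, n))
            arr = np.asarray(vals, float)
            ap[(float(thr), rname)] = (
                float(np.nanmean(arr)) if arr.size and not np.all(np.isnan(arr)) else float("nan")
            )

    per_thr = {t: ap[(float(t), "all")] for t in IOU_THRESHOLDS}

    def mean_over_thr(rname):
        vals = np.asarray([ap[(float(t), rname)] for t in IOU_THRESHOLDS])
        return float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")

    return EvalReport(
        ap_per_threshold={float(k): v for k, v in per_thr.items()},
        map=mean_over_thr("all"),
        ap50=per_thr[0.5],
        ap75=per_thr[0.75],
        map_small=mean_over_thr("small"),
        map_medium=mean_over_thr("medium"),
        map_large=mean_over_thr("large"),
        iou_type=iou_type,
    )


def evaluate_masks(predictions: list[dict], gt: dict) -> EvalReport:
    """Mask AP of COCO-results-format predictions against a COCO dataset.

    ``predictions``: list of ``{image_id, category_id, segmentation, score}``
    records (polygon list or uncompressed RLE segmentations).
    """
    return _evaluate(predictions, gt, "segm")


def evaluate_boxes(predictions: list[dict], gt: dict) -> EvalReport:
    """Box AP of ``{image_id, category_id, bbox, score}`` records (xywh)."""
    return _evaluate(predictions, gt, "bbox")
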
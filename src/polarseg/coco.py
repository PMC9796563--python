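"""COCO-format reading/writing, mask <-> polygon/RLE conversion, LabelMe import.

Datasets are carried as the plain COCO dictionary (``images`` /
``annotations`` / ``categories``), the field's lingua franca.  Coordinates
are 0-based, (x, y) order, polygons flat ``[x1, y1, x2, y2, ...]`` lists;
RLE is the uncompressed COCO run-length form (column-major, first run
counts background pixels).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from skimage.measure import find_contours

from .contours import rasterize_polygon

__all__ = [
    "read_coco",
    "write_coco",
    "validate_coco",
    "CocoValidationError",
    "mask_to_rle",
    "rle_to_mask",
    "polygon_to_mask",
    "mask_to_polygons",
    "annotation_to_mask",
    "labelme_to_coco",
]


class CocoValidationError(ValueError):
    """Raised with an itemized list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("COCO validation failed:\n" + "\n".join(f"- {e}" for e in errors))


def validate_coco(ds: dict) -> list[str]:
    """Return a list of referential-integrity / schema problems (empty if valid)."""
    errors: list[str] = []
    for key in ("images", "annotations", "categories"):
        if key not in ds:
            errors.append(f"missing top-level key {key!r}")
    if errors:
        return errors
    image_ids = {im["id"] for im in ds["images"]}
    if len(image_ids) != len(ds["images"]):
        errors.append("duplicate image ids")
    cat_ids = {c["id"] for c in ds["categories"]}
    ann_ids = set()
    for ann in ds["annotations"]:
        if ann["id"] in ann_ids:
            errors.append(f"duplicate annotation id {ann['id']}")
        ann_ids.add(ann["id"])
        if ann["image_id"] not in image_ids:
            errors.append(f"annotation {ann['id']} references missing image_id {ann['image_id']}")
        if ann["category_id"] not in cat_ids:
            errors.append(
                f"annotation {ann['id']} references missing category_id {ann['category_id']}"
            )
        if ann.get("area", 1) <= 0:
            errors.append(f"annotation {ann['id']} has non-positive area")
    return errors


def read_coco(path: str | Path) -> dict:
    with open(path) as fh:
        ds = json.load(fh)
    errors = validate_coco(ds)
    if errors:
        raise CocoValidationError(errors)
    return ds


def write_coco(ds: dict, path: str | Path) -> None:
    errors = validate_coco(ds)
    if errors:
        raise CocoValidationError(errors)
    with open(path, "w") as fh:
        json.dump(ds, fh, indent=None, separators=(",", ":"), sort_keys=False)


# ---------------------------------------------------------------------------
# mask <-> RLE / polygon


def mask_to_rle(mask: np.ndarray) -> dict:
    """Uncompressed COCO RLE: column-major runs, first run is background."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel(order="F").astype(np.int8)
    # run boundaries
    change = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"counts": counts, "size": [int(mask.shape[0]), int(mask.shape[1])]}


def rle_to_mask(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for run in rle["counts"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape((h, w), order="F")


def polygon_to_mask(polygons: list[list[float]], height: int, width: int) -> np.ndarray:
    """Rasterize COCO flat polygon list(s) to a single boolean mask."""
    mask = np.zeros((height, width), dtype=bool)
    for flat in polygons:
        pts = np.asarray(flat, dtype=float).reshape(-1, 2)
        if pts.shape[0] < 3:
            continue
        mask |= rasterize_polygon(pts, height, width)
    return mask


def mask_to_polygons(mask: np.ndarray) -> list[list[float]]:
    """Trace a mask's boundary into COCO flat polygon lists.

    Contours run along the 0.5-level between pixel squares, so rasterizing
    them back reproduces the mask exactly (pixel centers are never on the
    traced boundary).  One polygon per connected boundary loop.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask.astype(float), 1)
    polys = []
    for contour in find_contours(padded, 0.5):
        pts = contour[:, ::-1] - 1.0  # (row, col) -> (x, y), un-pad
        if len(pts) < 3:
            continue
        polys.append(np.round(pts, 4).ravel().tolist())
    return polys


def annotation_to_mask(ann: dict, height: int, width: int) -> np.ndarray:
    """Decode a COCO annotation's segmentation (polygon or RLE) to a mask."""
    seg = ann["segmentation"]
    if isinstance(seg, dict):
        return rle_to_mask(seg)
    return polygon_to_mask(seg, height, width)


# ---------------------------------------------------------------------------
# LabelMe import


def labelme_to_coco(json_dir: str | Path) -> dict:
    """Convert a directory of per-image LabelMe JSONs to one COCO dataset.

    Point polygons are carried over verbatim; distinct labels map to
    category ids in order of first appearance; shapes without a label are
    skipped with a warning.
    """
    json_dir = Path(json_dir)
    files = sorted(json_dir.glob("*.json"))
    images, annotations, categories = [], [], []
    label_to_id: dict[str, int] = {}
    next_ann = 1
    for image_id, path in enumerate(files, start=1):
        with open(path) as fh:
            rec = json.load(fh)
        height, width = rec["imageHeight"], rec["imageWidth"]
        images.append(
            {
                "id": image_id,
                "file_name": rec.get("imagePath", path.stem + ".png"),
                "height": height,
                "width": width,
            }
        )
        for shape in rec.get("shapes", []):
            label = shape.get("label")
            if not label:
                warnings.warn(f"{path.name}: unlabeled shape skipped", stacklevel=2)
                continue
            if label not in label_to_id:
                label_to_id[label] = len(label_to_id) + 1
                categories.append(
                    {"id": label_to_id[label], "name": label, "supercategory": ""}
                )
            pts = np.asarray(shape["points"], dtype=float)
            flat = pts.ravel().tolist()
            mask = polygon_to_mask([flat], height, width)
            area = float(mask.sum())
            if area <= 0:  # sub-pixel sliver: fall back to the shoelace area
                x, y = pts[:, 0], pts[:, 1]
                area = float(
                    0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
                ) or 1.0
            x0, y0 = pts.min(axis=0)
            x1, y1 = pts.max(axis=0)
            annotations.append(
                {
                    "id": next_ann,
                    "image_id": image_id,
                    "category_id": label_to_id[label],
                    "segmentation": [flat],
                    "area": area,
                    "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
                    "iscrowd": 0,
                }
            )
            next_ann += 1
    return {
        "info": {"description": "converted from LabelMe"},
        "images": images,
        "annotations": annotations,
        "categories": categories,
    }
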
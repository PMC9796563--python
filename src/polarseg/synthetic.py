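"""Synthetic orchard-like scenes and analytic fixtures with exact ground truth.

Real green-fruit imagery poses a homo-chromatic problem: the fruit and the
foliage background occupy overlapping green color distributions, instances
overlap each other, and branches occlude them.  The generator emulates
exactly those structural features -- quasi-elliptical green fruit on a
green-textured background, pairwise overlap, branch-like occluding stripes,
global brightness scaling for backlit/night shots, and sensor noise -- with
fully known per-instance masks, so that every downstream module can be
exercised without any image downloads.

It does not attempt photorealism: no specular highlights, no leaf geometry,
no raindrops.  Conclusions drawn from it concern the correctness of the
encoding/training/evaluation machinery, not field accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .contours import PolarContour, ray_angles

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "make_analytic_shape",
    "generate_scene",
    "generate_dataset",
]

FRUIT_CATEGORY = {"id": 1, "name": "fruit", "supercategory": "fruit"}


@dataclass
class SceneConfig:
    """Knobs of the scene generator.

    Defaults emulate the study conditions: 600x400 working resolution,
    dense fruit with frequent overlap and branch cover, near-equal greens
    (channel means within 15/255) and brightness spanning backlit to
    direct-light shots.
    """

    image_size: tuple[int, int] = (400, 600)  # (height, width)
    n_instances: tuple[int, int] = (3, 8)  # inclusive range
    radius_range: tuple[float, float] = (18.0, 55.0)
    eccentricity_range: tuple[float, float] = (1.0, 1.4)  # major/minor axis ratio
    overlap_prob: float = 0.6
    occluder_prob: float = 0.5
    occluder_width: tuple[float, float] = (6.0, 14.0)
    fruit_color: tuple[float, float, float] = (96.0, 138.0, 66.0)
    background_color: tuple[float, float, float] = (84.0, 126.0, 60.0)
    brightness_range: tuple[float, float] = (0.4, 1.2)
    noise_sigma: float = 6.0
    max_place_attempts: int = 40

    def __post_init__(self) -> None:
        if self.radius_range[0] <= 0:
            raise ValueError("radius range must be positive")
        for p in (self.overlap_prob, self.occluder_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticScene:
    """One generated image with its instance masks and COCO records."""

    image: np.ndarray  # (H, W, 3) uint8
    full_masks: list[np.ndarray]  # pre-occlusion truth
    visible_masks: list[np.ndarray]  # post-occlusion, the training targets
    annotations: list[dict]  # COCO annotation records (image_id unset = 0)
    occluders: np.ndarray | None = None  # union of branch stripes


def _grid(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    ys, xs = np.mgrid[0:height, 0:width]
    return xs.astype(float), ys.astype(float)


def _ellipse_mask(height, width, cx, cy, a, b, phi) -> np.ndarray:
    xs, ys = _grid(height, width)
    dx, dy = xs - cx, ys - cy
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_analytic_shape(
    kind: str,
    params: dict,
    image_size: tuple[int, int],
    n_rays: int = 36,
) -> tuple[np.ndarray, PolarContour]:
    """Rasterized mask plus the closed-form ``n_rays`` contour about the center.

    Supported kinds and params:

    - ``disc``: center=(x, y), radius
    - ``ellipse``: center, semi_axes=(a, b) with a along +x (no rotation)
    - ``square``: center, half_width
    - ``n_gon``: center, circumradius, n_sides, optional rotation (rad)
    """
    height, width = image_size
    cx, cy = params["center"]
    theta = ray_angles(n_rays)

    if kind == "disc":
        r = float(params["radius"])
        _check_fit(cx, cy, r, width, height)
        mask = _ellipse_mask(height, width, cx, cy, r, r, 0.0)
        rays = np.full(n_rays, r)
    elif kind == "ellipse":
        a, b = params["semi_axes"]
        _check_fit(cx, cy, max(a, b), width, height)
        mask = _ellipse_mask(height, width, cx, cy, a, b, 0.0)
        rays = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    elif kind == "square":
        hw = float(params["half_width"])
        _check_fit(cx, cy, hw * np.sqrt(2), width, height)
        xs, ys = _grid(height, width)
        mask = (np.abs(xs - cx) <= hw) & (np.abs(ys - cy) <= hw)
        rays = hw / np.maximum(np.abs(np.cos(theta)), np.abs(np.sin(theta)))
    elif kind == "n_gon":
        R = float(params["circumradius"])
        k = int(params["n_sides"])
        rot = float(params.get("rotation", 0.0))
        _check_fit(cx, cy, R, width, height)
        # polar form of a regular k-gon: apothem / cos(angle to nearest edge normal)
        sector = 2.0 * np.pi / k
        local = np.mod(theta - rot, sector) - sector / 2.0
        rays = R * np.cos(sector / 2.0) / np.cos(local)
        verts_t = rot + sector * np.arange(k)
        from .contours import rasterize_polygon  # local import to avoid cycle at module load

        verts = np.stack(
            [cx + R * np.cos(verts_t), cy + R * np.sin(verts_t)], axis=1
        )
        mask = rasterize_polygon(verts, height, width)
    else:
        raise ValueError(f"unknown shape kind {kind!r}")
    return mask, PolarContour((float(cx), float(cy)), rays, n_rays)


def _check_fit(cx, cy, extent, width, height) -> None:
    if cx - extent < 0 or cy - extent < 0 or cx + extent > width - 1 or cy + extent > height - 1:
        raise ValueError("shape does not fit inside the image")


def _occluder_stripe(height, width, width_range, rng) -> np.ndarray:
    """Boolean mask of a straight branch-like stripe crossing the image."""
    xs, ys = _grid(height, width)
    phi = rng.uniform(0, np.pi)
    nx, ny = np.cos(phi), np.sin(phi)
    cx = rng.uniform(0.2, 0.8) * width
    cy = rng.uniform(0.2, 0.8) * height
    w = rng.uniform(*width_range)
    return np.abs((xs - cx) * nx + (ys - cy) * ny) <= w / 2.0


def generate_scene(config: SceneConfig, seed: int) -> SyntheticScene:
    """Deterministically generate one scene from ``seed``."""
    rng = np.random.default_rng(seed)
    height, width = config.image_size
    n_target = int(rng.integers(config.n_instances[0], config.n_instances[1] + 1))

    full_masks: list[np.ndarray] = []
    ellipses: list[tuple] = []
    for _ in range(n_target):
        placed = False
        for _attempt in range(config.max_place_attempts):
            r = rng.uniform(*config.radius_range)
            ecc = rng.uniform(*config.eccentricity_range)
            a, b = r * np.sqrt(ecc), r / np.sqrt(ecc)
            phi = rng.uniform(0, np.pi)
            margin = max(a, b) + 2
            if 2 * margin >= min(height, width) - 1:
                continue
            cx = rng.uniform(margin, width - 1 - margin)
            cy = rng.uniform(margin, height - 1 - margin)
            mask = _ellipse_mask(height, width, cx, cy, a, b, phi)
            allow_overlap = rng.random() < config.overlap_prob
            if not allow_overlap and any(
                np.logical_and(mask, m).any() for m in full_masks
            ):
                continue
            full_masks.append(mask)
            ellipses.append((cx, cy, a, b, phi))
            placed = True
            break
        if not placed:
            warnings.warn("placement failed; scene has fewer instances", stacklevel=2)

    # branch-like occluders
    stripes = np.zeros((height, width), dtype=bool)
    for _ in range(len(full_masks)):
        if rng.random() < config.occluder_prob:
            stripes |= _occluder_stripe(height, width, config.occluder_width, rng)

    visible_masks, kept_full, kept_ell = [], [], []
    for mask, ell in zip(full_masks, ellipses):
        vis = mask & ~stripes
        if vis.any():
            visible_masks.append(vis)
            kept_full.append(mask)
            kept_ell.append(ell)
    full_masks = kept_full

    # composite: textured background, shaded fruit, dark stripes, noise, brightness
    bg = np.empty((height, width, 3))
    texture = gaussian_filter(rng.normal(0, 1, (height, width)), sigma=12)
    texture = texture / (np.abs(texture).max() + 1e-9)
    for c in range(3):
        bg[..., c] = config.background_color[c] + 18.0 * texture
    img = bg
    xs, ys = _grid(height, width)
    for mask, (cx, cy, a, b, phi) in zip(full_masks, kept_ell):
        rr = np.sqrt(((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2)
        shade = 1.0 - 0.25 * np.clip(rr, 0, 1) ** 2  # brighter center, darker rim
        for c in range(3):
            img[..., c] = np.where(mask, config.fruit_color[c] * shade, img[..., c])
    for c, dark in enumerate((45.0, 38.0, 28.0)):
        img[..., c] = np.where(stripes, dark, img[..., c])
    img *= rng.uniform(*config.brightness_range)
    img += rng.normal(0, config.noise_sigma, img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)

    from .coco import mask_to_rle  # deferred: coco imports contours

    annotations = []
    for i, vis in enumerate(visible_masks):
        ys_f, xs_f = np.nonzero(vis)
        bbox = [
            float(xs_f.min()),
            float(ys_f.min()),
            float(xs_f.max() - xs_f.min() + 1),
            float(ys_f.max() - ys_f.min() + 1),
        ]
        annotations.append(
            {
                "id": i + 1,
                "image_id": 0,
                "category_id": FRUIT_CATEGORY["id"],
                "segmentation": mask_to_rle(vis),
                "area": float(vis.sum()),
                "bbox": bbox,
                "iscrowd": 0,
            }
        )
    return SyntheticScene(image, full_masks, visible_masks, annotations, stripes)


def generate_dataset(
    n_images: int,
    config: SceneConfig,
    seed: int,
    out_dir: str | Path,
    train_fraction: float = 0.7,
) -> dict:
    """Write ``n_images`` scenes as a COCO dataset (images/ + annotations.json).

    Returns the COCO dictionary.  The train/test split lists are written as
    ``train.txt`` / ``test.txt`` of file names; the split is a deterministic
    prefix split after seeded shuffling.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_images)

    images, annotations = [], []
    next_ann = 1
    for idx, s in enumerate(scene_seeds):
        scene = generate_scene(config, int(s))
        image_id = idx + 1
        fname = f"scene_{image_id:05d}.png"
        Image.fromarray(scene.image).save(out / "images" / fname)
        h, w = scene.image.shape[:2]
        images.append({"id": image_id, "file_name": fname, "height": h, "width": w})
        for ann in scene.annotations:
            ann = dict(ann)
            ann["image_id"] = image_id
            ann["id"] = next_ann
            next_ann += 1
            annotations.append(ann)

    dataset = {
        "info": {"description": "synthetic orchard scenes", "version": "1"},
        "images": images,
        "annotations": annotations,
        "categories": [FRUIT_CATEGORY],
    }
    from .coco import write_coco

    write_coco(dataset, out / "annotations.json")

    order = rng.permutation(n_images)
    n_train = int(round(train_fraction * n_images))
    train = sorted(images[i]["file_name"] for i in order[:n_train])
    test = sorted(images[i]["file_name"] for i in order[n_train:])
    (out / "train.txt").write_text("\n".join(train) + "\n")
    (out / "test.txt").write_text("\n".join(test) + "\n")
    return dataset
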
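"""Training-target assignment for the dense polar head.

Each instance is assigned to the single pyramid level whose scale range
contains its maximum ray length (measured from the centroid), so large
fruit is regressed on coarse levels and small fruit on fine ones.  Within
that level, the positive locations are the grid cells whose image-plane
position lies within ``center_radius_factor * stride`` of the instance
centroid (the cell nearest the centroid is always positive).  At every
positive location the ray targets are re-extracted about that location, and
the center-ness target is the min/max ratio of those rays -- so a location
near the instance edge carries a low center-ness target even though it is
a positive sample.

When two instances claim the same cell the one with the smaller maximal
ray (the smaller instance) wins, the usual ambiguity rule for dense heads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..contours import compute_centroid, extract_rays, polar_centerness

__all__ = ["TargetAssignment", "LevelTargets", "default_scale_ranges", "assign_targets"]


@dataclass
class LevelTargets:
    """Dense targets on one pyramid level's grid."""

    stride: int
    cls_target: np.ndarray  # (H, W) int; 0 = background, else category id
    cen_target: np.ndarray  # (H, W) float in [0, 1]
    ray_targets: np.ndarray  # (n_rays, H, W) float
    pos_mask: np.ndarray  # (H, W) bool


@dataclass
class TargetAssignment:
    levels: list[LevelTargets]
    n_pos: int


def default_scale_ranges(strides: list[int]) -> list[tuple[float, float]]:
    """Per-level (min, max) admissible maximum-ray ranges, stride-proportional.

    Level i accepts instances whose max ray lies in [4*s_{i-1}, 4*s_i),
    with the first lower bound 0 and the last upper bound infinite.
    """
    bounds = [0.0] + [4.0 * s for s in strides[:-1]] + [float("inf")]
    return list(zip(bounds[:-1], bounds[1:]))


def assign_targets(
    instances: list[tuple[np.ndarray, int]],
    image_size: tuple[int, int],
    strides: list[int],
    n_rays: int = 36,
    scale_ranges: list[tuple[float, float]] | None = None,
    center_radius_factor: float = 1.5,
) -> TargetAssignment:
    """Build dense targets from ``(mask, category_id)`` instances.

    ``image_size`` is (height, width); grids are ``ceil(size / stride)``.
    """
    height, width = image_size
    if scale_ranges is None:
        scale_ranges = default_scale_ranges(strides)
    levels = []
    for stride in strides:
        gh = -(-height // stride)
        gw = -(-width // stride)
        levels.append(
            LevelTargets(
                stride=stride,
                cls_target=np.zeros((gh, gw), dtype=int),
                cen_target=np.zeros((gh, gw)),
                ray_targets=np.zeros((n_rays, gh, gw)),
                pos_mask=np.zeros((gh, gw), dtype=bool),
            )
        )
    # smaller instances assigned last would be overwritten; process large->small
    # so that the smaller instance wins contested cells
    prepared = []
    for mask, category in instances:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            warnings.warn("zero-area instance skipped in target assignment", stacklevel=2)
            continue
        centroid = compute_centroid(mask)
        max_ray = extract_rays(mask, centroid, n_rays).ray_lengths.max()
        prepared.append((max_ray, mask, category, centroid))
    prepared.sort(key=lambda t: -t[0])

    n_pos = 0
    claimed_max_ray = [np.full(lv.cls_target.shape, np.inf) for lv in levels]
    for max_ray, mask, category, centroid in prepared:
        li = next(
            (i for i, (lo, hi) in enumerate(scale_ranges) if lo <= max_ray < hi),
            len(levels) - 1,
        )
        lv = levels[li]
        s = lv.stride
        gh, gw = lv.cls_target.shape
        cx, cy = centroid
        radius = center_radius_factor * s
        gx = np.arange(gw) * s + s / 2.0
        gy = np.arange(gh) * s + s / 2.0
        dx = gx[None, :] - cx
        dy = gy[:, None] - cy
        near = dx**2 + dy**2 <= radius**2
        jc = int(np.clip(round((cx - s / 2.0) / s), 0, gw - 1))
        ic = int(np.clip(round((cy - s / 2.0) / s), 0, gh - 1))
        near[ic, jc] = True
        for i, j in zip(*np.nonzero(near)):
            px = min(gx[j], width - 1.0)
            py = min(gy[i], height - 1.0)
            rays = extract_rays(mask, (px, py), n_rays).ray_lengths
            if rays.max() <= 0:
                continue
            if max_ray >= claimed_max_ray[li][i, j]:
                continue  # a smaller instance already owns this cell
            was_pos = lv.pos_mask[i, j]
            claimed_max_ray[li][i, j] = max_ray
            lv.cls_target[i, j] = category
            lv.cen_target[i, j] = polar_centerness(rays)
            lv.ray_targets[:, i, j] = rays
            lv.pos_mask[i, j] = True
            if not was_pos:
                n_pos += 1
    return TargetAssignment(levels=levels, n_pos=n_pos)
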
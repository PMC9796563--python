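"""Polar contour representation of instance masks.

An instance mask is encoded as a center point plus ``n`` ray lengths at
fixed angular steps (default 36 rays, one every 10 degrees).  The image
convention is x = column, y = row, 0-based, with pixel centers at integer
coordinates; since y grows downward on screen, increasing angle runs
clockwise when displayed.  Ray ``a`` (1-based) points at angle
``theta_a = (a - 1) * 2*pi / n`` from the +x axis.

The center-ness of a contour is ``min(rays) / max(rays)``: 1 for a center
equidistant from the boundary in every sampled direction, small for an
off-center or degenerate encoding.  It is used to down-weight predictions
whose implied center sits near the instance boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as _draw_polygon

__all__ = [
    "PolarContour",
    "Polygon",
    "ray_angles",
    "compute_centroid",
    "select_center_samples",
    "extract_rays",
    "polar_centerness",
    "decode_contour",
    "rasterize_polygon",
    "mask_iou",
    "EmptyMaskError",
]

#: Sub-pixel step (in pixels) used when scanning along a ray.
RAY_SCAN_STEP = 0.25

#: Ray lengths below this are treated as zero-length when clamping for losses.
RAY_EPS = 1e-6


class EmptyMaskError(ValueError):
    """Raised when an instance-level operation receives an all-background mask."""


@dataclass(frozen=True)
class PolarContour:
    """Center point plus ``n_rays`` ray lengths at uniform angular spacing."""

    center: tuple[float, float]  # (x, y), continuous pixel coordinates
    ray_lengths: np.ndarray  # shape (n_rays,), non-negative
    n_rays: int = field(default=36)

    def __post_init__(self) -> None:
        rays = np.asarray(self.ray_lengths, dtype=float)
        object.__setattr__(self, "ray_lengths", rays)
        if self.n_rays != rays.shape[0]:
            object.__setattr__(self, "n_rays", rays.shape[0])
        if self.n_rays < 3:
            raise ValueError(f"need at least 3 rays, got {self.n_rays}")
        if np.any(rays < 0):
            raise ValueError("ray lengths must be non-negative")

    @property
    def angles(self) -> np.ndarray:
        return ray_angles(self.n_rays)


@dataclass(frozen=True)
class Polygon:
    """Ordered (clockwise on screen) vertex list; implicitly closed."""

    vertices: np.ndarray  # shape (n, 2) of (x, y)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must have shape (n, 2)")
        object.__setattr__(self, "vertices", v)


def ray_angles(n_rays: int) -> np.ndarray:
    """Angles of rays 1..n: ``theta_a = (a - 1) * 2*pi / n``."""
    return np.arange(n_rays) * (2.0 * np.pi / n_rays)


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    return mask.astype(bool, copy=False)


def compute_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Center of gravity (mean foreground coordinate) of an instance mask.

    Returns ``(x, y)`` in continuous pixel coordinates.
    """
    mask = _validate_mask(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("centroid of an empty mask is undefined")
    return float(cols.mean()), float(rows.mean())


def select_center_samples(mask: np.ndarray, radius: float) -> np.ndarray:
    """Foreground grid points within ``radius`` px of the instance centroid.

    The grid cell nearest the centroid is always included (even if it falls
    on background, e.g. for a ring-like mask).  Returns an (m, 2) integer
    array of (x, y) grid coordinates.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    mask = _validate_mask(mask)
    cx, cy = compute_centroid(mask)
    nearest = (int(round(cx)), int(round(cy)))
    rows, cols = np.nonzero(mask)
    d2 = (cols - cx) ** 2 + (rows - cy) ** 2
    keep = d2 <= radius**2
    pts = {(int(x), int(y)) for x, y in zip(cols[keep], rows[keep])}
    h, w = mask.shape
    if 0 <= nearest[0] < w and 0 <= nearest[1] < h:
        pts.add(nearest)
    out = np.array(sorted(pts), dtype=int)
    return out.reshape(-1, 2)


def extract_rays(
    mask: np.ndarray,
    center: tuple[float, float],
    n_rays: int = 36,
    step: float = RAY_SCAN_STEP,
) -> PolarContour:
    """Encode a mask as ray lengths about ``center``.

    Each ray is scanned outward in sub-pixel steps to the image diagonal;
    the ray length is the distance to the farthest sampled position whose
    nearest pixel is foreground (0 if the ray never meets the object).
    Taking the farthest hit implements the rule that background gaps along
    a ray -- concavities, holes -- do not truncate the ray.
    """
    mask = _validate_mask(mask)
    h, w = mask.shape
    cx, cy = float(center[0]), float(center[1])
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError(f"center {center!r} outside image bounds {w}x{h}")
    if n_rays < 3:
        raise ValueError("n_rays must be >= 3")
    if not mask.any():
        warnings.warn("extract_rays on an empty mask: all rays zero", stacklevel=2)
        return PolarContour((cx, cy), np.zeros(n_rays), n_rays)

    diag = float(np.hypot(h, w))
    dists = np.arange(0.0, diag + step, step)  # (S,)
    theta = ray_angles(n_rays)  # (R,)
    xs = cx + np.cos(theta)[:, None] * dists[None, :]
    ys = cy + np.sin(theta)[:, None] * dists[None, :]
    px = np.rint(xs).astype(int)
    py = np.rint(ys).astype(int)
    inside = (px >= 0) & (px < w) & (py >= 0) & (py < h)
    hit = np.zeros_like(inside)
    hit[inside] = mask[py[inside], px[inside]]
    # farthest foreground sample per ray
    any_hit = hit.any(axis=1)
    last = hit.shape[1] - 1 - np.argmax(hit[:, ::-1], axis=1)
    lengths = np.where(any_hit, dists[last], 0.0)
    return PolarContour((cx, cy), lengths, n_rays)


def polar_centerness(contour: PolarContour | np.ndarray) -> float:
    """``min(rays) / max(rays)`` in [0, 1]; 0 when all rays are zero."""
    rays = contour.ray_lengths if isinstance(contour, PolarContour) else np.asarray(contour, float)
    mx = rays.max()
    if mx <= 0:
        return 0.0
    return float(rays.min() / mx)


def decode_contour(contour: PolarContour) -> Polygon:
    """Vertices ``(cos(theta_a)*l_a + x_cen, sin(theta_a)*l_a + y_cen)`` in ray order."""
    cx, cy = contour.center
    theta = contour.angles
    x = np.cos(theta) * contour.ray_lengths + cx
    y = np.sin(theta) * contour.ray_lengths + cy
    return Polygon(np.stack([x, y], axis=1))


def rasterize_polygon(poly: Polygon | np.ndarray, height: int, width: int) -> np.ndarray:
    """Fill a polygon (even-odd rule) into a boolean mask, clipped to bounds."""
    verts = poly.vertices if isinstance(poly, Polygon) else np.asarray(poly, float)
    if verts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    area2 = np.abs(
        np.sum(
            verts[:, 0] * np.roll(verts[:, 1], -1) - np.roll(verts[:, 0], -1) * verts[:, 1]
        )
    )
    mask = np.zeros((height, width), dtype=bool)
    if area2 == 0.0:
        warnings.warn("degenerate (zero-area) polygon rasterizes to empty", stacklevel=2)
        return mask
    rr, cc = _draw_polygon(verts[:, 1], verts[:, 0], shape=(height, width))
    mask[rr, cc] = True
    return mask


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel intersection-over-union of two same-shape boolean masks."""
    a = _validate_mask(a)
    b = _validate_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(inter / union)


def clamp_rays(rays: np.ndarray, eps: float = RAY_EPS) -> np.ndarray:
    """Clamp zero-length rays to ``eps`` so that ratio/log losses stay finite."""
    return np.maximum(np.asarray(rays, dtype=float), eps)
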
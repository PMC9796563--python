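"""Training losses: Polar IoU (discrete and log-loss form), focal, BCE, composite.

The mask-regression loss treats the ``n`` predicted ray lengths of one
instance as a whole.  With equal angular weights the polar-coordinate IoU
of two ray vectors ``l`` and ``l*`` sharing a center is

    IoU = sum_i min(l_i, l*_i)^2 / sum_i max(l_i, l*_i)^2,

the discretization of the continuous areal IoU
``(int 1/2 min(l,l*)^2 d theta) / (int 1/2 max(l,l*)^2 d theta)``.
Dropping the squares gives the practical regression loss

    L = log( sum_i max(l_i, l*_i) / sum_i min(l_i, l*_i) ),

non-negative, zero iff the vectors coincide, scale-invariant, and with a
bounded piecewise-constant gradient per ray, which keeps regression on 36
rays balanced against the classification term without hand weighting.

All functions here are plain numpy; autodiff counterparts used inside the
training loop live in :mod:`polarseg.nn` and are cross-checked against
these in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossConfig",
    "polar_iou_discrete",
    "polar_iou_loss",
    "polar_iou_loss_grad",
    "focal_loss",
    "centerness_loss",
    "total_loss",
]

_EPS = 1e-12


@dataclass
class LossConfig:
    """Weights and shape parameters of the composite loss.

    ``centerness_balance`` is the balance coefficient applied to the
    center-ness term; focal defaults follow the standard focal-loss
    recommendation (alpha=0.25, gamma=2).
    """

    centerness_balance: float = 1.0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    weights: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        vals = (self.centerness_balance, self.focal_alpha, self.focal_gamma, *self.weights)
        if any(v < 0 for v in vals):
            raise ValueError("loss configuration values must be non-negative")

    def to_dict(self) -> dict:
        return {
            "centerness_balance": self.centerness_balance,
            "focal_alpha": self.focal_alpha,
            "focal_gamma": self.focal_gamma,
            "weights": list(self.weights),
        }


def _pair(pred, target) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"ray-vector length mismatch: {p.shape} vs {t.shape}")
    return p, t


def polar_iou_discrete(pred, target) -> float:
    """Discrete polar IoU ``sum min^2 / sum max^2`` of two ray vectors."""
    p, t = _pair(pred, target)
    lo = np.minimum(p, t)
    hi = np.maximum(p, t)
    denom = np.sum(hi**2)
    if denom <= 0:
        raise ValueError("polar IoU undefined for all-zero ray vectors")
    return float(np.sum(lo**2) / denom)


def polar_iou_loss(pred, target) -> float:
    """``log(sum max / sum min)``: zero iff pred == target elementwise."""
    p, t = _pair(pred, target)
    if np.any(p <= 0) or np.any(t <= 0):
        raise ValueError("ray lengths must be positive (epsilon-clamp upstream)")
    lo = np.sum(np.minimum(p, t))
    hi = np.sum(np.maximum(p, t))
    return float(np.log(hi / lo))


def polar_iou_loss_grad(pred, target) -> np.ndarray:
    """Analytic gradient of :func:`polar_iou_loss` w.r.t. the predicted rays.

    Per ray the loss sees the prediction through either the max-sum
    (``pred > target``: gradient ``+1/sum_max``) or the min-sum
    (``pred < target``: gradient ``-1/sum_min``); at a tie both branches
    move together and the subgradient ``1/sum_max - 1/sum_min`` is used.
    """
    p, t = _pair(pred, target)
    if np.any(p <= 0) or np.any(t <= 0):
        raise ValueError("ray lengths must be positive (epsilon-clamp upstream)")
    lo = np.sum(np.minimum(p, t))
    hi = np.sum(np.maximum(p, t))
    grad = np.where(p > t, 1.0 / hi, np.where(p < t, -1.0 / lo, 1.0 / hi - 1.0 / lo))
    return grad


def focal_loss(pred_prob, target, alpha: float = 0.25, gamma: float = 2.0) -> float:
    """Focal loss; scalar inputs give the per-sample value, arrays the
    batch form summed over all locations and divided by the positive count.

    Positives: ``-alpha * (1-p)^gamma * log p``; negatives:
    ``-(1-alpha) * p^gamma * log(1-p)``.  The batch normalizer is
    ``max(N_pos, 1)``.
    """
    p = np.asarray(pred_prob, dtype=float)
    t = np.asarray(target, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("predicted probabilities must lie strictly inside (0, 1)")
    pos = -alpha * (1.0 - p) ** gamma * np.log(p)
    neg = -(1.0 - alpha) * p**gamma * np.log(1.0 - p)
    per = np.where(t == 1, pos, neg)
    if per.ndim == 0:
        return float(per)
    n_pos = max(int(np.sum(t == 1)), 1)
    return float(np.sum(per) / n_pos)


def centerness_loss(pred, target) -> float:
    """Binary cross-entropy between predicted and target center-ness."""
    p = np.clip(np.asarray(pred, dtype=float), _EPS, 1.0 - _EPS)
    t = np.asarray(target, dtype=float)
    per = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))
    return float(np.mean(per))


def total_loss(
    cls_term: float,
    cen_term: float,
    mask_term: float,
    config: LossConfig | None = None,
) -> float:
    """Weighted composite ``w_cls*L_cls + w_cen*balance*L_cen + w_mask*L_mask``."""
    config = config or LossConfig()
    terms = {"cls": cls_term, "cen": cen_term, "mask": mask_term}
    for name, value in terms.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite {name} loss term: {value}")
    w_cls, w_cen, w_mask = config.weights
    return float(
        w_cls * cls_term + w_cen * config.centerness_balance * cen_term + w_mask * mask_term
    )
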
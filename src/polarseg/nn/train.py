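"""Training loop: composite loss on the autodiff graph, SGD with momentum.

The total objective is the sum of three terms, ``L = L_cls + L_cen +
L_mask``: focal classification loss over every location of every pyramid
level normalized by the number of positive samples, binary cross-entropy
on center-ness at the positive locations (scaled by a balance
coefficient), and the polar-IoU regression loss on the 36 predicted ray
lengths at the positive locations.  Optimization is plain SGD with
momentum 0.9, weight decay 1e-4 and learning rate 0.0025 by default.

Runs are bitwise deterministic for a fixed seed: parameter initialization,
scene synthesis and batch sampling all draw from seeded generators, and
the numpy compute path has no nondeterministic reductions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..synthetic import SceneConfig, generate_scene
from .autograd import Tensor, maximum, minimum
from .model import ModelConfig, PolarNet, normalize_image
from .targets import TargetAssignment, assign_targets

__all__ = ["TrainConfig", "TrainSample", "fit", "batch_loss", "build_toy_dataset",
           "toy_model_config", "toy_train_config", "toy_scene_config",
           "save_checkpoint", "load_checkpoint"]

_EPS = 1e-6


@dataclass
class TrainConfig:
    lr: float = 0.0025
    warmup_steps: int = 0  # linear learning-rate warmup
    weight_decay: float = 1e-4
    momentum: float = 0.9
    epochs: int = 24
    steps: int | None = None  # overrides epochs when set
    batch_size: int = 8
    seed: int = 0
    centerness_balance: float = 1.0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    checkpoint_every: int | None = None
    out_dir: str | None = None


@dataclass
class TrainSample:
    image: np.ndarray  # (H, W, 3)
    targets: TargetAssignment


def _clamp01(p: Tensor, eps: float = _EPS) -> Tensor:
    # affine squeeze into (eps, 1-eps); differentiable everywhere
    return p * (1.0 - 2.0 * eps) + eps


def batch_loss(model: PolarNet, batch: list[TrainSample], config: TrainConfig):
    """Forward pass + composite loss for a batch; returns (total, terms dict)."""
    images = np.stack(
        [normalize_image(np.asarray(s.image, dtype=np.float64)) for s in batch]
    ).transpose(0, 3, 1, 2)
    outputs = model.forward(images)
    n_classes = model.config.n_classes
    n_pos_total = sum(s.targets.n_pos for s in batch)
    n_pos_norm = max(n_pos_total, 1)
    alpha, gamma = config.focal_alpha, config.focal_gamma

    cls_sum: Tensor | None = None
    cen_sum: Tensor | None = None
    mask_sum: Tensor | None = None
    for li, out in enumerate(outputs):
        lvls = [s.targets.levels[li] for s in batch]
        cls_t = np.stack(
            [
                np.stack([(lv.cls_target == c + 1) for c in range(n_classes)])
                for lv in lvls
            ]
        ).astype(float)  # (B, n_classes, h, w)
        pos = np.stack([lv.pos_mask for lv in lvls])  # (B, h, w)
        # focal classification over all locations
        p = _clamp01(out["cls_logits"].sigmoid())
        pos_term = -alpha * (1.0 - p) ** gamma * p.log()
        neg_term = -(1.0 - alpha) * p**gamma * (1.0 - p).log()
        per = Tensor(cls_t) * pos_term + Tensor(1.0 - cls_t) * neg_term
        lvl_cls = per.sum()
        cls_sum = lvl_cls if cls_sum is None else cls_sum + lvl_cls
        if not pos.any():
            continue
        # center-ness BCE at positives
        cen_t = np.stack([lv.cen_target for lv in lvls])[pos]  # (P,)
        cen_logit = out["cen_logits"].reshape(out["cen_logits"].shape[0],
                                              *out["cen_logits"].shape[2:])
        cp = _clamp01(cen_logit[pos].sigmoid())
        t = Tensor(cen_t)
        bce = -(t * cp.log() + (1.0 - t) * (1.0 - cp).log())
        lvl_cen = bce.sum()
        cen_sum = lvl_cen if cen_sum is None else cen_sum + lvl_cen
        # polar IoU regression at positives
        ray_t = np.maximum(
            np.stack([lv.ray_targets for lv in lvls]).transpose(0, 2, 3, 1)[pos], _EPS
        )  # (P, R)
        rays = out["ray_lengths"].transpose((0, 2, 3, 1))[pos]
        tt = Tensor(ray_t)
        lo = minimum(rays, tt).sum(axis=1)
        hi = maximum(rays, tt).sum(axis=1)
        lvl_mask = (hi / lo).log().sum()
        mask_sum = lvl_mask if mask_sum is None else mask_sum + lvl_mask

    zero = Tensor(0.0)
    cls_loss = (cls_sum if cls_sum is not None else zero) * (1.0 / n_pos_norm)
    cen_loss = (cen_sum if cen_sum is not None else zero) * (
        config.centerness_balance / n_pos_norm
    )
    mask_loss = (mask_sum if mask_sum is not None else zero) * (1.0 / n_pos_norm)
    total = cls_loss + cen_loss + mask_loss
    terms = {
        "cls": float(cls_loss.data),
        "cen": float(cen_loss.data),
        "mask": float(mask_loss.data),
        "total": float(total.data),
    }
    return total, terms


def fit(samples: list[TrainSample], config: TrainConfig, model: PolarNet | None = None,
        model_config: ModelConfig | None = None):
    """Train a model on prepared samples; returns (model, loss history).

    The history is a list of per-step dicts with keys step/cls/cen/mask/
    total.  A CSV log and checkpoints are written under ``config.out_dir``
    when set.  Raises ``RuntimeError`` on divergence (non-finite loss).
    """
    if not samples:
        raise ValueError("training set is empty")
    if model is None:
        model = PolarNet(model_config or ModelConfig(seed=config.seed))
    params = model.parameters()
    velocity = [np.zeros_like(p.data) for p in params]
    rng = np.random.default_rng(config.seed)
    steps = config.steps
    if steps is None:
        steps = config.epochs * max(len(samples) // config.batch_size, 1)

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    history: list[dict] = []
    for step in range(steps):
        idx = rng.choice(len(samples), size=min(config.batch_size, len(samples)),
                         replace=False)
        batch = [samples[i] for i in idx]
        total, terms = batch_loss(model, batch, config)
        if not np.isfinite(terms["total"]):
            raise RuntimeError(
                f"divergence at step {step}: non-finite loss terms {terms}"
            )
        for p in params:
            p.zero_grad()
        total.backward()
        lr = config.lr
        if config.warmup_steps:
            lr *= min(1.0, (step + 1) / config.warmup_steps)
        for p, v in zip(params, velocity):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            g = g + config.weight_decay * p.data
            v *= config.momentum
            v += g
            p.data = p.data - lr * v
        history.append({"step": step, **terms})
        if out_dir and config.checkpoint_every and (step + 1) % config.checkpoint_every == 0:
            save_checkpoint(model, out_dir / f"ckpt_{step + 1:06d}.npz")
    if out_dir:
        save_checkpoint(model, out_dir / "ckpt_final.npz")
        with open(out_dir / "loss_log.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["step", "cls", "cen", "mask", "total"])
            writer.writeheader()
            writer.writerows(history)
    return model, history


def save_checkpoint(model: PolarNet, path: str | Path) -> None:
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    cfg = json.dumps(asdict(model.config), sort_keys=True)
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> PolarNet:
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["__config__"]).decode())
    from .layers import BackboneConfig

    cfg_dict["backbone"] = BackboneConfig(**cfg_dict["backbone"])
    model = PolarNet(ModelConfig(**cfg_dict))
    n = len([k for k in data.files if k.startswith("param_")])
    model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
    return model


def toy_model_config(seed: int = 0) -> ModelConfig:
    """Reduced channel widths for desk-scale CPU training experiments."""
    from .layers import BackboneConfig

    return ModelConfig(
        backbone=BackboneConfig(layers_per_block=2, growth_rate=8, stem_channels=16),
        fpn_width=24,
        head_convs=1,
        seed=seed,
    )


def toy_train_config(seed: int = 0, steps: int = 200, out_dir: str | None = None) -> TrainConfig:
    """Desk-scale optimization settings: a from-scratch toy model needs a
    larger learning rate (with a short warmup) than the transfer-learning
    default."""
    return TrainConfig(
        steps=steps, batch_size=4, seed=seed, out_dir=out_dir, lr=0.04, warmup_steps=20
    )


def toy_scene_config(image_size=(128, 128)) -> SceneConfig:
    """Down-scaled scene settings for desk-scale training experiments."""
    return SceneConfig(
        image_size=image_size,
        n_instances=(1, 3),
        radius_range=(10.0, 26.0),
        occluder_width=(3.0, 6.0),
        brightness_range=(0.7, 1.2),
        noise_sigma=4.0,
    )


def build_toy_dataset(
    n_images: int = 64,
    image_size: tuple[int, int] = (128, 128),
    seed: int = 0,
    strides: list[int] | None = None,
    n_rays: int = 36,
) -> list[TrainSample]:
    """Synthesize scenes and precompute dense targets for toy training."""
    strides = strides or [4, 8, 16, 32, 64]
    cfg = toy_scene_config(image_size)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_images)
    samples = []
    for s in seeds:
        scene = generate_scene(cfg, int(s))
        instances = [(m, 1) for m in scene.visible_masks]
        targets = assign_targets(instances, image_size, strides, n_rays=n_rays)
        samples.append(TrainSample(image=scene.image, targets=targets))
    return samples
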
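"""Network building blocks: dense backbone, feature pyramid, criss-cross attention.

The backbone follows the densely-connected design: three dense blocks of
3x3 convolutions in which every layer receives the concatenation of all
previous layer outputs within its block, each block preceded by a
transition (1x1 convolution to ``4 * growth_rate`` channels + 2x2 pooling)
that compresses features and halves resolution.  The three block outputs
C1..C3 (strides 4/8/16) feed a feature pyramid: 1x1 lateral connections
fused top-down with 2x nearest upsampling give P1..P3, and P4/P5 come from
P3 by two further downsamplings.  A criss-cross attention pass applied to
each pyramid level lets every position aggregate context from its full row
and column (H+W-1 positions) at low cost, sharpening features of small,
low-contrast instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, conv2d

__all__ = [
    "BackboneConfig",
    "Module",
    "Conv2d",
    "DenseBlock",
    "Transition",
    "DenseBackbone",
    "FPN",
    "CrissCrossAttention",
    "build_backbone",
    "build_fpn",
]


class Module:
    """Minimal parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding=None, bias=True, bias_init=0.0):
        if padding is None:
            padding = k // 2
        self.stride, self.padding = stride, padding
        # He-normal fan-in initialization
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, k, k)), requires_grad=True)
        self.bias = (
            Tensor(np.full(cout, float(bias_init)), requires_grad=True) if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class GroupNorm(Module):
    """Group normalization with learnable per-channel scale and shift.

    Batch-size independent (statistics over channel groups and space), so
    training and inference behave identically -- the norm of choice for
    small-batch dense prediction heads.
    """

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        groups = min(groups, channels)
        while channels % groups:
            groups -= 1
        self.groups, self.eps = groups, eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        t = x.reshape(n, g, (c // g) * h * w)
        mu = t.mean(axis=2, keepdims=True)
        var = ((t - mu) ** 2).mean(axis=2, keepdims=True)
        y = (t - mu) * ((var + self.eps) ** -0.5)
        y = y.reshape(n, c, h, w)
        return y * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ConvNorm(Module):
    """Conv2d -> GroupNorm (+ optional ReLU applied by the caller)."""

    def __init__(self, cin, cout, k, rng, stride=1, padding=None):
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, padding=padding, bias=False)
        self.norm = GroupNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x))


@dataclass
class BackboneConfig:
    """Dense backbone hyperparameters (toy-scale defaults)."""

    n_dense_blocks: int = 3
    layers_per_block: int = 4
    growth_rate: int = 16
    stem_channels: int = 32

    def __post_init__(self) -> None:
        if self.n_dense_blocks != 3:
            raise ValueError("the backbone emits C1..C3 and requires exactly 3 dense blocks")
        if self.growth_rate < 1:
            raise ValueError("growth rate must be >= 1")


class DenseBlock(Module):
    """``layers`` 3x3 conv layers, each fed the concat of all prior outputs."""

    def __init__(self, cin, layers, growth, rng):
        self.convs = []
        c = cin
        for _ in range(layers):
            self.convs.append(ConvNorm(c, growth, 3, rng))
            c += growth
        self.out_channels = c

    def __call__(self, x: Tensor) -> Tensor:
        feats = [x]
        for conv in self.convs:
            inp = feats[0] if len(feats) == 1 else concat(feats, axis=1)
            feats.append(conv(inp).relu())
        return concat(feats, axis=1)


class Transition(Module):
    """1x1 conv to ``4 * growth`` channels followed by 2x2 average pooling."""

    def __init__(self, cin, growth, rng):
        self.conv = ConvNorm(cin, 4 * growth, 1, rng, padding=0)
        self.out_channels = 4 * growth

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x).relu().avg_pool2()


class DenseBackbone(Module):
    """Stem (stride 2) + three [transition (pool) -> dense block] stages.

    Emits C1, C2, C3 at strides 4, 8, 16.
    """

    def __init__(self, config: BackboneConfig, rng):
        self.config = config
        self.stem = ConvNorm(3, config.stem_channels, 3, rng, stride=2)
        self.stages = []
        c = config.stem_channels
        for _ in range(config.n_dense_blocks):
            trans = Transition(c, config.growth_rate, rng)
            block = DenseBlock(
                trans.out_channels, config.layers_per_block, config.growth_rate, rng
            )
            self.stages.append((trans, block))
            c = block.out_channels
        self.out_channels = [blk.out_channels for _, blk in self.stages]
        self.strides = [4, 8, 16]

    def __call__(self, x: Tensor) -> list[Tensor]:
        y = self.stem(x).relu()
        cs = []
        for trans, block in self.stages:
            y = block(trans(y))
            cs.append(y)
        return cs


class FPN(Module):
    """Lateral 1x1 + top-down 2x fusion over C1..C3; P4/P5 by downsampling P3."""

    def __init__(self, in_channels: list[int], width: int, rng):
        if len(in_channels) != 3:
            raise ValueError("FPN expects exactly C1..C3")
        self.laterals = [Conv2d(c, width, 1, rng, padding=0) for c in in_channels]
        self.width = width
        self.strides = [4, 8, 16, 32, 64]

    def __call__(self, cs: list[Tensor]) -> list[Tensor]:
        c1, c2, c3 = cs
        for a, b in ((c1, c2), (c2, c3)):
            if a.shape[2] <= b.shape[2]:
                raise ValueError("C1..C3 must have strictly decreasing spatial size")
        p3 = self.laterals[2](c3)
        p2 = self.laterals[1](c2) + p3.upsample2()
        p1 = self.laterals[0](c1) + p2.upsample2()
        p4 = p3.max_pool2()
        p5 = p4.max_pool2()
        return [p1, p2, p3, p4, p5]


class CrissCrossAttention(Module):
    """One criss-cross attention pass with a residual connection.

    Each position forms attention weights over its own row and column
    (H+W-1 positions: the self position is masked out of the horizontal
    branch so it is counted once, in the vertical branch), aggregates the
    value projection with those weights, and adds the result to the input.
    """

    def __init__(self, channels: int, rng, reduction: int = 8):
        cq = max(channels // reduction, 1)
        self.query = Conv2d(channels, cq, 1, rng, padding=0, bias=False)
        self.key = Conv2d(channels, cq, 1, rng, padding=0, bias=False)
        self.value = Conv2d(channels, channels, 1, rng, padding=0, bias=False)
        self.channels = channels
        self.cq = cq

    def attention(self, x: Tensor) -> Tensor:
        """The (N, H, W, W+H) softmax attention map (self masked in row branch)."""
        n, c, h, w = x.shape
        if h < 1 or w < 1:
            raise ValueError("spatial dimensions must be >= 1")
        q = self.query(x)  # (N, C', H, W)
        k = self.key(x)
        # horizontal: along each row
        qh = q.transpose((0, 2, 3, 1)).reshape(n * h, w, self.cq)
        kh = k.transpose((0, 2, 1, 3)).reshape(n * h, self.cq, w)
        eh = qh.matmul(kh).reshape(n, h, w, w)
        mask = np.where(np.eye(w, dtype=bool), -1e9, 0.0)[None, None]
        eh = eh + Tensor(np.broadcast_to(mask, (n, h, w, w)).copy())
        # vertical: along each column
        qv = q.transpose((0, 3, 2, 1)).reshape(n * w, h, self.cq)
        kv = k.transpose((0, 3, 1, 2)).reshape(n * w, self.cq, h)
        ev = qv.matmul(kv).reshape(n, w, h, h).transpose((0, 2, 1, 3))  # (N,H,W,H)
        return concat([eh, ev], axis=3).softmax(axis=3)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        attn = self.attention(x)
        v = self.value(x)
        ah = attn[:, :, :, :w].reshape(n * h, w, w)
        vh = v.transpose((0, 2, 3, 1)).reshape(n * h, w, c)
        out_h = ah.matmul(vh).reshape(n, h, w, c)
        av = attn[:, :, :, w:].transpose((0, 2, 1, 3)).reshape(n * w, h, h)
        vv = v.transpose((0, 3, 2, 1)).reshape(n * w, h, c)
        out_v = av.matmul(vv).reshape(n, w, h, c).transpose((0, 2, 1, 3))
        out = (out_h + out_v).transpose((0, 3, 1, 2))
        return x + out


def build_backbone(config: BackboneConfig, rng=None) -> DenseBackbone:
    """Construct the dense backbone from its configuration."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return DenseBackbone(config, rng)


def build_fpn(in_channels: list[int], width: int = 32, rng=None) -> FPN:
    rng = rng if rng is not None else np.random.default_rng(0)
    return FPN(in_channels, width, rng)
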
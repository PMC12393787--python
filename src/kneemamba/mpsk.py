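"""Multi-scale pyramid / selective-kernel (MPSK) local feature extractor.

The local branch of the encoder.  Each residual block runs three parallel
convolutions with 1x1, 3x3 and 5x5 kernels, fuses them adaptively with
selective-kernel (SK) channel attention — a softmax over the three branches
computed per channel from a global average-pooled descriptor — then enriches
the result with a pyramid-pooling module (adaptive average pooling at several
grid levels, upsampled and re-mixed by a 1x1 convolution).  Blocks are
residual: F_out is added back onto F_in, so a zero inner path is the identity.
Four stages of such blocks, connected by stride-2 projections that double the
channel count, produce local feature maps at strides 4/8/16/32 that mirror
the global (state-space) encoder stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .types import FeatureMap


@dataclass
class MPSKConfig:
    stage_channels: tuple[int, int, int, int] = (96, 192, 384, 768)
    blocks_per_stage: tuple[int, int, int, int] = (2, 2, 2, 2)
    sk_reduction_ratio: int = 8
    sk_min_hidden: int = 32
    pool_levels: tuple[int, ...] = (1, 2, 3, 6)
    #: inner bottleneck width of a block as a fraction of its stage channels
    branch_width_ratio: float = 0.5
    #: explicit per-stage bottleneck widths; overrides the ratio when set
    branch_widths: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        cs = self.stage_channels
        if len(cs) != 4 or any(cs[i + 1] != 2 * cs[i] for i in range(3)):
            raise ValueError("stage_channels must be 4 values, doubling per stage")
        if list(self.pool_levels) != sorted(self.pool_levels) or min(self.pool_levels) < 1:
            raise ValueError("pool_levels must be ascending and >= 1")

    def width(self, stage: int) -> int:
        if self.branch_widths is not None:
            return self.branch_widths[stage]
        return max(int(round(self.stage_channels[stage] * self.branch_width_ratio)), 8)


@dataclass
class SKState:
    """Intermediate quantities of one selective-kernel attention pass."""

    fused_map: FeatureMap            # element-wise sum of the branches
    channel_descriptor: np.ndarray   # global average pool of the fused map, (C,)
    attention_logits: np.ndarray     # (branches M, C), pre-softmax
    attention_weights: np.ndarray    # (M, C), softmax over branches per channel


def _wrap(f: FeatureMap) -> Tensor:
    return Tensor(f.values[None])


def _unwrap(t: Tensor, stride: int) -> FeatureMap:
    return FeatureMap(np.asarray(t.data[0]), stride=stride)


class ConvBNAct(nn.Module):
    def __init__(self, c_in, c_out, k, rng, stride=1, act=True):
        super().__init__()
        # bias omitted: BatchNorm immediately recentres, a bias would be dead
        self.conv = nn.Conv2d(c_in, c_out, k, rng, stride=stride, bias=False)
        self.bn = nn.BatchNorm2d(c_out)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return y.relu() if self.act else y


class MultiScaleBranches(nn.Module):
    """Parallel 1x1 / 3x3 / 5x5 convolutions, each preserving (C, H, W)."""

    KERNELS = (1, 3, 5)

    def __init__(self, channels: int, rng: np.random.Generator, norm_act: bool = True):
        super().__init__()
        self.channels = channels
        if norm_act:
            self.b1 = ConvBNAct(channels, channels, 1, rng)
            self.b3 = ConvBNAct(channels, channels, 3, rng)
            self.b5 = ConvBNAct(channels, channels, 5, rng)
        else:
            self.b1 = nn.Conv2d(channels, channels, 1, rng)
            self.b3 = nn.Conv2d(channels, channels, 3, rng)
            self.b5 = nn.Conv2d(channels, channels, 5, rng)

    def forward(self, x: Tensor):
        if x.shape[1] != self.channels:
            raise ValueError(
                f"branch weights expect {self.channels} channels, input has {x.shape[1]}")
        return self.b1(x), self.b3(x), self.b5(x)


def multi_scale_branches(f_in: FeatureMap, branches: MultiScaleBranches):
    """Run the three parallel branches on a single feature map."""
    outs = branches(_wrap(f_in))
    return tuple(_unwrap(o, f_in.stride) for o in outs)


class SKSelect(nn.Module):
    """Selective-kernel fusion of M parallel branch maps.

    Fuse by element-wise sum, describe with global average pooling, squeeze
    through a bottleneck FC, expand to one logit per (branch, channel) and
    softmax over branches; the output is the weighted sum of the branches.
    """

    def __init__(self, channels: int, rng: np.random.Generator, branches: int = 3,
                 reduction: int = 8, min_hidden: int = 32):
        super().__init__()
        self.channels, self.branches = channels, branches
        hidden = max(channels // reduction, min_hidden)
        self.fc_reduce = nn.Linear(channels, hidden, rng)
        self.fc_expand = nn.Linear(hidden, branches * channels, rng)

    def forward(self, maps: list[Tensor]):
        shapes = {m.shape for m in maps}
        if len(shapes) != 1:
            raise ValueError(f"branch maps must share a shape, got {sorted(shapes)}")
        fused = maps[0]
        for m in maps[1:]:
            fused = fused + m
        z = fused.mean(axis=(2, 3))                      # (B, C)
        logits = self.fc_expand(self.fc_reduce(z).relu())
        B = fused.shape[0]
        logits = logits.reshape(B, self.branches, self.channels)
        weights = logits.softmax(axis=1)                 # (B, M, C)
        out = None
        for m_idx, m in enumerate(maps):
            w = weights[:, m_idx].reshape(B, self.channels, 1, 1)
            term = m * w
            out = term if out is None else out + term
        return out, (fused, z, logits, weights)


def sk_select(f_s1: FeatureMap, f_s2: FeatureMap, f_s3: FeatureMap,
              module: SKSelect) -> tuple[FeatureMap, SKState]:
    out, (fused, z, logits, weights) = module([_wrap(f_s1), _wrap(f_s2), _wrap(f_s3)])
    state = SKState(
        fused_map=_unwrap(fused, f_s1.stride),
        channel_descriptor=np.asarray(z.data[0]),
        attention_logits=np.asarray(logits.data[0]),
        attention_weights=np.asarray(weights.data[0]),
    )
    return _unwrap(out, f_s1.stride), state


class PyramidPool(nn.Module):
    """PSP-style pooling: per-level adaptive average pool -> 1x1 conv ->
    nearest upsample, concatenated with the un-pooled map, then a 1x1
    restoration conv back to the input channel count."""

    def __init__(self, channels: int, levels, rng: np.random.Generator,
                 strict: bool = True):
        super().__init__()
        self.levels = tuple(levels)
        self.strict = strict
        c_lvl = max(channels // len(self.levels), 1)
        self.level_convs = nn.Sequential(*[
            ConvBNAct(channels, c_lvl, 1, rng) for _ in self.levels])
        self.restore = ConvBNAct(channels + c_lvl * len(self.levels), channels, 1,
                                 rng, act=False)
        self.channels = channels
        self.c_lvl = c_lvl

    def forward(self, x: Tensor):
        H, W = x.shape[2], x.shape[3]
        parts = [x]
        for lvl, conv in zip(self.levels, self.level_convs.mods):
            if lvl > min(H, W):
                if self.strict:
                    raise ValueError(
                        f"pool level {lvl} exceeds spatial size {min(H, W)}")
                lvl = min(H, W)   # clamp to the spatial size inside blocks
            pooled = nn.adaptive_avg_pool2d(x, (lvl, lvl))
            parts.append(nn.upsample_nearest(conv(pooled), (H, W)))
        return self.restore(nn.concat(parts, axis=1))


def pyramid_pool(f_in: FeatureMap, module: PyramidPool) -> FeatureMap:
    return _unwrap(module(_wrap(f_in)), f_in.stride)


class MPSKBlock(nn.Module):
    """Residual MPSK unit: F_MPSK = F_in + inner(F_in).

    inner = 1x1 reduce -> {1x1,3x3,5x5} branches -> SK fusion -> pyramid
    pooling -> 1x1 expand (BN, no activation so a zeroed expand conv makes
    the block an exact identity).
    """

    def __init__(self, channels: int, cfg: MPSKConfig, stage: int,
                 rng: np.random.Generator):
        super().__init__()
        w = cfg.width(stage)
        self.reduce = ConvBNAct(channels, w, 1, rng)
        self.branches = MultiScaleBranches(w, rng)
        self.sk = SKSelect(w, rng, reduction=cfg.sk_reduction_ratio,
                           min_hidden=cfg.sk_min_hidden)
        self.pyramid = PyramidPool(w, cfg.pool_levels, rng, strict=False)
        self.expand = ConvBNAct(w, channels, 1, rng, act=False)

    def inner(self, x: Tensor) -> Tensor:
        h = self.reduce(x)
        b1, b3, b5 = self.branches(h)
        h, _ = self.sk([b1, b3, b5])
        h = self.pyramid(h)
        return self.expand(h)

    def forward(self, x: Tensor) -> Tensor:
        y = self.inner(x)
        if y.shape != x.shape:
            raise ValueError(f"inner path drifted from {x.shape} to {y.shape}")
        return x + y


def mpsk_block(f_in: FeatureMap, block: MPSKBlock) -> FeatureMap:
    return _unwrap(block(_wrap(f_in)), f_in.stride)


class MPSKPyramid(nn.Module):
    """Four stages of MPSK blocks with stride-2 channel-doubling transitions.

    Consumes the shared stride-4 stem features and emits local feature maps
    at strides 4/8/16/32 whose channel counts match the global encoder.
    """

    def __init__(self, cfg: MPSKConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        stages, transitions = [], []
        for s, c in enumerate(cfg.stage_channels):
            stages.append(nn.Sequential(*[
                MPSKBlock(c, cfg, s, rng) for _ in range(cfg.blocks_per_stage[s])]))
            if s < 3:
                transitions.append(
                    ConvBNAct(c, cfg.stage_channels[s + 1], 1, rng, stride=2))
        self.stages = nn.Sequential(*stages)
        self.transitions = nn.Sequential(*transitions)

    def forward(self, x: Tensor) -> list[Tensor]:
        H, W = x.shape[2], x.shape[3]
        if H % 8 or W % 8:
            raise ValueError(
                f"stride-4 input spatial dims must be divisible by 8, got {H}x{W}")
        outs = []
        for s in range(4):
            x = self.stages.mods[s](x)
            outs.append(x)
            if s < 3:
                x = self.transitions.mods[s](x)
        return outs


def mpsk_pyramid(f_in: FeatureMap, module: MPSKPyramid) -> list[FeatureMap]:
    """Run the 4-stage local pyramid on stride-4 stem features."""
    if f_in.stride != 4:
        raise ValueError(f"MPSK pyramid expects stride-4 input, got stride {f_in.stride}")
    outs = module(_wrap(f_in))
    return [_unwrap(o, 4 * 2 ** s) for s, o in enumerate(outs)]
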
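"""Per-stage fusion of global (state-space) and local (MPSK) features.

At every encoder level the two parallel branches produce feature maps of
identical shape; they are concatenated along channels (C + C -> 2C) and
mixed back to C channels by a 1x1 fusion convolution, optionally followed by
BatchNorm + ReLU.  The fused maps F1..F4 form the encoder pyramid that feeds
both the next encoder stage and the skip connections.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .types import FeatureMap, EncoderPyramid
from .mpsk import _wrap, _unwrap, ConvBNAct


class FuseStage(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator, activation: bool = True):
        super().__init__()
        self.channels = channels
        self.activation = activation
        self.conv = nn.Conv2d(2 * channels, channels, 1, rng, bias=False)
        self.bn = nn.BatchNorm2d(channels)

    def forward(self, f_mamba: Tensor, f_mpsk: Tensor) -> Tensor:
        if f_mamba.shape != f_mpsk.shape:
            raise ValueError(
                f"fusion inputs must match: global {f_mamba.shape} vs local {f_mpsk.shape}")
        y = self.bn(self.conv(nn.concat([f_mamba, f_mpsk], axis=1)))
        return y.relu() if self.activation else y


def fuse_stage(f_mamba: FeatureMap, f_mpsk: FeatureMap, module: FuseStage) -> FeatureMap:
    if f_mamba.stride != f_mpsk.stride:
        raise ValueError(
            f"fusion inputs at different strides: {f_mamba.stride} vs {f_mpsk.stride}")
    out = module(_wrap(f_mamba), _wrap(f_mpsk))
    return _unwrap(out, f_mamba.stride)


def build_pyramid(global_maps: list[FeatureMap], local_maps: list[FeatureMap],
                  fusers: list[FuseStage]) -> EncoderPyramid:
    """Fuse the four stage pairs into the encoder pyramid F1..F4."""
    if not (len(global_maps) == len(local_maps) == len(fusers) == 4):
        raise ValueError("expected four stages of global/local maps and fusers")
    stages = tuple(fuse_stage(g, l, f)
                   for g, l, f in zip(global_maps, local_maps, fusers))
    return EncoderPyramid(stages)
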
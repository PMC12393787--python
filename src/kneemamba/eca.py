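"""Efficient channel attention (ECA) on the skip connections.

Encoder features are reweighted per channel before being handed to the
decoder: a global average pool gives one descriptor per channel, a 1D
convolution across the channel axis (kernel size adapted to the channel
count) captures local cross-channel interaction, and a sigmoid turns the
result into weights in (0,1) that scale the encoder map.  The attended map
is fused with the decoder feature by element-wise addition, which requires
decoder stage widths to equal encoder stage widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .types import FeatureMap
from .mpsk import _wrap, _unwrap


@dataclass
class ECAState:
    channel_means: np.ndarray   # z, (C,)
    weights: np.ndarray         # omega, (C,), sigmoid range (0,1)
    kernel_size: int


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive 1D kernel size: nearest odd integer to (log2(C)/gamma + b/gamma).

    With the conventional gamma=2, b=1 this is (log2 C + 1) / 2.  Ties between
    the two neighbouring odd integers resolve downward; the result is >= 1.
    """
    if channels < 1:
        raise ValueError("channel count must be >= 1")
    target = (np.log2(channels) + b) / gamma
    lower = max(2 * int(np.floor((target - 1) / 2)) + 1, 1)
    upper = lower + 2
    k = lower if (target - lower) <= (upper - target) else upper
    return max(k, 1)


class ECAAttend(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator,
                 k: int | None = None):
        super().__init__()
        self.channels = channels
        self.k = eca_kernel_size(channels) if k is None else k
        if self.k % 2 == 0 or self.k < 1:
            raise ValueError("ECA kernel size must be odd and >= 1")
        # 1D conv across channels as a (1,1,1,k) conv on a (B,1,1,C) map
        self.register_parameter(
            "kernel", rng.normal(0, 1.0 / np.sqrt(self.k), (1, 1, 1, self.k)))
        self.register_parameter("bias", np.zeros(1))

    def forward(self, x: Tensor):
        B, C, H, W = x.shape
        z = x.mean(axis=(2, 3))                                   # (B, C)
        zi = z.reshape(B, 1, 1, C)
        conv = nn.conv2d(zi, self.kernel, self.bias,
                         padding=(0, self.k // 2))                # zero 'same' pad
        omega = conv.reshape(B, C).sigmoid()
        out = x * omega.reshape(B, C, 1, 1)
        return out, z, omega


def eca_attend(x_encoder: FeatureMap, module: ECAAttend) -> tuple[FeatureMap, ECAState]:
    out, z, omega = module(_wrap(x_encoder))
    state = ECAState(channel_means=np.asarray(z.data[0]),
                     weights=np.asarray(omega.data[0]),
                     kernel_size=module.k)
    return _unwrap(out, x_encoder.stride), state


def skip_fuse(x_eca: FeatureMap, x_decoder: FeatureMap) -> FeatureMap:
    """Skip fusion by element-wise addition of attended encoder and decoder maps."""
    if x_eca.values.shape != x_decoder.values.shape:
        raise ValueError(
            f"skip fusion requires identical shapes, got {x_eca.values.shape} "
            f"vs {x_decoder.values.shape}")
    return FeatureMap(x_eca.values + x_decoder.values, stride=x_decoder.stride)
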
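"""Shipped reference configurations.

The full-scale configuration targets a 256x256 input and a complexity budget
of 15.65 M trainable parameters for the plain state-space U-Net and 22.67 M
with the local pyramid and channel-attention additions.  The free width
knobs — the feed-forward ratio of the state-space blocks and the per-stage
bottleneck widths of the MPSK blocks — were calibrated once against that
budget; everything else follows the architecture defaults.
"""

from __future__ import annotations

from .ssm import VSSConfig
from .mpsk import MPSKConfig
from .model import ModelConfig

#: input size all stride arithmetic is documented against
REFERENCE_INPUT_HW = (256, 256)


def reference_vss_config() -> VSSConfig:
    return VSSConfig(embed_dim=64, depths=(2, 2, 2, 2), state_dim=16,
                     expansion=2.0, mlp_ratio=1.7334)


def reference_mpsk_config() -> MPSKConfig:
    return MPSKConfig(stage_channels=(64, 128, 256, 512),
                      blocks_per_stage=(2, 2, 2, 2),
                      branch_widths=(30, 66, 119, 227))


def baseline_reference(seed: int = 0) -> ModelConfig:
    """Plain state-space U-Net (no local pyramid, plain additive skips)."""
    return ModelConfig(vss=reference_vss_config(), mpsk=reference_mpsk_config(),
                       use_mpsk=False, use_eca=False, seed=seed)


def full_reference(seed: int = 0) -> ModelConfig:
    """Full model: fused local pyramid + channel-attended skips."""
    return ModelConfig(vss=reference_vss_config(), mpsk=reference_mpsk_config(),
                       use_mpsk=True, use_eca=True, seed=seed)
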
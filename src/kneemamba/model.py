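"""Full segmentation network and its ablation variants.

The encoder runs two parallel branches over the shared stride-4 patch
embedding: the state-space (global) stages and, when enabled, the MPSK
(local) pyramid; per-stage fusion concatenates the pair and mixes back to
the stage width.  Skips optionally pass through efficient channel attention
before additive fusion in the decoder.  The four ablation variants are:

    baseline      global encoder only, plain additive skips
    +ECA          baseline with channel attention on the skips
    +MPSK         parallel local pyramid fused per stage, plain skips
    full          both additions
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import Tensor
from .types import FeatureMap, EncoderPyramid, NUM_CLASSES
from .ssm import VSSConfig, PatchEmbed, VSSEncoder
from .mpsk import MPSKConfig, MPSKPyramid, _wrap, _unwrap
from .fusion import FuseStage
from .eca import ECAAttend
from .decoder import DecoderHead, predict_labels


@dataclass
class ModelConfig:
    vss: VSSConfig = field(default_factory=VSSConfig)
    mpsk: MPSKConfig = field(default_factory=MPSKConfig)
    use_mpsk: bool = True
    use_eca: bool = True
    decoder_depths: tuple[int, int, int, int] = (2, 2, 2, 1)
    in_channels: int = 1
    num_classes: int = NUM_CLASSES
    seed: int = 0

    def __post_init__(self):
        if self.use_mpsk and self.mpsk.stage_channels[0] != self.vss.embed_dim:
            raise ValueError(
                f"MPSK stage channels {self.mpsk.stage_channels} must start at "
                f"the embedding width {self.vss.embed_dim}")


class SegmentationModel(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.vss.embed_dim
        self.widths = [c, 2 * c, 4 * c, 8 * c]
        self.patch_embed = PatchEmbed(c, rng, in_channels=cfg.in_channels,
                                      eps=cfg.vss.norm_epsilon)
        self.encoder = VSSEncoder(cfg.vss, rng)
        if cfg.use_mpsk:
            self.mpsk = MPSKPyramid(cfg.mpsk, rng)
            self.fusers = nn.Sequential(*[FuseStage(w, rng) for w in self.widths])
        if cfg.use_eca:
            # skips exist on the three finer levels (the coarsest map starts
            # the decoder rather than being added to it)
            self.eca = nn.Sequential(*[ECAAttend(w, rng) for w in self.widths[:3]])
        self.decoder = DecoderHead(cfg.vss, rng, depths=cfg.decoder_depths,
                                   num_classes=cfg.num_classes)

    def encode(self, x: Tensor) -> list[Tensor]:
        f0 = self.patch_embed(x)
        global_maps = self.encoder(f0)
        if not self.cfg.use_mpsk:
            return global_maps
        local_maps = self.mpsk(f0)
        return [f(g, l) for f, g, l in
                zip(self.fusers.mods, global_maps, local_maps)]

    def forward(self, x: Tensor) -> Tensor:
        pyramid = self.encode(x)
        transform = None
        if self.cfg.use_eca:
            def transform(lvl, t):
                out, _, _ = self.eca.mods[lvl](t)
                return out
        return self.decoder(pyramid, skip_transform=transform)

    def predict_slice(self, image_2d: np.ndarray) -> np.ndarray:
        """Argmax labels for one preprocessed slice (ties -> lower class)."""
        x = np.asarray(image_2d, dtype=np.float64)
        logits = self(Tensor(x[None, None]))
        return predict_labels(np.asarray(logits.data))[0]

    def encoder_pyramid(self, image_2d: np.ndarray) -> EncoderPyramid:
        x = Tensor(np.asarray(image_2d, dtype=np.float64)[None, None])
        maps = self.encode(x)
        return EncoderPyramid(tuple(
            _unwrap(m, 4 * 2 ** s) for s, m in enumerate(maps)))


def build_variant(cfg: ModelConfig) -> SegmentationModel:
    """Construct one of the four ablation variants from its config flags."""
    return SegmentationModel(cfg)


def variant_grid(base: ModelConfig) -> dict[str, ModelConfig]:
    """The four ablation configurations sharing every other knob."""
    return {
        "baseline": replace(base, use_mpsk=False, use_eca=False),
        "+eca": replace(base, use_mpsk=False, use_eca=True),
        "+mpsk": replace(base, use_mpsk=True, use_eca=False),
        "full": replace(base, use_mpsk=True, use_eca=True),
    }


# -- complexity accounting ---------------------------------------------------

def _conv_flops(c_in, c_out, k, h, w):
    return 2 * c_in * c_out * k * k * h * w


def _linear_flops(d_in, d_out, tokens):
    return 2 * d_in * d_out * tokens


def _vss_block_flops(c, cfg: VSSConfig, h, w):
    t = h * w
    ci = int(round(cfg.expansion * c))
    n = cfg.state_dim
    fl = _linear_flops(c, 2 * ci, t)                       # in_proj
    fl += 4 * t * 2 * (n * n + 2 * n * ci + ci)            # 4-direction scan
    fl += _linear_flops(ci, c, t)                          # out_proj
    fl += 2 * _linear_flops(c, int(round(cfg.mlp_ratio * c)), t)  # MLP
    return fl


def _mpsk_stage_flops(c, cfg: MPSKConfig, stage, h, w):
    wd = cfg.width(stage)
    fl = _conv_flops(c, wd, 1, h, w)                       # reduce
    fl += sum(_conv_flops(wd, wd, k, h, w) for k in (1, 3, 5))
    c_lvl = max(wd // len(cfg.pool_levels), 1)
    for lvl in cfg.pool_levels:
        fl += _conv_flops(wd, c_lvl, 1, min(lvl, h), min(lvl, w))
    fl += _conv_flops(wd + c_lvl * len(cfg.pool_levels), wd, 1, h, w)  # restore
    fl += _conv_flops(wd, c, 1, h, w)                      # expand
    return fl * cfg.blocks_per_stage[stage]


def estimate_flops(cfg: ModelConfig, input_hw: tuple[int, int] = (256, 256)) -> float:
    """Analytic multiply-add FLOPs of one forward pass (2 FLOPs per MAC).

    Counts convolutions, linear maps and scan recurrences; normalisation,
    activations and pooling are omitted as lower-order terms.
    """
    H, W = input_hw
    c = cfg.vss.embed_dim
    widths = [c, 2 * c, 4 * c, 8 * c]
    sizes = [(H // (4 * 2 ** s), W // (4 * 2 ** s)) for s in range(4)]
    fl = _conv_flops(cfg.in_channels, c, 4, H // 4, W // 4)      # patch embed
    for s, (h, w) in enumerate(sizes):
        fl += cfg.vss.depths[s] * _vss_block_flops(widths[s], cfg.vss, h, w)
        if s < 3:
            fl += _linear_flops(4 * widths[s], 2 * widths[s],
                                sizes[s + 1][0] * sizes[s + 1][1])
        if cfg.use_mpsk:
            fl += _mpsk_stage_flops(widths[s], cfg.mpsk, s, h, w)
            if s < 3:
                fl += _conv_flops(widths[s], widths[s + 1], 1,
                                  sizes[s + 1][0], sizes[s + 1][1])
            fl += _conv_flops(2 * widths[s], widths[s], 1, h, w)  # fusion
    for i, lvl in enumerate(range(3, -1, -1)):                    # decoder
        h, w = sizes[lvl]
        fl += cfg.decoder_depths[i] * _vss_block_flops(widths[lvl], cfg.vss, h, w)
        if lvl > 0:
            fl += _linear_flops(widths[lvl], 4 * widths[lvl - 1], h * w)
    fl += _linear_flops(c, 16 * c, sizes[0][0] * sizes[0][1])     # final expand
    fl += _linear_flops(c, cfg.num_classes, H * W)
    if cfg.use_eca:
        for s in range(3):
            fl += 2 * widths[s] * 5                                # 1D conv, k<=5
    return float(fl)


def complexity_report(model: SegmentationModel,
                      input_hw: tuple[int, int] = (256, 256)) -> dict:
    """Exact trainable-parameter count plus analytic FLOPs at `input_hw`."""
    return {
        "parameter_count": model.num_parameters(),
        "parameters_millions": model.num_parameters() / 1e6,
        "flops_estimate": estimate_flops(model.cfg, input_hw),
        "flops_input_hw": tuple(input_hw),
    }
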
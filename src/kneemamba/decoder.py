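"""Decoder, segmentation head and training loss.

The decoder mirrors the global encoder: starting from the coarsest pyramid
level it alternates visual state-space blocks with patch-expanding (linear
channel expansion + pixel rearrangement) to double resolution and halve
channels, adding the (optionally ECA-attended) encoder skip at each level.
A final 4x patch expansion restores input resolution and a linear head emits
one logit map per class.  Training minimises cross-entropy plus soft-Dice
averaged over classes (weight lambda on the Dice term, default 1).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .types import FeatureMap, EncoderPyramid, NUM_CLASSES
from .ssm import VSSBlock, VSSConfig
from .mpsk import _wrap


class PatchExpand(nn.Module):
    """Linear expansion + pixel shuffle: (H,W,C) -> (rH,rW,C_out).

    The linear layer maps C -> r*r*C_out, and the r*r factor is rearranged
    into space.
    """

    def __init__(self, channels: int, c_out: int, r: int,
                 rng: np.random.Generator, eps: float = 1e-5):
        super().__init__()
        self.r, self.c_out = r, c_out
        self.expand = nn.Linear(channels, r * r * c_out, rng, bias=False)
        self.norm = nn.LayerNorm(c_out, eps=eps)

    def forward(self, t: Tensor) -> Tensor:
        B, H, W, _ = t.shape
        r, co = self.r, self.c_out
        y = self.expand(t).reshape(B, H, W, r, r, co)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(B, H * r, W * r, co)
        return self.norm(y)


class DecoderHead(nn.Module):
    """State-space U-Net decoder over a 4-level pyramid with additive skips."""

    def __init__(self, cfg: VSSConfig, rng: np.random.Generator,
                 depths: tuple[int, int, int, int] = (2, 2, 2, 1),
                 num_classes: int = NUM_CLASSES):
        super().__init__()
        self.cfg = cfg
        c = cfg.embed_dim
        widths = [c, 2 * c, 4 * c, 8 * c]          # stage widths, fine -> coarse
        self.depths = tuple(depths)                # listed coarse -> fine
        blocks, expands = [], []
        for lvl in range(3, -1, -1):               # 3 = coarsest
            blocks.append(nn.Sequential(*[
                VSSBlock(widths[lvl], cfg, rng)
                for _ in range(self.depths[3 - lvl])]))
            if lvl > 0:
                expands.append(PatchExpand(widths[lvl], widths[lvl - 1], 2, rng,
                                           eps=cfg.norm_epsilon))
        self.blocks = nn.Sequential(*blocks)
        self.expands = nn.Sequential(*expands)
        self.final_expand = PatchExpand(c, c, 4, rng, eps=cfg.norm_epsilon)
        self.head = nn.Linear(c, num_classes, rng)

    def forward(self, pyramid_maps: list[Tensor],
                skip_transform=None) -> Tensor:
        """pyramid_maps: four (B,C_s,H_s,W_s) tensors, fine to coarse.

        `skip_transform(level, tensor)` is applied to encoder maps on levels
        2..0 before additive fusion (e.g. ECA attention); identity if None.
        """
        if len(pyramid_maps) != 4:
            missing = 4 - len(pyramid_maps)
            raise ValueError(f"pyramid incomplete: missing {missing} level(s)")
        t = pyramid_maps[3].transpose(0, 2, 3, 1)
        for i, lvl in enumerate(range(3, -1, -1)):
            if lvl < 3:
                skip = pyramid_maps[lvl]
                if skip_transform is not None:
                    skip = skip_transform(lvl, skip)
                t = t + skip.transpose(0, 2, 3, 1)
            t = self.blocks.mods[i](t)
            if lvl > 0:
                t = self.expands.mods[i](t)
        t = self.final_expand(t)
        return self.head(t).transpose(0, 3, 1, 2)   # (B, classes, H, W)


def decode_forward(pyramid: EncoderPyramid, module: DecoderHead,
                   eca_modules=None) -> np.ndarray:
    """Decode a pyramid into (num_classes, H, W) logits at input resolution."""
    maps = [_wrap(s) for s in pyramid]
    transform = None
    if eca_modules is not None:
        def transform(lvl, t):
            out, _, _ = eca_modules[lvl](t)
            return out
    logits = module(maps, skip_transform=transform)
    return np.asarray(logits.data[0])


def seg_loss(logits: Tensor | np.ndarray, labels: np.ndarray,
             dice_weight: float = 1.0) -> Tensor:
    """Cross-entropy + soft-Dice over (B, classes, H, W) logits.

    The Dice term is one minus the soft Dice coefficient, averaged over all
    classes with equal weight; a class absent from both prediction mass and
    labels contributes zero loss.
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(np.asarray(logits, dtype=np.float64))
    if logits.ndim == 3:
        logits = logits.reshape((1,) + logits.shape)
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[None]
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise ValueError(
            f"labels must lie in 0..{logits.shape[1] - 1}, "
            f"got range [{labels.min()},{labels.max()}]")
    if labels.shape != (logits.shape[0],) + logits.shape[2:]:
        raise ValueError("labels must align with logits spatially")
    B, K = logits.shape[0], logits.shape[1]
    onehot = np.eye(K)[labels].transpose(0, 3, 1, 2)   # (B, K, H, W)
    logp = logits.log_softmax(axis=1)
    ce = -(logp * onehot).sum(axis=1).mean()
    probs = logits.softmax(axis=1)
    inter = (probs * onehot).sum(axis=(0, 2, 3))
    sums = probs.sum(axis=(0, 2, 3)) + Tensor(onehot.sum(axis=(0, 2, 3)))
    eps = 1e-7
    dice = (inter * 2.0 + eps) / (sums + eps)
    dice_loss = 1.0 - dice.mean()
    return ce + dice_weight * dice_loss


def predict_labels(logits: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over class logits; ties break toward the lower index."""
    return np.argmax(logits, axis=-3).astype(np.int16)
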
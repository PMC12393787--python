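"""Training, prediction and reporting pipeline.

Training follows the reference protocol: AdamW (beta1 = 0.9, the usual
reading of 'momentum' for Adam-family optimizers), initial learning rate
1e-4, batch size 24, 100 epochs, cross-entropy + Dice loss on 2D slices.
Reduced configurations (smaller widths, fewer steps) are provided for
CPU-scale smoke runs on synthetic phantoms.  Prediction is slice-wise with
automatic pad-and-crop to the stride-32 grid; evaluation stacks slice
predictions back into volumes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import Tensor
from .types import ImageVolume, LabelMask, NUM_CLASSES
from .ssm import VSSConfig
from .mpsk import MPSKConfig
from .model import ModelConfig, SegmentationModel, build_variant
from .decoder import seg_loss, predict_labels
from .metrics import evaluate_cohort


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    optimizer: str = "adamw"
    lr: float = 1e-4
    momentum: float = 0.9          # beta1 of AdamW
    weight_decay: float = 0.01
    epochs: int = 100
    max_steps: int | None = None   # overrides epochs when set
    batch_size: int = 24
    dice_weight: float = 1.0
    seed: int = 0
    input_size: tuple[int, int] = (256, 256)

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be >= 1")


def smoke_config(seed: int = 0, max_steps: int = 200, lr: float = 1e-3) -> RunConfig:
    """Reduced configuration for CPU-scale training on 64x64 phantoms."""
    vss = VSSConfig(embed_dim=32, depths=(1, 1, 1, 1), state_dim=8,
                    expansion=1.0, mlp_ratio=1.0)
    mpsk = MPSKConfig(stage_channels=(32, 64, 128, 256),
                      blocks_per_stage=(1, 1, 1, 1), pool_levels=(1, 2, 3))
    model = ModelConfig(vss=vss, mpsk=mpsk, decoder_depths=(1, 1, 1, 1), seed=seed)
    return RunConfig(model=model, lr=lr, max_steps=max_steps, batch_size=8,
                     seed=seed, input_size=(64, 64))


@dataclass
class TrainLog:
    step_losses: list[float] = field(default_factory=list)
    epoch_val_dsc: list[float] = field(default_factory=list)
    best_val_dsc: float = -1.0
    wall_seconds: float = 0.0


def _slices_of(cohort) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for vol, mask in cohort:
        for s in range(vol.intensities.shape[0]):
            xs.append(vol.intensities[s])
            ys.append(mask.labels[s])
    return np.stack(xs), np.stack(ys)


def train_model(cfg: RunConfig, cohort, val_cohort=None,
                checkpoint_path=None) -> tuple[SegmentationModel, TrainLog]:
    """Train on (ImageVolume, LabelMask) pairs; returns model + loss log.

    The returned model carries the best-validation-DSC weights when a
    validation cohort is given, otherwise the final weights.
    """
    if not cohort:
        raise ValueError("training cohort is empty")
    if cfg.optimizer.lower() != "adamw":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    xs, ys = _slices_of(cohort)
    model = build_variant(cfg.model)
    opt = nn.AdamW(model.parameters(), lr=cfg.lr,
                   betas=(cfg.momentum, 0.999), weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n = xs.shape[0]
    steps_per_epoch = max(n // cfg.batch_size, 1)
    total_steps = (cfg.max_steps if cfg.max_steps is not None
                   else cfg.epochs * steps_per_epoch)
    log = TrainLog()
    best_state = None
    t0 = time.time()
    model.train()
    for step in range(total_steps):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        xb = Tensor(xs[idx][:, None].astype(np.float32))
        yb = ys[idx]
        logits = model(xb)
        loss = seg_loss(logits, yb, dice_weight=cfg.dice_weight)
        lval = float(loss.data)
        if not np.isfinite(lval):
            raise RuntimeError(
                f"training diverged at step {step + 1}: loss = {lval}")
        log.step_losses.append(lval)
        opt.zero_grad()
        loss.backward()
        opt.step()
        end_of_epoch = (step + 1) % steps_per_epoch == 0 or step + 1 == total_steps
        if val_cohort and end_of_epoch:
            dsc = mean_foreground_dsc(model, val_cohort)
            log.epoch_val_dsc.append(dsc)
            if dsc > log.best_val_dsc:
                log.best_val_dsc = dsc
                best_state = model.state_dict()
            model.train()
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    log.wall_seconds = time.time() - t0
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model)
    return model, log


def save_checkpoint(path, model: SegmentationModel) -> None:
    np.savez(path, **model.state_dict())


def load_checkpoint(path, cfg: ModelConfig) -> SegmentationModel:
    model = build_variant(cfg)
    with np.load(str(path)) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model.eval()


def _pad_to_grid(x: np.ndarray, grid: int = 32):
    h, w = x.shape
    ph, pw = (-h) % grid, (-w) % grid
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw)), mode="edge")
    return x, (h, w)


def predict_volume(model: SegmentationModel, volume: ImageVolume) -> LabelMask:
    """Slice-wise argmax prediction stacked into a 3D mask."""
    model.eval()
    out = []
    for s in range(volume.intensities.shape[0]):
        padded, (h, w) = _pad_to_grid(volume.intensities[s])
        labels = model.predict_slice(padded)
        out.append(labels[:h, :w])
    return LabelMask(np.stack(out).astype(np.int16), spacing=volume.spacing,
                     identifier=volume.identifier)


def mean_foreground_dsc(model: SegmentationModel, cohort) -> float:
    """Mean DSC over the four foreground tissues across a cohort."""
    preds = [predict_volume(model, vol) for vol, _ in cohort]
    gts = [mask for _, mask in cohort]
    report = evaluate_cohort(preds, gts)
    return float(report.per_volume["dice"].mean())
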
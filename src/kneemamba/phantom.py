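"""Synthetic knee phantoms: paired intensity volumes and 5-class label maps.

Each slice contains two ellipse-like bone blobs (femur above, tibia below)
facing each other across a joint gap, with a thin cartilage rim on the
joint-facing side of each bone — femoral cartilage hugging the femur,
tibial cartilage hugging the tibia.  Cartilage rims are 1-3 px bands grown
from the bone boundary toward the gap, so the two cartilage classes stay
heavily under-represented (< 5% of pixels each), mimicking the strong class
imbalance of knee MRI.  Intensities are per-class base levels modulated by
a smooth multiplicative bias field plus additive Gaussian noise; all
randomness (pose jitter, thickness, bias, noise) derives from the spec seed,
so a phantom is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ImageVolume, LabelMask

#: noise-free intensity level per class {bg, femur, tibia, FC, TC}
BASE_LEVELS = (0.10, 0.85, 0.65, 0.45, 0.30)


@dataclass
class PhantomSpec:
    size: tuple[int, int, int] = (64, 64, 4)       # (H, W, slices)
    spacing: tuple[float, float, float] = (1.5, 0.5, 0.5)  # (slice, row, col) mm
    bone_axes: tuple[float, float] = (0.30, 0.38)  # ellipse semi-axes, fraction of H/W
    pose_jitter: float = 0.03                      # centre jitter, fraction of size
    rim_thickness: tuple[int, int] = (2, 3)        # cartilage band, px (inclusive)
    noise_sd: float = 0.05
    bias_amplitude: float = 0.10                   # multiplicative, +/- fraction
    seed: int = 0

    def __post_init__(self):
        h, w, s = self.size
        if h < 64 or w < 64:
            raise ValueError("phantom slices must be at least 64x64")
        if s < 1:
            raise ValueError("need at least one slice")
        if self.rim_thickness[0] < 1 or self.rim_thickness[1] < self.rim_thickness[0]:
            raise ValueError("rim thickness range must be >= 1 px and ordered")


def _ellipse_mask(h, w, cy, cx, ay, ax_):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax_) ** 2 <= 1.0


def _smooth_field(rng, h, w, amplitude):
    """Low-frequency multiplicative bias in [1-a, 1+a]."""
    coarse = rng.standard_normal((4, 4))
    field = ndimage.zoom(coarse, (h / 4, w / 4), order=3)
    field = field[:h, :w]
    span = np.abs(field).max() or 1.0
    return 1.0 + amplitude * field / span


def _slice_labels(rng, h, w, spec: PhantomSpec) -> np.ndarray:
    jit = spec.pose_jitter
    fy = (0.27 + jit * rng.uniform(-1, 1)) * h
    fx = (0.50 + jit * rng.uniform(-1, 1)) * w
    ty = (0.76 + jit * rng.uniform(-1, 1)) * h
    tx = (0.50 + jit * rng.uniform(-1, 1)) * w
    ay = spec.bone_axes[0] * h * rng.uniform(0.9, 1.05)
    ax_ = spec.bone_axes[1] * w * rng.uniform(0.9, 1.05)
    femur = _ellipse_mask(h, w, fy, fx, ay * 0.75, ax_)
    tibia = _ellipse_mask(h, w, ty, tx, ay * 0.75, ax_)
    overlap = femur & tibia
    femur &= ~overlap
    tibia &= ~overlap
    labels = np.zeros((h, w), dtype=np.int16)
    labels[femur] = 1
    labels[tibia] = 2
    t_fc = int(rng.integers(spec.rim_thickness[0], spec.rim_thickness[1] + 1))
    t_tc = int(rng.integers(spec.rim_thickness[0], spec.rim_thickness[1] + 1))
    # cartilage: Chebyshev band around each bone, restricted to the gap side
    yy = np.mgrid[0:h, 0:w][0]
    d_femur = ndimage.distance_transform_cdt(~femur, metric="chessboard")
    d_tibia = ndimage.distance_transform_cdt(~tibia, metric="chessboard")
    mid = (fy + ty) / 2.0
    fc = (d_femur >= 1) & (d_femur <= t_fc) & (labels == 0) & (yy > fy) & (yy < mid + t_fc)
    labels[fc] = 3
    tc = (d_tibia >= 1) & (d_tibia <= t_tc) & (labels == 0) & (yy < ty) & (yy > mid - t_tc)
    labels[tc] = 4
    return labels


def generate_phantom_volume(spec: PhantomSpec) -> tuple[ImageVolume, LabelMask]:
    """Deterministic phantom: labels contain all 5 classes; cartilage < 5%."""
    h, w, n_slices = spec.size
    rng = np.random.default_rng(spec.seed)
    labels = np.empty((n_slices, h, w), dtype=np.int16)
    image = np.empty((n_slices, h, w), dtype=np.float64)
    levels = np.asarray(BASE_LEVELS)
    for s in range(n_slices):
        lab = _slice_labels(rng, h, w, spec)
        if len(np.unique(lab)) < 5:
            raise ValueError(
                "phantom geometry too small to fit all five classes; "
                "increase size or reduce jitter")
        base = levels[lab]
        bias = (_smooth_field(rng, h, w, spec.bias_amplitude)
                if spec.bias_amplitude > 0 else np.ones((h, w)))
        noise = (spec.noise_sd * rng.standard_normal((h, w))
                 if spec.noise_sd > 0 else 0.0)
        labels[s] = lab
        image[s] = base * bias + noise
    ident = f"phantom-{spec.seed:06d}"
    vol = ImageVolume(image, spacing=spec.spacing, identifier=ident)
    mask = LabelMask(labels, spacing=spec.spacing, identifier=ident)
    return vol, mask


def generate_cohort(n: int, base_spec: PhantomSpec | None = None,
                    seed: int = 0) -> list[tuple[ImageVolume, LabelMask]]:
    """n reproducible phantoms with pseudo-KL strata assigned round-robin."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec()
    root = np.random.default_rng(seed)
    item_seeds = root.integers(0, 2 ** 31 - 1, size=n)
    out = []
    for i in range(n):
        spec = PhantomSpec(size=base_spec.size, spacing=base_spec.spacing,
                           bone_axes=base_spec.bone_axes,
                           pose_jitter=base_spec.pose_jitter,
                           rim_thickness=base_spec.rim_thickness,
                           noise_sd=base_spec.noise_sd,
                           bias_amplitude=base_spec.bias_amplitude,
                           seed=int(item_seeds[i]))
        vol, mask = generate_phantom_volume(spec)
        vol.identifier = mask.identifier = f"phantom-{i:04d}"
        vol.stratum = i % 5        # pseudo Kellgren-Lawrence grade
        out.append((vol, mask))
    return out


def oracle_segment(volume: ImageVolume) -> LabelMask:
    """Threshold segmenter at the midpoints of the noise-free class levels.

    On a noise-free, bias-free phantom this reproduces the labels exactly —
    the sanity anchor for the metrics stack.
    """
    order = np.argsort(BASE_LEVELS)              # class ids sorted by level
    levels = np.asarray(BASE_LEVELS)[order]
    edges = (levels[:-1] + levels[1:]) / 2.0
    bins = np.digitize(volume.intensities, edges)
    labels = np.asarray(order, dtype=np.int16)[bins]
    return LabelMask(labels, spacing=volume.spacing, identifier=volume.identifier)
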
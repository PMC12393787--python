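"""Shared domain containers: images, label maps and feature maps.

Segmentation targets use the fixed 5-class encoding
{0 background, 1 femur, 2 tibia, 3 femoral cartilage, 4 tibial cartilage}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NUM_CLASSES = 5
CLASS_NAMES = ("background", "femur", "tibia",
               "femoral_cartilage", "tibial_cartilage")
#: short clinical labels for the four foreground tissues
TISSUE_ABBREV = {1: "FB", 2: "TB", 3: "FC", 4: "TC"}


@dataclass
class FeatureMap:
    """A C-channel spatial feature array at a given stride vs the input image."""

    values: np.ndarray  # (C, H, W)
    stride: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"FeatureMap expects (C,H,W), got shape {self.values.shape}")
        if min(self.values.shape) < 1:
            raise ValueError("FeatureMap dimensions must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap values must be finite")

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def spatial(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


@dataclass
class ImageVolume:
    """Real-valued intensities with physical voxel spacing in mm.

    ``intensities`` is (slices, H, W); a single 2D slice may be passed and is
    promoted to a 1-slice volume.  ``stratum`` carries the Kellgren-Lawrence
    osteoarthritis grade (0-4) used for stratified splitting when known.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    identifier: str = ""
    stratum: int | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim == 2:
            self.intensities = self.intensities[None]
        if self.intensities.ndim != 3:
            raise ValueError("ImageVolume expects a 2D slice or 3D volume")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("ImageVolume intensities must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self):
        return self.intensities.shape


@dataclass
class LabelMask:
    """Integer class map aligned with an ImageVolume; values in {0..4}."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    identifier: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim == 2:
            self.labels = self.labels[None]
        if self.labels.ndim != 3:
            raise ValueError("LabelMask expects a 2D slice or 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("LabelMask requires integer labels")
            self.labels = self.labels.astype(np.int16)
        lo, hi = int(self.labels.min()), int(self.labels.max())
        if lo < 0 or hi >= NUM_CLASSES:
            raise ValueError(f"labels must lie in 0..{NUM_CLASSES - 1}, got range [{lo},{hi}]")

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class EncoderPyramid:
    """The four fused encoder feature maps F1..F4 at strides 4/8/16/32."""

    stages: tuple[FeatureMap, FeatureMap, FeatureMap, FeatureMap]

    def __post_init__(self):
        strides = tuple(s.stride for s in self.stages)
        if strides != (4, 8, 16, 32):
            raise ValueError(f"pyramid strides must be (4,8,16,32), got {strides}")
        c = self.stages[0].channels
        chans = tuple(s.channels for s in self.stages)
        if chans != (c, 2 * c, 4 * c, 8 * c):
            raise ValueError(f"pyramid channels must double per stage, got {chans}")

    def __iter__(self):
        return iter(self.stages)

    def __getitem__(self, i):
        return self.stages[i]
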
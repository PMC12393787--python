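"""Preprocessing, volume I/O and cohort splitting.

Slices are contrast-enhanced with CLAHE (contrast-limited adaptive histogram
equalization, applied per slice on intensities rescaled to [0,1]), then each
volume is Z-score standardised.  Cohorts are split 7:2:1 into
train/validation/test stratified by Kellgren-Lawrence grade using
largest-remainder rounding per stratum, with stratified five-fold
cross-validation partitions inside the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from skimage import exposure

from .types import ImageVolume, LabelMask


@dataclass
class SplitPlan:
    train: list[str]
    val: list[str]
    test: list[str]
    cv_folds: list[list[str]]
    seed: int = 42

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("train/val/test sets must be disjoint")
        fold_union = set().union(*map(set, self.cv_folds)) if self.cv_folds else set()
        if self.cv_folds and fold_union != set(self.train):
            raise ValueError("cv folds must partition the training set")


def clahe_enhance(slice_2d: np.ndarray, clip_limit: float = 0.02,
                  tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """CLAHE on one slice; intensities are rescaled to [0,1] before tiling.

    `clip_limit` follows scikit-image's normalized convention (fraction of
    the tile histogram); `tiles` is the adaptive grid, so the kernel size is
    image_size / tiles per axis.
    """
    x = np.asarray(slice_2d, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("clahe_enhance expects a single 2D slice")
    h, w = x.shape
    if tiles[0] > h or tiles[1] > w:
        raise ValueError(f"tile grid {tiles} larger than image {x.shape}")
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0:
        return np.zeros_like(x)
    x01 = (x - lo) / (hi - lo)
    kernel = (max(h // tiles[0], 1), max(w // tiles[1], 1))
    return exposure.equalize_adapthist(x01, kernel_size=kernel,
                                       clip_limit=clip_limit)


def zscore_normalize(volume: ImageVolume) -> ImageVolume:
    """Standardise a volume to mean 0, population SD 1 (constant -> zeros)."""
    x = volume.intensities
    sd = x.std()
    if sd == 0:
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd
    return ImageVolume(z, spacing=volume.spacing, identifier=volume.identifier,
                       stratum=volume.stratum)


def preprocess_volume(volume: ImageVolume, clip_limit: float = 0.02,
                      tiles: tuple[int, int] = (8, 8)) -> ImageVolume:
    """CLAHE per slice, then per-volume Z-score."""
    enhanced = np.stack([clahe_enhance(s, clip_limit, tiles)
                         for s in volume.intensities])
    return zscore_normalize(ImageVolume(enhanced, spacing=volume.spacing,
                                        identifier=volume.identifier,
                                        stratum=volume.stratum))


def _largest_remainder(n: int, weights: np.ndarray) -> np.ndarray:
    """Allocate n items to bins proportionally, exactly summing to n."""
    quotas = n * weights / weights.sum()
    alloc = np.floor(quotas).astype(int)
    rem = quotas - alloc
    for i in np.argsort(-rem, kind="stable")[: n - alloc.sum()]:
        alloc[i] += 1
    return alloc


def stratified_split_cv(cohort: list[ImageVolume], ratios=(7, 2, 1),
                        folds: int = 5, seed: int = 42) -> SplitPlan:
    """7:2:1 stratified split + stratified K folds inside the training set."""
    strata: dict[int, list[str]] = {}
    for v in cohort:
        if v.stratum is None:
            raise ValueError(f"volume {v.identifier!r} has no stratum")
        strata.setdefault(int(v.stratum), []).append(v.identifier)
    rng = np.random.default_rng(seed)
    weights = np.asarray(ratios, dtype=np.float64)
    train, val, test = [], [], []
    fold_lists: list[list[str]] = [[] for _ in range(folds)]
    fold_cursor = 0
    for grade in sorted(strata):
        ids = sorted(strata[grade])
        rng.shuffle(ids)
        n = len(ids)
        n_train, n_val, n_test = _largest_remainder(n, weights)
        tr = ids[:n_train]
        val.extend(ids[n_train:n_train + n_val])
        test.extend(ids[n_train + n_val:])
        train.extend(tr)
        if len(tr) < folds:
            import warnings
            warnings.warn(
                f"stratum {grade} has {len(tr)} training items for {folds} folds;"
                " assigning best-effort", stacklevel=2)
        for ident in tr:
            fold_lists[fold_cursor % folds].append(ident)
            fold_cursor += 1
    return SplitPlan(train=train, val=val, test=test, cv_folds=fold_lists,
                     seed=seed)


# -- NIfTI I/O ---------------------------------------------------------------

def save_volume(path, volume: ImageVolume) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), affine),
             str(path))


def load_volume(path, identifier: str = "", stratum: int | None = None) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64),
                       spacing=spacing, identifier=identifier, stratum=stratum)


def save_labels(path, mask: LabelMask) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), affine), str(path))


def load_labels(path, identifier: str = "") -> LabelMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMask(np.asarray(img.dataobj).astype(np.int16),
                     spacing=spacing, identifier=identifier)
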
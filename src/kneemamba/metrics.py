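"""Segmentation evaluation: Dice, exact Hausdorff distance, paired statistics.

Per class, DSC = 2TP / (2TP + FP + FN).  The Hausdorff distance is the exact
symmetric maximum H(A,B) = max(h(A,B), h(B,A)) with h(A,B) = max_a min_b
||a - b||, computed in physical millimetres between boundary voxel sets (a
labelled voxel is boundary if any face-adjacent voxel has a different label
or lies outside the image).  Cohort evaluation aggregates per-volume,
per-class scores as mean +/- sample standard deviation, and model
comparisons use the classic paired t-test with a 95% confidence interval on
the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .types import LabelMask, NUM_CLASSES, TISSUE_ABBREV


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def dice(self) -> float:
        denom = 2 * self.TP + self.FP + self.FN
        return 1.0 if denom == 0 else 2.0 * self.TP / denom


@dataclass
class BoundaryPointSet:
    """Boundary voxel coordinates in physical mm (index * spacing)."""

    points: np.ndarray          # (n, d)
    source_class: int = 0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))

    def __len__(self):
        return 0 if self.points.size == 0 else self.points.shape[0]


@dataclass
class PairedStatResult:
    mean_diff: float
    t_statistic: float
    df: int
    p_value: float
    ci95_low: float
    ci95_high: float
    degenerate: bool = False


class DegenerateStatError(ValueError):
    """Raised when the paired differences have zero variance."""


def confusion_counts(pred: LabelMask | np.ndarray, gt: LabelMask | np.ndarray,
                     cls: int) -> ConfusionCounts:
    p = pred.labels if isinstance(pred, LabelMask) else np.asarray(pred)
    g = gt.labels if isinstance(gt, LabelMask) else np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    if not 0 <= cls < NUM_CLASSES:
        raise ValueError(f"class {cls} outside 0..{NUM_CLASSES - 1}")
    pm, gm = p == cls, g == cls
    return ConfusionCounts(TP=int(np.sum(pm & gm)),
                           FP=int(np.sum(pm & ~gm)),
                           FN=int(np.sum(~pm & gm)))


def dice_score(pred, gt, cls: int) -> float:
    """DSC in [0,1]; defined as 1.0 when the class is absent from both."""
    return confusion_counts(pred, gt, cls).dice


def extract_boundary(labels: np.ndarray, cls: int,
                     spacing=(1.0, 1.0, 1.0)) -> BoundaryPointSet:
    """Boundary voxels of `cls`: face-adjacent to another label or the border."""
    arr = labels.labels if isinstance(labels, LabelMask) else np.asarray(labels)
    if arr.ndim == 2:
        arr = arr[None]
    mask = arr == cls
    if not mask.any():
        return BoundaryPointSet(np.empty((0, 3)), source_class=cls)
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0)
    boundary = mask & ~interior
    idx = np.argwhere(boundary).astype(np.float64)
    return BoundaryPointSet(idx * np.asarray(spacing, dtype=np.float64),
                            source_class=cls)


def directed_hausdorff_mm(A: BoundaryPointSet, B: BoundaryPointSet) -> float:
    """h(A,B) = max over a of the distance to the nearest b."""
    if len(A) == 0 or len(B) == 0:
        raise ValueError("directed Hausdorff needs nonempty point sets")
    d, _ = cKDTree(B.points).query(A.points, k=1)
    return float(np.max(d))


def hausdorff_distance(A: BoundaryPointSet, B: BoundaryPointSet) -> float:
    """Exact symmetric Hausdorff distance H(A,B) in mm."""
    return max(directed_hausdorff_mm(A, B), directed_hausdorff_mm(B, A))


def paired_t_ci(x, y, alpha: float = 0.05) -> PairedStatResult:
    """Classic paired t-test on d = x - y with a (1-alpha) CI on mean(d)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired test needs two equal-length vectors")
    n = x.size
    if n < 2:
        raise ValueError("paired test needs n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        raise DegenerateStatError(
            "zero variance of paired differences; t statistic undefined")
    se = sd / np.sqrt(n)
    t_stat = mean / se
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    tq = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return PairedStatResult(mean_diff=mean, t_statistic=float(t_stat), df=df,
                            p_value=p, ci95_low=mean - tq * se,
                            ci95_high=mean + tq * se)


def _bbox_diagonal_mm(shape, spacing) -> float:
    ext = (np.asarray(shape, dtype=np.float64) - 1) * np.asarray(spacing)
    return float(np.sqrt(np.sum(ext ** 2)))


def volume_scores(pred: LabelMask, gt: LabelMask,
                  classes=range(1, NUM_CLASSES)) -> dict[int, dict]:
    """Per-class DSC and HD (mm) for one prediction/ground-truth volume pair."""
    if pred.labels.shape != gt.labels.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.labels.shape} vs gt {gt.labels.shape}")
    spacing = gt.spacing
    out = {}
    for cls in classes:
        dsc = dice_score(pred, gt, cls)
        bp = extract_boundary(pred, cls, spacing)
        bg = extract_boundary(gt, cls, spacing)
        flagged = False
        if len(bp) == 0 and len(bg) == 0:
            hd = 0.0
        elif len(bp) == 0 or len(bg) == 0:
            # missing structure: worst-case boundary error, flagged
            hd = _bbox_diagonal_mm(gt.labels.shape, spacing)
            flagged = True
        else:
            hd = hausdorff_distance(bp, bg)
        out[cls] = {"dice": dsc, "hd_mm": hd, "missing_structure": flagged}
    return out


@dataclass
class EvalReport:
    """Cohort-level per-tissue summary with optional paired comparisons."""

    per_volume: pd.DataFrame          # columns: volume, class, tissue, dice, hd_mm
    summary: pd.DataFrame             # per tissue: mean/std of dice and hd

    def tissue_mean(self, metric: str = "dice") -> dict[str, float]:
        return dict(zip(self.summary["tissue"], self.summary[f"{metric}_mean"]))


def evaluate_cohort(preds: list[LabelMask], gts: list[LabelMask]) -> EvalReport:
    """Per-volume, per-tissue DSC and HD, aggregated as mean +/- sample SD."""
    if len(preds) != len(gts):
        raise ValueError(f"{len(preds)} predictions vs {len(gts)} ground truths")
    rows = []
    for i, (p, g) in enumerate(zip(preds, gts)):
        ident = g.identifier or str(i)
        for cls, sc in volume_scores(p, g).items():
            rows.append({"volume": ident, "class": cls,
                         "tissue": TISSUE_ABBREV[cls], "dice": sc["dice"],
                         "hd_mm": sc["hd_mm"],
                         "missing_structure": sc["missing_structure"]})
    per_volume = pd.DataFrame(rows)
    summary = (per_volume.groupby(["class", "tissue"], as_index=False)
               .agg(dice_mean=("dice", "mean"), dice_std=("dice", lambda s: s.std(ddof=1)),
                    hd_mean=("hd_mm", "mean"), hd_std=("hd_mm", lambda s: s.std(ddof=1)),
                    n=("dice", "size")))
    return EvalReport(per_volume=per_volume, summary=summary)


def compare_models(report_a: EvalReport, report_b: EvalReport,
                   metric: str = "dice") -> pd.DataFrame:
    """Paired t-test per tissue between two cohort reports on the same volumes."""
    rows = []
    for cls in sorted(report_a.per_volume["class"].unique()):
        a = report_a.per_volume.query("`class` == @cls").sort_values("volume")
        b = report_b.per_volume.query("`class` == @cls").sort_values("volume")
        if not (a["volume"].values == b["volume"].values).all():
            raise ValueError("paired comparison requires identical volume sets")
        try:
            r = paired_t_ci(a[metric].values, b[metric].values)
            rows.append({"class": cls, "tissue": TISSUE_ABBREV[cls],
                         "mean_diff": r.mean_diff, "t": r.t_statistic,
                         "df": r.df, "p_value": r.p_value,
                         "ci95_low": r.ci95_low, "ci95_high": r.ci95_high})
        except DegenerateStatError:
            rows.append({"class": cls, "tissue": TISSUE_ABBREV[cls],
                         "mean_diff": float(np.mean(a[metric].values - b[metric].values)),
                         "t": np.nan, "df": len(a) - 1, "p_value": np.nan,
                         "ci95_low": np.nan, "ci95_high": np.nan})
    return pd.DataFrame(rows)
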
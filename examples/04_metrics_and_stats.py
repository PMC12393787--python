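"""Segmentation metrics and the paired statistical harness.

Dice = 2TP/(2TP+FP+FN) measures region overlap; the exact symmetric
Hausdorff distance (in mm) measures the worst boundary error.  Paired
t-tests with 95% confidence intervals compare two models evaluated on the
same volumes.
"""

import numpy as np

import kneemamba as km
from kneemamba.metrics import BoundaryPointSet
from kneemamba.types import LabelMask

# 4-pixel prediction overlapping 3 of 6 ground-truth pixels -> DSC 0.6
pred = np.zeros((4, 4), dtype=int)
gt = np.zeros((4, 4), dtype=int)
pred[0, :4] = 1
gt[0, 1:4] = 1
gt[1, :3] = 1
print("worked Dice example:", km.dice_score(LabelMask(pred), LabelMask(gt), 1))

a = BoundaryPointSet([[0.0, 0.0]])
b = BoundaryPointSet([[3.0, 4.0]])
print("Hausdorff of a 3-4-5 offset:", km.hausdorff_distance(a, b), "mm")

# paired comparison of two per-volume score vectors (differences 1, 2, 3)
r = km.paired_t_ci([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
print(f"paired t: t={r.t_statistic:.4f}, df={r.df}, p={r.p_value:.4f}, "
      f"CI95=[{r.ci95_low:.4f}, {r.ci95_high:.4f}]")
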
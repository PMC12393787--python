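"""Preprocess a phantom cohort and build the stratified split.

Slices go through CLAHE (local contrast enhancement) and each volume is
Z-score standardised; the cohort is then split 7:2:1 by pseudo
osteoarthritis grade with five cross-validation folds inside the training
set.  The printed allocation shows each grade contributing proportionally.
"""

import numpy as np

import kneemamba as km

cohort = km.generate_cohort(30, km.PhantomSpec(size=(64, 64, 2)), seed=5)
volumes = []
for vol, _ in cohort:
    pre = km.preprocess_volume(vol)
    volumes.append(pre)
print(f"after preprocessing: mean {volumes[0].intensities.mean():+.2e}, "
      f"sd {volumes[0].intensities.std():.4f} (Z-scored per volume)")

plan = km.stratified_split_cv(volumes, seed=42)
print(f"train/val/test sizes: {len(plan.train)}/{len(plan.val)}/{len(plan.test)}")
print("fold sizes:", [len(f) for f in plan.cv_folds])
strata = {v.identifier: v.stratum for v in volumes}
for grade in range(5):
    n = sum(1 for x in plan.train if strata[x] == grade)
    print(f"  grade {grade}: {n} training volumes")
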
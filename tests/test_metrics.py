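"""Dice, Hausdorff and paired statistics against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import kneemamba as km
from kneemamba.metrics import (BoundaryPointSet, DegenerateStatError,
                               extract_boundary, volume_scores)
from kneemamba.types import LabelMask


def brute_dice(pred, gt, cls):
    tp = fp = fn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p == cls and g == cls:
            tp += 1
        elif p == cls:
            fp += 1
        elif g == cls:
            fn += 1
    return 1.0 if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)


def brute_hausdorff(A, B):
    def directed(P, Q):
        return max(min(np.linalg.norm(p - q) for q in Q) for p in P)
    return max(directed(A, B), directed(B, A))


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((6, 6), dtype=int)
        m[:2, :5] = 1
        assert km.dice_score(LabelMask(m), LabelMask(m.copy()), 1) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6), dtype=int)
        b = np.zeros((6, 6), dtype=int)
        a[0, :3] = 1
        b[5, :3] = 1
        assert km.dice_score(LabelMask(a), LabelMask(b), 1) == 0.0

    def test_worked_overlap_example(self):
        # pred 4 px, gt 6 px, overlap 3 -> 2*3/(2*3+1+3) = 0.6
        pred = np.zeros((4, 4), dtype=int)
        gt = np.zeros((4, 4), dtype=int)
        pred[0, 0:4] = 1                      # 4 pixels
        gt[0, 1:4] = 1                        # overlap 3
        gt[1, 0:3] = 1                        # 3 more gt-only
        assert km.dice_score(LabelMask(pred), LabelMask(gt), 1) == pytest.approx(0.6)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(100):
            p = rng.integers(0, 5, size=(12, 12))
            g = rng.integers(0, 5, size=(12, 12))
            cls = int(rng.integers(0, 5))
            assert km.dice_score(LabelMask(p), LabelMask(g), cls) == \
                brute_dice(p, g, cls)

    def test_symmetry_and_invalid_class(self, rng):
        p = rng.integers(0, 3, size=(8, 8))
        g = rng.integers(0, 3, size=(8, 8))
        assert km.dice_score(LabelMask(p), LabelMask(g), 2) == \
            km.dice_score(LabelMask(g), LabelMask(p), 2)
        with pytest.raises(ValueError):
            km.dice_score(LabelMask(p), LabelMask(g), 9)


class TestHausdorff:
    def test_equal_sets_zero(self):
        a = BoundaryPointSet(np.array([[0.0, 0.0], [1.0, 2.0]]))
        assert km.hausdorff_distance(a, a) == 0.0

    def test_three_four_five(self):
        a = BoundaryPointSet(np.array([[0.0, 0.0]]))
        b = BoundaryPointSet(np.array([[3.0, 4.0]]))
        assert km.hausdorff_distance(a, b) == pytest.approx(5.0)

    def test_asymmetric_directed_distances(self):
        a = BoundaryPointSet(np.array([[0.0, 0.0], [10.0, 0.0]]))
        b = BoundaryPointSet(np.array([[0.0, 0.0]]))
        assert km.directed_hausdorff_mm(a, b) == pytest.approx(10.0)
        assert km.directed_hausdorff_mm(b, a) == pytest.approx(0.0)
        assert km.hausdorff_distance(a, b) == pytest.approx(10.0)

    def test_matches_all_pairs_brute_force(self, rng):
        for _ in range(100):
            a = rng.normal(size=(10, 3)) * 5
            b = rng.normal(size=(10, 3)) * 5
            got = km.hausdorff_distance(BoundaryPointSet(a), BoundaryPointSet(b))
            assert got == pytest.approx(brute_hausdorff(a, b), abs=1e-9)

    def test_adding_points_cannot_increase_directed_distance(self, rng):
        a = BoundaryPointSet(rng.normal(size=(8, 2)))
        b_small = rng.normal(size=(4, 2))
        b_large = np.vstack([b_small, rng.normal(size=(4, 2))])
        assert km.directed_hausdorff_mm(a, BoundaryPointSet(b_large)) <= \
            km.directed_hausdorff_mm(a, BoundaryPointSet(b_small)) + 1e-12

    def test_empty_set_raises(self):
        a = BoundaryPointSet(np.empty((0, 3)))
        b = BoundaryPointSet(np.array([[0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="nonempty"):
            km.hausdorff_distance(a, b)


class TestBoundaryExtraction:
    def test_interior_voxels_excluded(self):
        lab = np.zeros((1, 7, 7), dtype=int)
        lab[0, 1:6, 1:6] = 1
        pts = extract_boundary(lab, 1).points
        # 5x5 square: boundary ring has 25 - 9 = 16 voxels (single slice ->
        # all are boundary in z, but the ring counts in-plane faces too)
        assert len(pts) == 25  # single-slice: every voxel touches a z-face
        lab3 = np.stack([lab[0]] * 5)
        pts3 = extract_boundary(lab3, 1).points
        inner = [p for p in pts3 if p[0] == 2]
        assert len(inner) == 16  # middle slice keeps only the in-plane ring

    def test_spacing_scales_coordinates(self):
        lab = np.zeros((1, 4, 4), dtype=int)
        lab[0, 2, 3] = 1
        pts = extract_boundary(lab, 1, spacing=(0.7, 0.5, 0.25)).points
        np.testing.assert_allclose(pts, [[0.0, 1.0, 0.75]])


class TestPairedT:
    def test_worked_example(self):
        # d = [1,2,3]: t = 2/(1/sqrt(3)), df 2, p ~ 0.0742, CI ~ [-0.484, 4.484]
        r = km.paired_t_ci([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert r.mean_diff == pytest.approx(2.0)
        assert r.t_statistic == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-4)
        assert r.df == 2
        assert r.p_value == pytest.approx(0.0742, abs=1e-3)
        assert r.ci95_low == pytest.approx(-0.4844, abs=1e-3)
        assert r.ci95_high == pytest.approx(4.4844, abs=1e-3)

    def test_degenerate_zero_variance_signals(self):
        x = [1.0, 2.0, 3.0]
        with pytest.raises(DegenerateStatError):
            km.paired_t_ci(x, x)

    def test_sign_flip_symmetry(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        a = km.paired_t_ci(x, y)
        b = km.paired_t_ci(y, x)
        assert a.t_statistic == pytest.approx(-b.t_statistic)
        assert a.mean_diff == pytest.approx(-b.mean_diff)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_scipy_ttest_rel(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15) + 0.3
        mine = km.paired_t_ci(x, y)
        ref = stats.ttest_rel(x, y)
        assert mine.t_statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    @pytest.mark.parametrize("df,quantile", [(2, 4.303), (5, 2.571), (10, 2.228)])
    def test_ci_width_reproduces_t_quantiles(self, df, quantile, rng):
        x = rng.normal(size=df + 1)
        y = rng.normal(size=df + 1)
        r = km.paired_t_ci(x, y)
        d = x - y
        se = d.std(ddof=1) / np.sqrt(d.size)
        implied = (r.ci95_high - r.mean_diff) / se
        assert implied == pytest.approx(quantile, abs=1e-3)


class TestEvaluateCohort:
    def _mask(self, arr, spacing=(1.0, 1.0, 1.0), ident=""):
        return LabelMask(arr, spacing=spacing, identifier=ident)

    def test_mean_and_sample_sd_aggregation(self):
        # construct volumes whose class-1 dice are 0.9, 0.8, 1.0
        gts, preds = [], []
        pairs = [(9, 10), (8, 12), (10, 10)]  # overlap/edits chosen per dice
        dices = []
        rng = np.random.default_rng(0)
        for i, _ in enumerate(pairs):
            g = np.zeros((1, 10, 10), dtype=int)
            g[0, :2, :] = 1   # 20 px of class 1
            p = g.copy()
            flip = {0: 2, 1: 4, 2: 0}[i]   # remove this many -> dice 2*(20-f)/(40-f)
            p[0, 0, :flip] = 0
            gts.append(self._mask(g, ident=f"v{i}"))
            preds.append(self._mask(p, ident=f"v{i}"))
            dices.append(2 * (20 - flip) / (40 - flip))
        rep = km.evaluate_cohort(preds, gts)
        got = rep.per_volume.query("`class` == 1")["dice"].values
        np.testing.assert_allclose(sorted(got), sorted(dices), atol=1e-12)
        row = rep.summary.query("`class` == 1").iloc[0]
        assert row["dice_mean"] == pytest.approx(np.mean(dices))
        assert row["dice_std"] == pytest.approx(np.std(dices, ddof=1))

    def test_perfect_predictions_give_dice1_hd0(self, phantom_pair):
        _, mask = phantom_pair
        rep = km.evaluate_cohort([mask], [mask])
        assert np.allclose(rep.per_volume["dice"], 1.0)
        assert np.allclose(rep.per_volume["hd_mm"], 0.0)

    def test_in_plane_voxel_offset_scales_with_spacing(self):
        g = np.zeros((1, 8, 8), dtype=int)
        p = np.zeros((1, 8, 8), dtype=int)
        g[0, 4, 4] = 1
        p[0, 4, 5] = 1   # one voxel offset along the 0.5 mm axis
        sp = (0.7, 0.5, 0.5)
        sc = volume_scores(self._mask(p, sp), self._mask(g, sp))
        assert sc[1]["hd_mm"] == pytest.approx(0.5)

    def test_missing_structure_flagged_with_bbox_diagonal(self):
        g = np.zeros((1, 10, 10), dtype=int)
        g[0, 2:4, 2:4] = 1
        p = np.zeros((1, 10, 10), dtype=int)
        sc = volume_scores(self._mask(p), self._mask(g))
        assert sc[1]["missing_structure"]
        assert sc[1]["dice"] == 0.0
        assert sc[1]["hd_mm"] == pytest.approx(np.sqrt(2 * 9.0 ** 2))
        # absent from both prediction and reference: perfect by convention
        assert sc[2]["dice"] == 1.0 and sc[2]["hd_mm"] == 0.0

    def test_length_mismatch_raises(self):
        m = self._mask(np.zeros((1, 4, 4), dtype=int))
        with pytest.raises(ValueError):
            km.evaluate_cohort([m], [m, m])
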
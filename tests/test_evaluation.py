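import numpy as np
import pytest

from m3mc.evaluation import (
    cls_metrics,
    hausdorff,
    pr_curve_ap,
    roc_auc,
    seg_metrics,
    slice_profile,
)
from m3mc.volume_io import MultiClassMask


def mask_from_points(points, label, shape=(6, 6, 6)):
    labels = np.zeros(shape, dtype=int)
    for p in points:
        labels[tuple(p)] = label
    return MultiClassMask(labels)


class TestSegMetrics:
    def test_identity(self):
        m = mask_from_points([(1, 1, 1), (2, 2, 2)], 1)
        out = seg_metrics(m, m, 1)
        assert (out.dsc, out.iou, out.voe, out.rvd) == (1.0, 1.0, 0.0, 0.0)
        assert out.precision == out.recall == 1.0

    def test_hand_counted_partial_overlap(self):
        """2 predicted vs 2 true voxels sharing exactly one."""
        pred = mask_from_points([(0, 0, 0), (1, 0, 0)], 1)
        gt = mask_from_points([(0, 0, 0), (2, 0, 0)], 1)
        out = seg_metrics(pred, gt, 1)
        assert out.precision == pytest.approx(0.5)
        assert out.recall == pytest.approx(0.5)
        assert out.dsc == pytest.approx(0.5)
        assert out.iou == pytest.approx(1 / 3)
        assert out.voe == pytest.approx(2 / 3)
        assert out.rvd == pytest.approx(0.0)

    def test_disjoint(self):
        pred = mask_from_points([(0, 0, 0)], 1)
        gt = mask_from_points([(5, 5, 5)], 1)
        out = seg_metrics(pred, gt, 1)
        assert out.dsc == 0.0 and out.voe == 1.0

    def test_empty_gt_flags_rvd(self):
        pred = mask_from_points([(0, 0, 0)], 1)
        gt = mask_from_points([], 1)
        out = seg_metrics(pred, gt, 1)
        assert np.isnan(out.rvd)
        assert out.recall == 0.0  # 0/0 convention

    def test_dsc_iou_identity_random(self, rng):
        """DSC = 2 IoU / (1 + IoU) for arbitrary masks."""
        for _ in range(50):
            pred = MultiClassMask((rng.random((5, 5, 5)) < 0.5).astype(int))
            gt = MultiClassMask((rng.random((5, 5, 5)) < 0.5).astype(int))
            out = seg_metrics(pred, gt, 1)
            assert out.dsc == pytest.approx(2 * out.iou / (1 + out.iou), abs=1e-12)

    def test_invariant_under_joint_permutation(self, rng):
        pred = (rng.random((4, 4, 4)) < 0.4).astype(int)
        gt = (rng.random((4, 4, 4)) < 0.4).astype(int)
        perm = rng.permutation(64)
        a = seg_metrics(MultiClassMask(pred), MultiClassMask(gt), 1)
        b = seg_metrics(
            MultiClassMask(pred.reshape(-1)[perm].reshape(4, 4, 4)),
            MultiClassMask(gt.reshape(-1)[perm].reshape(4, 4, 4)),
            1,
        )
        assert a.as_dict() == b.as_dict()


class TestHausdorff:
    def test_identical_sets(self, rng):
        a = rng.random((5, 5, 5)) < 0.3
        a[0, 0, 0] = True
        assert hausdorff(a, a) == 0.0

    def test_3_4_5_triangle(self):
        a = np.zeros((4, 5, 1), dtype=bool)
        b = np.zeros((4, 5, 1), dtype=bool)
        a[0, 0, 0] = True
        b[3, 4, 0] = True
        assert hausdorff(a, b) == pytest.approx(5.0)

    def test_empty_set_flagged(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        b = np.ones((3, 3, 3), dtype=bool)
        assert np.isnan(hausdorff(a, b))

    def test_matches_bruteforce_on_random_sets(self, rng):
        for _ in range(30):
            a = rng.random((5, 5, 5)) < 0.3
            b = rng.random((5, 5, 5)) < 0.3
            if not a.any() or not b.any():
                continue
            pa, pb = np.argwhere(a).astype(float), np.argwhere(b).astype(float)
            d = np.sqrt(((pa[:, None] - pb[None]) ** 2).sum(-1))
            expected = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert hausdorff(a, b) == pytest.approx(expected)

    def test_spacing_scales_distance(self):
        a = np.zeros((3, 1, 1), dtype=bool)
        b = np.zeros((3, 1, 1), dtype=bool)
        a[0, 0, 0] = True
        b[2, 0, 0] = True
        assert hausdorff(a, b, (0.2, 0.2, 0.2)) == pytest.approx(0.4)


class TestSliceProfile:
    def test_identical_masks_all_dsc_one(self, default_phantom):
        _, mask, _ = default_phantom
        table = slice_profile(mask, mask, 1)
        assert len(table) > 0
        assert (table.dsc == 1.0).all()
        assert (table.hausdorff == 0.0).all()

    def test_offset_single_slice_structures(self):
        pred = np.zeros((4, 4, 6), dtype=int)
        gt = np.zeros((4, 4, 6), dtype=int)
        gt[1, 1, 2] = 1
        pred[1, 1, 3] = 1
        table = slice_profile(MultiClassMask(pred), MultiClassMask(gt), 1)
        row_gt = table[table.z == 2].iloc[0]
        assert row_gt.dsc == 0.0
        assert np.isnan(row_gt.hausdorff)

    def test_per_slice_counts_aggregate_to_volume_metrics(self, rng, default_phantom):
        _, gt, _ = default_phantom
        noisy = gt.labels.copy()
        flip = rng.random(noisy.shape) < 0.02
        noisy[flip] = 0
        pred = MultiClassMask(noisy)
        table = slice_profile(pred, gt, 1)
        tp, fp, fn = table.tp.sum(), table.fp.sum(), table.fn.sum()
        vol = seg_metrics(pred, gt, 1)
        assert vol.dsc == pytest.approx(2 * tp / (2 * tp + fp + fn))

    def test_empty_everywhere_slices_omitted(self):
        empty = MultiClassMask(np.zeros((3, 3, 5), dtype=int))
        assert len(slice_profile(empty, empty, 1)) == 0


class TestPRCurveAP:
    def test_perfect_cases(self):
        _, ap = pr_curve_ap([1.0, 1.0, 1.0])
        assert ap == 1.0

    def test_no_case_passes(self):
        _, ap = pr_curve_ap([0.0, 0.0], thresholds=[0.5, 0.9])
        assert ap == 0.0

    def test_hand_enumerated_example(self):
        """IoUs {0.9, 0.7, 0.5, 0.3} on grid {0.25, 0.5, 0.75}: fractions
        passing are 1.0, 0.75, 0.25 -> AP = mean = 2/3."""
        curve, ap = pr_curve_ap([0.9, 0.7, 0.5, 0.3], thresholds=[0.25, 0.5, 0.75])
        assert list(curve.precision) == [1.0, 0.75, 0.25]
        assert list(curve.recall) == [1.0, 0.75, 0.25]
        assert ap == pytest.approx((1.0 + 0.75 + 0.25) / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pr_curve_ap([])


class TestROCAndClsMetrics:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_trapezoid_equals_pairwise_concordance(self, rng):
        """AUC via the ROC trapezoid equals the O(n^2) concordance count."""
        for _ in range(30):
            n = 12
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            _, auc = roc_auc(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = (pos[:, None] > neg[None]).sum() + 0.5 * (pos[:, None] == neg[None]).sum()
            assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_auc_flagged(self):
        _, auc = roc_auc([0.2, 0.9], [1, 1])
        assert np.isnan(auc)

    def test_confusion_table_metrics(self):
        m = cls_metrics([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0])
        # at 0.5: TP=1 FN=1 TN=1 FP=1
        assert m.accuracy == 0.5
        assert m.sensitivity == 0.5
        assert m.specificity == 0.5


class TestHypothesisProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        arrays(np.int8, (3, 3, 3), elements=st.integers(0, 1)),
        arrays(np.int8, (3, 3, 3), elements=st.integers(0, 1)),
    )
    def test_dsc_iou_identity_and_bounds(self, p, g):
        out = seg_metrics(MultiClassMask(p.astype(int)), MultiClassMask(g.astype(int)), 1)
        assert 0.0 <= out.dsc <= 1.0 and 0.0 <= out.iou <= 1.0
        assert out.dsc == pytest.approx(2 * out.iou / (1 + out.iou), abs=1e-12)
        # symmetry of the overlap metrics in pred/gt
        back = seg_metrics(MultiClassMask(g.astype(int)), MultiClassMask(p.astype(int)), 1)
        assert out.dsc == back.dsc and out.iou == back.iou
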
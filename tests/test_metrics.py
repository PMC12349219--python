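"""Classification metrics and IoU/mIoU explanation scoring."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazefusion import (binarize_cam, classification_metrics, compute_iou,
                        compute_miou, macro_auc)


class TestClassificationMetrics:
    def test_perfect_predictions_score_one_everywhere(self):
        labels = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        probs = labels.astype(float) * 0.8 + 0.1
        cm = classification_metrics(probs, labels)
        for m in ("accuracy", "precision", "recall", "f1", "auc"):
            assert cm.macro[m] == pytest.approx(1.0)
        assert (cm.per_class["fp"] == 0).all()
        assert (cm.per_class["fn"] == 0).all()

    def test_hand_counted_confusion_formulas(self):
        # single class: TP=2 FP=1 FN=1 TN=4
        labels = np.array([[1], [1], [1], [0], [0], [0], [0], [0]])
        probs = np.array([[0.9], [0.8], [0.2], [0.7], [0.1], [0.1], [0.1], [0.2]])
        cm = classification_metrics(probs, labels)
        row = cm.per_class.iloc[0]
        assert (row.tp, row.fp, row.fn, row.tn) == (2, 1, 1, 4)
        assert row.precision == pytest.approx(2 / 3)
        assert row.recall == pytest.approx(2 / 3)
        assert row.f1 == pytest.approx(2 / 3)
        assert row.accuracy == pytest.approx(3 / 4)

    def test_random_probabilities_give_chance_auc(self, rng):
        n = 10_000
        labels = (rng.random((n, 3)) < 0.4).astype(int)
        probs = rng.random((n, 3))
        cm = classification_metrics(probs, labels)
        assert cm.macro["auc"] == pytest.approx(0.5, abs=0.02)

    def test_accuracy_recomputes_from_reported_confusion(self, rng):
        labels = (rng.random((200, 4)) < 0.3).astype(int)
        probs = rng.random((200, 4))
        cm = classification_metrics(probs, labels)
        for _, row in cm.per_class.iterrows():
            total = row.tp + row.fp + row.fn + row.tn
            assert total == 200
            assert row.accuracy == pytest.approx((row.tp + row.tn) / total)

    def test_class_without_positives_excluded_from_macro_with_warning(self):
        labels = np.array([[1, 0], [0, 0], [1, 0]])
        probs = np.array([[0.9, 0.2], [0.1, 0.3], [0.8, 0.1]])
        with pytest.warns(UserWarning, match="class 1"):
            cm = classification_metrics(probs, labels)
        assert np.isnan(cm.per_class.loc[1, "recall"])
        assert cm.macro["recall"] == pytest.approx(1.0)  # only class 0 counts

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = (rng.random((500, 2)) < 0.5).astype(int)
        probs = rng.random((500, 2))
        a, _ = macro_auc(probs, labels)
        b, _ = macro_auc(probs**3, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_shape_mismatch_and_bad_threshold_raise(self):
        with pytest.raises(ValueError, match="shape"):
            classification_metrics(np.zeros((3, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="threshold"):
            classification_metrics(np.zeros((3, 2)), np.zeros((3, 2)), threshold=1.0)


class TestBinarizeCam:
    def test_constant_zero_map_gives_empty_mask(self):
        assert not binarize_cam(np.zeros((8, 8)), 0.5).any()

    def test_lower_threshold_grows_mask_monotonically(self, rng):
        d = rng.random((16, 16))
        prev = None
        for t in (0.9, 0.6, 0.3, 0.1):
            mask = binarize_cam(d, t)
            if prev is not None:
                assert np.all(prev <= mask)  # set inclusion
            prev = mask

    def test_threshold_just_below_unique_max_isolates_argmax(self):
        d = np.zeros((4, 4))
        d[1, 2] = 1.0
        mask = binarize_cam(d, 0.999)
        assert mask.sum() == 1 and mask[1, 2]

    def test_threshold_outside_open_interval_raises(self):
        with pytest.raises(ValueError, match="threshold"):
            binarize_cam(np.zeros((2, 2)), 0.0)


class TestIoU:
    def test_identical_nonempty_masks_give_one(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1:3, 1:3] = True
        assert compute_iou(m, m) == 1.0

    def test_disjoint_nonempty_masks_give_zero(self):
        a = np.zeros((4, 4), dtype=bool); a[0, 0] = True
        b = np.zeros((4, 4), dtype=bool); b[3, 3] = True
        assert compute_iou(a, b) == 0.0

    def test_hand_counted_third(self):
        a = np.zeros((4, 4), dtype=bool); a[0, :4] = True          # 4 px
        b = np.zeros((4, 4), dtype=bool); b[0, 2:4] = b[1, 0:2] = True  # 4 px, 2 shared
        assert compute_iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        assert compute_iou(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shapes"):
            compute_iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    def test_symmetry_and_bounds(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], dtype=bool).reshape(4, 4)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], dtype=bool).reshape(4, 4)
        iou = compute_iou(a, b)
        assert iou == compute_iou(b, a)
        assert 0.0 <= iou <= 1.0
        if a.any():
            assert compute_iou(a, a) == 1.0


class TestMIoU:
    def test_identical_stacks_give_miou_one(self, rng):
        masks = rng.random((3, 8, 8)) > 0.5
        assert compute_miou(masks, masks).miou == pytest.approx(1.0)

    def test_mean_of_half_and_one_is_three_quarters(self):
        roi = np.zeros((2, 4, 4), dtype=bool)
        cam = np.zeros((2, 4, 4), dtype=bool)
        roi[0, 0, :] = True; cam[0, 0, :] = True                  # IoU 1.0
        roi[1, 0, 0:2] = True; cam[1, 0, 0:4] = True              # IoU 0.5
        report = compute_miou(cam, roi)
        assert report.miou == pytest.approx(0.75)
        np.testing.assert_allclose(report.per_class_iou, [1.0, 0.5])

    def test_matches_brute_force_loop_oracle(self, rng):
        cam = rng.random((4, 6, 6)) > 0.5
        roi = rng.random((4, 6, 6)) > 0.4
        report = compute_miou(cam, roi, include_empty=True)
        expected = []
        for k in range(4):
            inter = union = 0
            for i in range(6):
                for j in range(6):
                    inter += cam[k, i, j] and roi[k, i, j]
                    union += cam[k, i, j] or roi[k, i, j]
            expected.append(inter / union if union else 1.0)
        assert report.miou == pytest.approx(np.mean(expected), abs=1e-12)

    def test_class_without_roi_excluded_with_warning(self):
        cam = np.ones((2, 4, 4), dtype=bool)
        roi = np.zeros((2, 4, 4), dtype=bool)
        roi[0] = True
        with pytest.warns(UserWarning, match="no ROI"):
            report = compute_miou(cam, roi)
        assert report.miou == pytest.approx(1.0)
        assert list(report.included) == [True, False]

    def test_empty_class_stack_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            compute_miou(np.zeros((0, 4, 4), bool), np.zeros((0, 4, 4), bool))

    def test_single_class_labels_flagged_in_macro_auc(self):
        labels = np.array([[1], [1], [1]])
        probs = np.array([[0.2], [0.5], [0.9]])
        with pytest.warns(UserWarning, match="one label value"):
            auc, per_class = macro_auc(probs, labels)
        assert np.isnan(auc)


def test_warnings_are_not_errors_for_valid_inputs(rng):
    labels = (rng.random((50, 3)) < 0.5).astype(int)
    probs = rng.random((50, 3))
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        classification_metrics(probs, labels)
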
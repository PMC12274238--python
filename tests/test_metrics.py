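"""Confusion metrics, AUC/F1, IoU, and Total Agreement."""

import itertools

import numpy as np
import pytest

from gestseg.metrics import (
    class_metrics,
    confusion_matrix,
    iou,
    macro_auc,
    macro_f1,
    to_retained_blocks,
    total_agreement,
)


class TestConfusionMatrix:
    def test_perfect_prediction_identity(self, rng):
        truth = rng.integers(1, 6, size=500)
        cm = confusion_matrix(truth, truth)
        np.testing.assert_allclose(np.diag(cm.values[:, :5]), 100.0)

    def test_single_off_diagonal(self):
        truth = np.ones(50, dtype=int)
        pred = np.full(50, 2)
        cm = confusion_matrix(pred, truth)
        assert cm.loc["G1", "G2"] == 100.0

    def test_background_truth_excluded_and_rows_sum_100(self, rng):
        truth = rng.integers(0, 6, size=400)
        pred = rng.integers(0, 6, size=400)
        cm = confusion_matrix(pred, truth)
        np.testing.assert_allclose(cm.sum(axis=1), 100.0)

    def test_matches_brute_force_tally(self, rng):
        truth = rng.integers(1, 6, size=200)
        pred = rng.integers(1, 6, size=200)
        cm = confusion_matrix(pred, truth)
        for t in range(1, 6):
            for p in range(1, 6):
                expected = 100.0 * np.sum((truth == t) & (pred == p)) / np.sum(truth == t)
                assert cm.loc[f"G{t}", f"G{p}"] == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_matrix(np.ones(3, int), np.ones(4, int))


class TestClassMetrics:
    def test_perfect_prediction(self, rng):
        truth = rng.integers(0, 6, size=300)
        m = class_metrics(truth, truth, gesture_label=3)
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    def test_complement_prediction(self):
        truth = np.array([1, 1, 1, 0, 0, 0])
        pred = np.array([0, 0, 0, 1, 1, 1])
        m = class_metrics(pred, truth, gesture_label=1)
        assert m.sensitivity == 0.0 and m.specificity == 0.0

    def test_hand_counted_contingency(self):
        truth = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 1])
        m = class_metrics(pred, truth, gesture_label=1)
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(6 / 7)
        assert m.accuracy == pytest.approx(8 / 10)

    def test_absent_class_flagged(self):
        truth = np.zeros(10, dtype=int)
        m = class_metrics(truth, truth, gesture_label=2)
        assert m.undefined_sensitivity

    def test_per_video_ci_brackets_mean(self, rng):
        truth = rng.integers(0, 3, size=400)
        pred = np.where(rng.random(400) < 0.8, truth, rng.integers(0, 3, size=400))
        vids = np.repeat(np.arange(8), 50)
        m = class_metrics(pred, truth, gesture_label=1, video_ids=vids)
        assert m.accuracy_ci[0] <= m.accuracy <= m.accuracy_ci[1]


class TestMacroAUC:
    def test_one_hot_probabilities(self, rng):
        truth = rng.integers(1, 6, size=100)
        probs = np.eye(6)[truth]
        assert macro_auc(probs, truth) == 1.0

    def test_random_probabilities_near_half(self, rng):
        truth = rng.integers(1, 6, size=4000)
        probs = rng.dirichlet(np.ones(6), size=4000)
        assert abs(macro_auc(probs, truth) - 0.5) < 0.04

    def test_perfect_ranking_small_example(self):
        truth = np.array([1, 1, 0, 0])
        probs = np.zeros((4, 6))
        probs[:, 1] = [0.9, 0.8, 0.3, 0.1]
        value, per_class = macro_auc(probs, truth, return_per_class=True)
        assert per_class[1] == 1.0

    def test_single_class_truth_flagged(self):
        truth = np.ones(10, dtype=int)
        probs = np.full((10, 6), 1 / 6)
        assert np.isnan(macro_auc(probs, truth))


class TestMacroF1:
    def test_perfect(self, rng):
        truth = rng.integers(1, 6, size=100)
        assert macro_f1(truth, truth) == 1.0

    def test_missed_class_scores_zero(self):
        truth = np.array([1, 1, 2, 2])
        pred = np.array([2, 2, 2, 2])
        _, per_class = macro_f1(pred, truth, return_per_class=True)
        assert per_class[1] == 0.0

    def test_hand_computed(self):
        truth = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 1])
        _, per_class = macro_f1(pred, truth, return_per_class=True)
        assert per_class[1] == pytest.approx(2 / 3)


class TestIoU:
    def test_equal_nonzero(self):
        a = np.array([1, 1, 0, 0])
        assert iou(a, a) == 1.0

    def test_disjoint(self):
        assert iou(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_hand_count(self):
        assert iou(np.array([1, 1, 0, 0]), np.array([0, 1, 1, 0])) == pytest.approx(1 / 3)

    def test_both_empty_degenerate(self):
        assert iou(np.zeros(10), np.zeros(10)) == 1.0


class TestTotalAgreement:
    def test_both_all_zero_is_one(self):
        score = total_agreement(np.zeros(1000), np.zeros(1000))
        assert score.value == 1.0
        assert score.zero_matches == 1000

    def test_identical_arrays(self, rng):
        a = rng.integers(0, 2, size=64)
        assert total_agreement(a, a).value == 1.0

    def test_equals_framewise_agreement_exhaustive_len4(self):
        """Complete enumeration over all 256 pairs of length-4 binary arrays."""
        for bits_a in itertools.product([0, 1], repeat=4):
            for bits_b in itertools.product([0, 1], repeat=4):
                a, b = np.array(bits_a), np.array(bits_b)
                expected = np.mean(a == b)
                assert total_agreement(a, b).value == pytest.approx(expected)

    def test_equals_framewise_agreement_random_len10(self, rng):
        for _ in range(10_000):
            a = rng.integers(0, 2, size=10)
            b = rng.integers(0, 2, size=10)
            assert total_agreement(a, b).value == np.mean(a == b)

    def test_symmetry_and_relation_to_iou(self, rng):
        a = rng.integers(0, 2, size=50)
        b = rng.integers(0, 2, size=50)
        assert total_agreement(a, b).value == total_agreement(b, a).value
        # when no matched zeros exist, TA collapses to IoU
        a2 = np.array([1, 1, 0, 1])
        b2 = np.array([0, 1, 1, 1])
        assert total_agreement(a2, b2).value == iou(a2, b2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            total_agreement(np.array([]), np.array([]))


class TestRetainedBlocks:
    def test_block_aggregation(self):
        P = np.tile(np.eye(6)[np.array([1] * 10 + [2] * 10 + [2] * 5)], (1, 1))
        truth = np.array([1] * 10 + [2] * 15)
        probs, preds, truths = to_retained_blocks(P, truth, block=10)
        assert preds.tolist() == [1, 2, 2]
        assert truths.tolist() == [1, 2, 2]
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)

    def test_majority_truth_label(self):
        P = np.full((10, 6), 1 / 6)
        truth = np.array([1, 1, 1, 1, 1, 1, 2, 2, 2, 2])
        _, _, truths = to_retained_blocks(P, truth, block=10)
        assert truths.tolist() == [1]


class TestStratifiedAgreement:
    def _fixture(self):
        from gestseg.annotation import AnnotationEvent, AnnotationTrack, GestureClass
        from gestseg.postprocess import SegmentationResult, annotation_occupancy

        track = AnnotationTrack(video_id="v", duration_s=10.0, procedure="BND",
                                events=[AnnotationEvent(GestureClass.G1, 0.0, 5.0)])
        occ = annotation_occupancy(track, L=100)
        seg = SegmentationResult(video_id="v", duration_s=10.0, L=100,
                                 occupancy={c: occ[c].copy() for c in occ})
        return seg, track

    def test_absent_class_scores_one_with_zero_ci(self):
        from gestseg.metrics import stratified_agreement

        seg, track = self._fixture()
        df = stratified_agreement([(seg, track)], strata=("class",))
        g4 = df[df["class"] == "G4"].iloc[0]
        assert g4["mean"] == 1.0
        assert g4["ci_half_width"] == 0.0

    def test_single_video_degenerate_ci_flagged(self):
        from gestseg.metrics import stratified_agreement

        seg, track = self._fixture()
        seg.occupancy[1][:10] = 0  # degrade G1 slightly
        df = stratified_agreement([(seg, track)], strata=("procedure", "class"))
        row = df[(df["procedure"] == "BND") & (df["class"] == "G1")].iloc[0]
        assert 0.8 < row["mean"] < 1.0
        assert row["degenerate_ci"]
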
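"""Detection contract, baseline detector, matching and metrics."""

import numpy as np
import pytest

from hemamorph.io_formats import Calibration, LabelSchema
from hemamorph.segmentation import (
    Detection,
    baseline_detector,
    confusion_matrix,
    center_to_corner,
    detect_cells,
    detection_metrics,
    iou,
    mask_iou,
    match_detections,
    oracle_detector_from_truth,
)
from hemamorph.synthetic_smear import CellSpec, generate_dataset, render_smear


@pytest.fixture(scope="module")
def five_cell_sample(cal):
    specs = [
        CellSpec("rbc", "Normal", (40.0, 40.0), 3.5, 3.5, pallor_ratio=0.4),
        CellSpec("rbc", "Normal", (40.0, 140.0), 3.5, 3.5, pallor_ratio=0.4),
        CellSpec("rbc", "Normal", (140.0, 40.0), 3.5, 3.5, pallor_ratio=0.4),
        CellSpec("rbc", "Normal", (140.0, 140.0), 3.5, 3.5, pallor_ratio=0.4),
        CellSpec("rbc", "Normal", (90.0, 90.0), 3.5, 3.5, pallor_ratio=0.4),
    ]
    return render_smear(specs, (180, 180), cal, seed=4)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        assert mask_iou(mask, mask) == 1.0

    def test_disjoint(self):
        assert iou((0, 0, 1, 1), (5, 5, 1, 1)) == 0.0

    def test_hand_computed_overlap(self):
        assert iou((0, 0, 2, 2), (1, 1, 2, 2)) == pytest.approx(1 / 7, abs=1e-9)

    def test_symmetry(self):
        a, b = (0, 0, 3, 2), (1, 0.5, 2, 2)
        assert iou(a, b) == iou(b, a)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 2), (0, 0, 1, 1))
        with pytest.raises(ValueError):
            mask_iou(np.zeros((4, 4), bool), np.ones((4, 4), bool))


class TestMatching:
    def test_exact_predictions_all_tp(self, five_cell_sample):
        preds = oracle_detector_from_truth(five_cell_sample.instances)
        r = match_detections(preds, five_cell_sample.instances)
        assert len(r.matches) == 5 and not r.unmatched_preds and not r.unmatched_truths

    def test_no_predictions_all_fn(self, five_cell_sample):
        r = match_detections([], five_cell_sample.instances)
        assert len(r.unmatched_truths) == 5

    def test_duplicate_predictions_higher_confidence_wins(self, five_cell_sample):
        truth = [five_cell_sample.instances[0]]
        t = truth[0]
        best = Detection(
            (t.box.x_center, t.box.y_center, t.box.width, t.box.height),
            t.mask, t.class_id, 0.9,
        )
        shifted = np.roll(t.mask, 2, axis=0)
        worse = Detection(best.box, shifted, t.class_id, 0.4)
        r = match_detections([worse, best], truth)
        assert r.matches[0][0] == 1          # the confident one is the TP
        assert r.unmatched_preds == [0]


class TestMetrics:
    def test_perfect_detector_all_ones(self, five_cell_sample):
        preds = oracle_detector_from_truth(five_cell_sample.instances)
        r = match_detections(preds, five_cell_sample.instances)
        m = detection_metrics([r])
        assert m["precision"] == m["recall"] == m["f1"] == m["mAP50"] == 1.0

    def test_counting_arithmetic(self, five_cell_sample):
        """TP=8, FP=2, FN=2 gives P=R=F1=0.8."""
        results = []
        for _ in range(2):
            preds = oracle_detector_from_truth(five_cell_sample.instances[:4])
            fp_mask = np.zeros_like(five_cell_sample.instances[0].mask)
            fp_mask[:6, :6] = True
            preds.append(Detection((0.02, 0.02, 0.03, 0.03), fp_mask, 9, 0.2))
            results.append(match_detections(preds, five_cell_sample.instances))
        m = detection_metrics(results)
        assert (m["tp"], m["fp"], m["fn"]) == (8, 2, 2)
        for key in ("precision", "recall", "f1"):
            assert m[key] == pytest.approx(0.8)

    def test_no_predictions_convention(self, five_cell_sample):
        r = match_detections([], five_cell_sample.instances)
        m = detection_metrics([r])
        assert m["precision"] == m["recall"] == m["f1"] == 0.0

    def test_metrics_permutation_invariant_over_images(self, five_cell_sample):
        preds = oracle_detector_from_truth(five_cell_sample.instances)
        r1 = match_detections(preds[:3], five_cell_sample.instances)
        r2 = match_detections(preds, five_cell_sample.instances[:4])
        assert detection_metrics([r1, r2]) == detection_metrics([r2, r1])

    def test_map_monotone_in_iou_threshold(self, five_cell_sample):
        preds = oracle_detector_from_truth(five_cell_sample.instances)
        # degrade one mask so its IoU is between 0.5 and 1
        preds[0].mask = np.roll(preds[0].mask, 8, axis=1)
        maps = []
        for thr in (0.5, 0.7, 0.9, 0.99):
            r = match_detections(preds, five_cell_sample.instances, iou_threshold=thr)
            maps.append(detection_metrics([r])["mAP50"])
        assert all(a >= b - 1e-12 for a, b in zip(maps, maps[1:]))


class TestConfusion:
    def test_perfect_predictions_identity_block(self, five_cell_sample):
        preds = oracle_detector_from_truth(five_cell_sample.instances)
        mat = confusion_matrix([preds], [five_cell_sample.instances])
        rbc = LabelSchema.id_of("rbc")
        assert mat[rbc, rbc] == 1.0

    def test_all_missed_mass_in_background_column(self, five_cell_sample):
        mat = confusion_matrix([[]], [five_cell_sample.instances])
        rbc = LabelSchema.id_of("rbc")
        assert mat[rbc, 10] == 1.0

    def test_partial_misses_row_fractions(self, five_cell_sample):
        """7 of 10 truths matched: row = 0.7 diagonal, 0.3 background."""
        truths = five_cell_sample.instances * 2
        preds = oracle_detector_from_truth(truths[:7])
        mat = confusion_matrix([preds], [truths])
        rbc = LabelSchema.id_of("rbc")
        assert mat[rbc, rbc] == pytest.approx(0.7)
        assert mat[rbc, 10] == pytest.approx(0.3)

    def test_nonempty_rows_sum_to_one(self, five_cell_sample):
        preds = oracle_detector_from_truth(five_cell_sample.instances[:3])
        mat = confusion_matrix([preds], [five_cell_sample.instances])
        sums = mat.sum(axis=1)
        for s in sums:
            assert s == pytest.approx(1.0, abs=1e-9) or s == 0.0


class TestBaselineDetector:
    def test_single_dark_ellipse(self, cal):
        spec = CellSpec("rbc", "Normal", (48.0, 48.0), 3.5, 3.5)
        sample = render_smear([spec], (96, 96), cal, seed=1)
        dets = detect_cells(sample.image, baseline_detector)
        assert len(dets) == 1

    def test_two_disjoint_ellipses(self, cal):
        specs = [
            CellSpec("rbc", "Normal", (40.0, 40.0), 3.5, 3.5),
            CellSpec("rbc", "Normal", (40.0, 120.0), 3.5, 3.5),
        ]
        sample = render_smear(specs, (80, 160), cal, seed=2)
        assert len(detect_cells(sample.image, baseline_detector)) == 2

    def test_touching_ellipses_split_by_watershed(self, cal):
        specs = [
            CellSpec("rbc", "Normal", (48.0, 40.0), 3.5, 3.5),
            CellSpec("rbc", "Normal", (48.0, 101.0), 3.5, 3.5),
        ]
        sample = render_smear(specs, (96, 144), cal, seed=3, max_overlap=0.35)
        dets = detect_cells(sample.image, baseline_detector)
        assert len(dets) == 2

    def test_blank_background_empty(self, cal):
        sample = render_smear([], (64, 64), cal, seed=5)
        assert detect_cells(sample.image, baseline_detector) == []

    def test_well_separated_cells_found_with_iou(self, five_cell_sample):
        dets = detect_cells(five_cell_sample.image, baseline_detector)
        assert len(dets) == 5
        r = match_detections(dets, five_cell_sample.instances, class_aware=False)
        assert len(r.matches) == 5
        assert all(i >= 0.5 for _, _, i in r.matches)

    def test_output_boxes_are_tight_boxes_of_masks(self, five_cell_sample):
        from hemamorph.io_formats import box_from_mask

        for d in detect_cells(five_cell_sample.image, baseline_detector):
            assert d.box == box_from_mask(d.mask)

    def test_detector_failure_has_context(self):
        def broken(image):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="broken"):
            detect_cells(np.zeros((8, 8, 3)), broken)
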
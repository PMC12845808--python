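"""IoU, one-to-one matching, precision/recall/F1 and AP50."""

import numpy as np
import pytest

import pigpen as pp
from pigpen.detmetrics import Detection, MatchResult
from conftest import max_assignment_tp


def det(x1, y1, x2, y2, conf):
    return Detection(box=(x1, y1, x2, y2), confidence=conf)


class TestIoU:
    def test_identical_boxes(self):
        assert pp.iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert pp.iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0

    def test_half_overlap_worked_example(self):
        assert pp.iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_symmetry_and_range(self, rng):
        for _ in range(50):
            a = tuple(sorted(rng.uniform(0, 50, 2))) + tuple(sorted(rng.uniform(0, 50, 2)))
            a = (a[0], a[2], a[1] + 1, a[3] + 1)
            b = tuple(sorted(rng.uniform(0, 50, 2))) + tuple(sorted(rng.uniform(0, 50, 2)))
            b = (b[0], b[2], b[1] + 1, b[3] + 1)
            v = pp.iou(a, b)
            assert v == pp.iou(b, a)
            assert 0.0 <= v <= 1.0

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            pp.iou((0, 0, 0, 10), (0, 0, 10, 10))


class TestMatching:
    def test_iou_boundary_at_half(self):
        gt = [(0.0, 0.0, 10.0, 10.0)]
        # IoU = inter / union; shift so IoU lands below/at/above 0.5
        d_60 = det(0, 0, 10, 7.5, 0.9)   # IoU = 75/100 = 0.75 -> TP
        m = pp.match_detections([d_60], gt)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)
        d_049 = det(0, 0, 10, 4.9, 0.9)  # IoU = 0.49 -> FP + FN
        m = pp.match_detections([d_049], gt)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)
        d_05 = det(0, 0, 10, 5.0, 0.9)   # IoU = 0.50 exactly -> TP
        m = pp.match_detections([d_05], gt)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_one_to_one_matching(self):
        gt = [(0.0, 0.0, 10.0, 10.0)]
        dets = [det(0, 0, 10, 10, 0.9), det(0, 0, 10, 9, 0.8)]
        m = pp.match_detections(dets, gt)
        assert (m.tp, m.fp) == (1, 1)
        assert m.matched_pairs[0][0] == 0  # higher confidence wins the gt

    def test_greedy_equals_exhaustive_assignment_on_random_instances(self):
        """200 random scenes with up to 6 boxes: the confidence-ordered greedy
        TP count equals the maximum one-to-one assignment."""
        rng = np.random.default_rng(0)
        mismatches = 0
        for _ in range(200):
            n_gt = int(rng.integers(1, 7))
            gts = []
            for _ in range(n_gt):
                x, y = rng.uniform(0, 70, 2)
                w, h = rng.uniform(8, 30, 2)
                gts.append((x, y, x + w, y + h))
            dets = []
            for g in gts:
                if rng.random() < 0.75:  # jittered copy of the gt
                    dx, dy = rng.uniform(-6, 6, 2)
                    dets.append(det(g[0] + dx, g[1] + dy, g[2] + dx, g[3] + dy,
                                    float(rng.random())))
            for _ in range(int(rng.integers(0, 3))):  # spurious boxes
                x, y = rng.uniform(0, 70, 2)
                w, h = rng.uniform(8, 30, 2)
                dets.append(det(x, y, x + w, y + h, float(rng.random())))
            if len(dets) > 6:
                dets = dets[:6]
            m = pp.match_detections(dets, gts)
            iou_matrix = np.array(
                [[pp.iou(d.box, g) for g in gts] for d in dets]
            ).reshape(len(dets), len(gts))
            if m.tp != max_assignment_tp(iou_matrix, 0.5):
                mismatches += 1
        assert mismatches == 0


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp, fp, fn, expected",
        [
            (3, 1, 1, (0.75, 0.75, 0.75)),
            (0, 0, 5, (0.0, 0.0, 0.0)),
            (4, 0, 0, (1.0, 1.0, 1.0)),
        ],
    )
    def test_worked_examples(self, tp, fp, fn, expected):
        got = pp.precision_recall_f1(MatchResult(tp=tp, fp=fp, fn=fn))
        assert got == pytest.approx(expected)


class TestAP50:
    def test_single_perfect_detection(self):
        gt = [(0.0, 0.0, 10.0, 10.0)]
        assert pp.ap50([det(0, 0, 10, 10, 0.9)], gt) == 1.0

    def test_all_false_positives(self):
        gt = [(0.0, 0.0, 10.0, 10.0)]
        dets = [det(50, 50, 60, 60, 0.9), det(70, 70, 80, 80, 0.8)]
        assert pp.ap50(dets, gt) == 0.0

    def test_three_detection_worked_example(self):
        """conf .9 TP, .8 FP, .7 TP over 2 gts: AP = 0.5*1 + 0.5*(2/3)."""
        gts = [(0.0, 0.0, 10.0, 10.0), (20.0, 0.0, 30.0, 10.0)]
        dets = [
            det(0, 0, 10, 10, 0.9),
            det(50, 50, 60, 60, 0.8),
            det(20, 0, 30, 10, 0.7),
        ]
        assert pp.ap50(dets, gts) == pytest.approx(5 / 6)

    def test_invariant_to_uniform_confidence_rescaling(self):
        gts = [(0.0, 0.0, 10.0, 10.0), (20.0, 0.0, 30.0, 10.0)]
        dets = [
            det(0, 0, 10, 10, 0.9),
            det(50, 50, 60, 60, 0.8),
            det(20, 0, 30, 10, 0.7),
        ]
        scaled = [det(*d.box, d.confidence / 2) for d in dets]
        assert pp.ap50(dets, gts) == pytest.approx(pp.ap50(scaled, gts))

    def test_perfect_unique_detections_give_one(self, rng):
        gts, dets = [], []
        for k in range(5):
            x = 20.0 * k
            gts.append((x, 0.0, x + 10, 10.0))
            dets.append(det(x, 0, x + 10, 10, float(rng.random())))
        assert pp.ap50(dets, gts) == 1.0

    def test_interpolated_precision_non_increasing(self, rng):
        gts = [(20.0 * k, 0.0, 20.0 * k + 10, 10.0) for k in range(6)]
        dets = []
        for g in gts:
            if rng.random() < 0.7:
                dets.append(det(g[0] + 2, 1, g[2] + 2, 11, float(rng.random())))
        for _ in range(4):
            x = rng.uniform(0, 100)
            dets.append(det(x, 30, x + 10, 40, float(rng.random())))
        rep = pp.evaluate({"img": dets}, {"img": gts})
        precisions = [p for _, p in rep.pr_curve]
        recalls = [r for r, _ in rep.pr_curve]
        assert all(a >= b for a, b in zip(precisions, precisions[1:]))
        assert all(a <= b for a, b in zip(recalls, recalls[1:]))

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            pp.ap50([det(0, 0, 1, 1, 0.5)], [])


class TestDetectionsJson:
    def test_round_trip(self, tmp_path):
        dets = {
            "a": [det(0, 0, 10, 10, 0.9)],
            "b": [det(5, 5, 15, 15, 0.4), det(1, 1, 2, 2, 0.2)],
        }
        path = tmp_path / "dets.json"
        pp.detmetrics.save_detections_json(path, dets)
        back = pp.detmetrics.load_detections_json(path)
        assert back == dets
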
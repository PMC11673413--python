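"""Detection metrics (AP, AUC, lesion tally) and quadrant localization."""
import numpy as np
import pytest

from bcrcnn.dataset_io import (BENIGN, MALIGNANT, Box, LesionAnnotation,
                               Plane, VOCRecord)
from bcrcnn.eval3d import (BreastGeometry, ConfusionCounts, Detection,
                           Laterality, QuadrantLabel, average_precision_50,
                           box_center, build_case_report, confusion_rates,
                           laterality, lesion_level_tally, locate_quadrant,
                           map50, roc_auc)


class TestConfusionRates:
    def test_sensitivity_arithmetic(self):
        r = confusion_rates(ConfusionCounts(TP=19, FN=1))
        assert r["sensitivity"] == pytest.approx(0.95)

    def test_fpr_arithmetic(self):
        r = confusion_rates(ConfusionCounts(FP=8, TN=52))
        assert r["fpr"] == pytest.approx(8 / 60)

    def test_perfect_specificity_bound(self):
        r = confusion_rates(ConfusionCounts(TP=1, FP=0, TN=10, FN=0))
        assert r["specificity"] == 1.0 and r["fpr"] == 0.0

    def test_zero_counts_are_nan_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="bcrcnn"):
            r = confusion_rates(ConfusionCounts())
        assert all(np.isnan(v) for v in r.values())
        assert caplog.records

    def test_complement_identities(self, rng):
        for _ in range(20):
            c = ConfusionCounts(*(int(x) for x in rng.integers(1, 50, 4)))
            r = confusion_rates(c)
            assert r["sensitivity"] + c.FN / (c.TP + c.FN) == pytest.approx(1.0)
            assert r["fpr"] + r["specificity"] == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1)


def make_records_and_detections(rng, n_images=8, drop=0.2, jitter=3.0):
    """Random ground truth plus jittered/dropped/spurious detections."""
    records, detections = [], []
    lesion = 0
    for i in range(n_images):
        anns = []
        for _ in range(int(rng.integers(1, 4))):
            x, y = rng.uniform(5, 70, 2)
            w, h = rng.uniform(8, 25, 2)
            label = int(rng.integers(1, 3))
            anns.append(LesionAnnotation(Box(x, y, x + w, y + h), label,
                                         f"L{lesion}"))
            lesion += 1
            if rng.uniform() > drop:
                d = np.array([x, y, x + w, y + h]) + rng.normal(0, jitter, 4)
                d[2] = max(d[2], d[0] + 1)
                d[3] = max(d[3], d[1] + 1)
                detections.append(Detection(f"img{i}", Box(*d), label,
                                            float(rng.uniform(0.1, 1.0))))
        if rng.uniform() < 0.5:  # spurious detection
            x, y = rng.uniform(5, 80, 2)
            detections.append(Detection(f"img{i}", Box(x, y, x + 10, y + 10),
                                        int(rng.integers(1, 3)),
                                        float(rng.uniform(0.1, 1.0))))
        records.append(VOCRecord(f"img{i}.png", (128, 128), anns))
        records[-1].image_path = f"img{i}.png"
    return records, detections


def ap_oracle(detections, records, label, iou_threshold=0.5):
    """Independent AP: explicit matching loop + rectangle-sum under the
    running-max precision envelope."""
    from bcrcnn.detector import iou as iou_fn
    gts = {}
    for rec in records:
        gts[rec.image_id] = [[a.box, False] for a in rec.annotations
                             if a.label == label]
    npos = sum(len(v) for v in gts.values())
    dets = sorted((d for d in detections if d.label == label),
                  key=lambda d: -d.score)
    flags = []
    for d in dets:
        cand = gts.get(d.image_id, [])
        ious = [iou_fn(d.box, b) if not used else -1 for b, used in cand]
        j = int(np.argmax(ious)) if ious else -1
        if j >= 0 and ious[j] >= iou_threshold:
            cand[j][1] = True
            flags.append(1)
        else:
            flags.append(0)
    # area under precision-envelope vs recall, rectangle by rectangle
    ap, matched = 0.0, 0
    precisions = [sum(flags[:k + 1]) / (k + 1) for k in range(len(flags))]
    for k, f in enumerate(flags):
        if f:
            env = max(precisions[k:])
            ap += env / npos
            matched += 1
    return ap


class TestAveragePrecision:
    def test_perfect_detections_give_ap_one(self, rng):
        records, _ = make_records_and_detections(rng, drop=2.0)
        detections = [Detection(rec.image_id, a.box, a.label,
                                float(rng.uniform(0.5, 1)))
                      for rec in records for a in rec.annotations]
        assert map50(detections, records) == pytest.approx(1.0)

    def test_no_detections_give_zero(self, rng):
        records, _ = make_records_and_detections(rng)
        labels = {a.label for r in records for a in r.annotations}
        for label in labels:
            assert average_precision_50([], records, label) == 0.0

    def test_matches_independent_oracle(self, rng):
        for trial in range(30):
            records, detections = make_records_and_detections(rng)
            for label in (BENIGN, MALIGNANT):
                try:
                    got = average_precision_50(detections, records, label)
                except ValueError:
                    continue   # no ground truth of this class
                want = ap_oracle(detections, records, label)
                assert got == pytest.approx(want, abs=1e-9)

    def test_class_without_ground_truth_raises(self):
        records = [VOCRecord("i.png", (64, 64), [
            LesionAnnotation(Box(0, 0, 10, 10), BENIGN, "L0")])]
        with pytest.raises(ValueError):
            average_precision_50([], records, MALIGNANT)


def auc_oracle(scores, labels):
    """O(n^2) pairwise comparisons, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores_give_half(self):
        _, auc = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == 0.5

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(30):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.uniform(0, 1, n), 2)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_roc_points_monotone(self, rng):
        scores = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        points, _ = roc_auc(scores, labels)
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestLesionLevelTally:
    def _fixture(self):
        """10 lesions with 2 planted mistakes: one missed malignant (L9 on
        both planes) and one benign lesion hit by a malignant detection
        (L2 axial); plus one stray malignant detection on img0_axial."""
        records, detections = [], []
        for i in range(10):
            label = MALIGNANT if i % 2 else BENIGN
            box = Box(10, 10, 30, 30)
            for plane in ("axial", "sagittal"):
                rec = VOCRecord(f"img{i}_{plane}.png", (64, 64), [
                    LesionAnnotation(box, label, f"L{i}",
                                     Plane(plane))])
                records.append(rec)
                hit = (label == MALIGNANT and i != 9) or (i == 2 and plane == "axial")
                if hit:
                    detections.append(Detection(f"img{i}_{plane}", box,
                                                MALIGNANT, 0.9))
        detections.append(Detection("img0_axial", Box(40, 40, 55, 55),
                                    MALIGNANT, 0.7))
        return records, detections

    def test_hand_enumerated_counts(self):
        records, detections = self._fixture()
        tally = lesion_level_tally(detections, records)
        # malignant lesions L1,L3,L5,L7,L9; L9 missed -> TP=4, FN=1.
        # benign lesions L0,L2,L4,L6,L8; L2 hit by a malignant detection
        # -> FP, the other four TN; the stray detection adds one more FP.
        assert tally.TP == 4
        assert tally.FN == 1
        assert tally.FP == 2
        assert tally.TN == 4

    def test_perfect_detections(self):
        records, _ = self._fixture()
        detections = [Detection(rec.image_id, a.box, MALIGNANT, 0.9)
                      for rec in records for a in rec.annotations
                      if a.label == MALIGNANT]
        tally = lesion_level_tally(detections, records)
        rates = confusion_rates(tally)
        assert rates["sensitivity"] == 1.0 and rates["fpr"] == 0.0

    def test_no_detections(self):
        records, _ = self._fixture()
        tally = lesion_level_tally([], records)
        rates = confusion_rates(tally)
        assert rates["sensitivity"] == 0.0 and rates["fpr"] == 0.0

    def test_unknown_image_rejected(self):
        records, _ = self._fixture()
        with pytest.raises(ValueError):
            lesion_level_tally([Detection("ghost", Box(0, 0, 5, 5),
                                          MALIGNANT, 0.9)], records)

    def test_stray_cluster_counts_once(self):
        records, _ = self._fixture()
        stray = [Detection("img0_axial", Box(40 + d, 40, 55 + d, 55),
                           MALIGNANT, 0.7) for d in (0.0, 2.0, 4.0)]
        tally = lesion_level_tally(stray, records)
        assert tally.FP == 1


GEOM = BreastGeometry(Y_mid=-64.0, x_Rmid=34.0, x_Lmid=94.0, x_mid=64.0,
                      axial_baseline=100.0, y_orientation=-1)


class TestBoxCenter:
    def test_midpoint(self):
        assert box_center(Box(0, 0, 10, 20)) == (5.0, 10.0)

    def test_point_box(self):
        assert box_center(Box(3, 4, 3, 4)) == (3.0, 4.0)

    def test_translation_equivariance(self):
        c = box_center(Box(2, 3, 8, 9))
        c2 = box_center(Box(12, 13, 18, 19))
        assert (c[0] + 10, c[1] + 10) == c2


def quadrant_oracle(y_sag_anat, x_ax, g):
    """Direct indicator evaluation with the documented tie conventions."""
    up = y_sag_anat > g.Y_mid
    outside = x_ax < g.x_Rmid or x_ax > g.x_Lmid
    table = {(True, True): "outside_up", (True, False): "outside_down",
             (False, True): "inside_up", (False, False): "inside_down"}
    return table[(outside, up)]


class TestLocateQuadrant:
    def test_printed_rule_examples(self):
        # anatomical y above midline, x left of right-breast midline
        assert locate_quadrant((0, 50), (20, 50), GEOM) \
            == QuadrantLabel.OUTSIDE_UP   # row 50 -> anat -50 > -64
        assert locate_quadrant((0, 80), (50, 50), GEOM) \
            == QuadrantLabel.INSIDE_DOWN  # row 80 -> anat -80 < -64

    def test_grid_matches_indicator_oracle(self):
        rows = np.linspace(0, 128, 100)
        xs = np.linspace(0, 128, 100)
        for r in rows:
            for x in xs:
                got = locate_quadrant((10.0, r), (x, 60.0), GEOM)
                want = quadrant_oracle(GEOM.anatomical_y(r), x, GEOM)
                assert got.value == want

    def test_boundary_ties_go_down_and_inside(self):
        assert locate_quadrant((0, 64.0), (64.0, 0), GEOM) \
            == QuadrantLabel.INSIDE_DOWN
        assert locate_quadrant((0, 64.0), (34.0, 0), GEOM) \
            == QuadrantLabel.INSIDE_DOWN
        assert locate_quadrant((0, 64.0), (94.0, 0), GEOM) \
            == QuadrantLabel.INSIDE_DOWN

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            BreastGeometry(Y_mid=0, x_Rmid=90.0, x_Lmid=30.0, x_mid=64.0)


class TestLaterality:
    def test_left_of_midline_is_left(self):
        assert laterality(GEOM.x_mid - 1, GEOM) == Laterality.LEFT

    def test_right_of_midline_is_right(self):
        assert laterality(GEOM.x_mid + 1, GEOM) == Laterality.RIGHT

    def test_tie_goes_right(self):
        assert laterality(GEOM.x_mid, GEOM) == Laterality.RIGHT

    def test_flip_flag_swaps(self):
        assert laterality(GEOM.x_mid - 1, GEOM, flip=True) == Laterality.RIGHT


class TestBuildCaseReport:
    def _det(self, image_id, box, label=MALIGNANT, score=0.9):
        return Detection(image_id, box, label, score)

    def test_phantom_truth_recovered_for_200_cases(self):
        """Reports built from the generator's own boxes agree with the
        stored quadrant and laterality ground truth."""
        from bcrcnn.phantom import PhantomSpec, generate_case
        spec = PhantomSpec(seed=101, n_cases=200)
        n_ok_q = n_ok_l = n = 0
        for i in range(200):
            case = generate_case(spec, i)
            sag = {a.lesion_id: a for a in case.sagittal_annotations}
            for ann in case.axial_annotations:
                rep = build_case_report(
                    ann.lesion_id,
                    self._det("ax", ann.box, ann.label),
                    self._det("sag", sag[ann.lesion_id].box, ann.label),
                    case.geometry)
                n += 1
                n_ok_q += rep.quadrant == case.true_quadrant[ann.lesion_id].value
                n_ok_l += rep.laterality == case.true_laterality[ann.lesion_id].value
        assert n >= 200
        assert n_ok_q / n >= 0.99
        assert n_ok_l / n >= 0.99

    def test_single_plane_detection_reports_that_plane(self):
        rep = build_case_report("L0", self._det("ax", Box(10, 10, 30, 30)),
                                None, GEOM)
        assert rep.detected and rep.quadrant is None
        assert rep.laterality is not None
        assert rep.diagnosis == "malignant"

    def test_undetected_lesion_flagged_not_benign(self):
        rep = build_case_report("L0", None, None, GEOM)
        assert not rep.detected and rep.diagnosis is None

    def test_fields_complete_for_detected_lesions(self):
        rep = build_case_report("L0", self._det("ax", Box(10, 10, 30, 30)),
                                self._det("sag", Box(20, 20, 40, 40)), GEOM)
        row = rep.as_row()
        for key in ("lesion_id", "laterality", "quadrant", "diagnosis",
                    "axial_x", "sagittal_y"):
            assert row[key] is not None
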
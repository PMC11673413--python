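"""Evaluation metrics and dual-plane 3D quadrant localization.

Detection quality is scored with the standard object-detection toolkit —
per-class average precision at IoU 0.5 (all-points precision envelope),
ROC/AUC via the Mann-Whitney rank statistic with ties counted one half —
plus lesion-level sensitivity and false-positive counts, where a lesion is
credited as found if any of its slices (either imaging plane) carries a
retained malignant detection overlapping the annotation at IoU >= 0.5.

Localization places each lesion into one of four breast quadrants
{outside, inside} x {up, down} from its sagittal-plane center (up/down
relative to the breast midline, in anatomical orientation where superior
is positive) and its axial-plane center (outside/inside relative to the
per-breast midlines), plus laterality from the axial center against the
midline between the two breasts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .dataset_io import (BENIGN, MALIGNANT, Box, LesionAnnotation, Plane,
                         VOCRecord, boxes_to_array)
from .detector import iou, iou_matrix

log = logging.getLogger("bcrcnn")


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_rates(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
    FPR FP/(FP+TN).  Undefined rates (zero denominator) are NaN with a
    warning."""
    def rate(num, den, name):
        if den == 0:
            log.warning("confusion_rates: %s undefined (zero denominator)", name)
            return float("nan")
        return num / den

    return {
        "sensitivity": rate(c.TP, c.TP + c.FN, "sensitivity"),
        "specificity": rate(c.TN, c.TN + c.FP, "specificity"),
        "precision": rate(c.TP, c.TP + c.FP, "precision"),
        "fpr": rate(c.FP, c.FP + c.TN, "fpr"),
    }


# ---------------------------------------------------------------------------
# detections container


@dataclass
class Detection:
    image_id: str
    box: Box
    label: int          # BENIGN or MALIGNANT
    score: float        # score of `label`
    plane: Plane = Plane.AXIAL
    lesion_id: str | None = None   # filled by matching, when known


# ---------------------------------------------------------------------------
# average precision


def average_precision_50(detections: list[Detection], records: list[VOCRecord],
                         label: int, iou_threshold: float = 0.5) -> float:
    """All-points-interpolated AP for one class at the given IoU threshold.

    Score-sorted detections greedily match the highest-IoU unmatched
    ground-truth box of the same class in their image.
    """
    gt_by_image: dict[str, list[LesionAnnotation]] = {}
    for rec in records:
        gt_by_image[rec.image_id] = [a for a in rec.annotations if a.label == label]
    npos = sum(len(v) for v in gt_by_image.values())
    if npos == 0:
        raise ValueError(f"no ground truth of class {label}; AP undefined")
    dets = sorted([d for d in detections if d.label == label],
                  key=lambda d: -d.score)
    matched: dict[str, np.ndarray] = {
        k: np.zeros(len(v), dtype=bool) for k, v in gt_by_image.items()}
    tp = np.zeros(len(dets))
    fp = np.zeros(len(dets))
    for i, det in enumerate(dets):
        gts = gt_by_image.get(det.image_id, [])
        best_iou, best_j = 0.0, -1
        for j, ann in enumerate(gts):
            v = iou(det.box, ann.box)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold and not matched[det.image_id][best_j]:
            matched[det.image_id][best_j] = True
            tp[i] = 1
        else:
            fp[i] = 1
    if len(dets) == 0:
        return 0.0
    ctp, cfp = np.cumsum(tp), np.cumsum(fp)
    recall = ctp / npos
    precision = ctp / np.maximum(ctp + cfp, 1e-12)
    # precision envelope over all recall points
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    changed = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[changed + 1] - mrec[changed]) * mpre[changed + 1]))


def map50(detections: list[Detection], records: list[VOCRecord],
          iou_threshold: float = 0.5) -> float:
    """Unweighted mean AP over the benign and malignant classes; classes
    without ground truth are excluded with a warning."""
    aps = []
    for label in (BENIGN, MALIGNANT):
        try:
            aps.append(average_precision_50(detections, records, label, iou_threshold))
        except ValueError:
            log.warning("map50: class %d has no ground truth, excluded", label)
    if not aps:
        raise ValueError("map50 undefined: no class has ground truth")
    return float(np.mean(aps))


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and AUC for binary labels.

    AUC is the normalized Mann-Whitney U statistic (ties count one half);
    the returned ROC points (fpr, tpr) are monotone non-decreasing.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    npos = int(labels.sum())
    nneg = int((~labels).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("roc_auc requires both classes present")
    from scipy.stats import rankdata
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - npos * (npos + 1) / 2) / (npos * nneg)
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    # one ROC point per distinct threshold
    distinct = np.where(np.diff(sorted_scores))[0]
    idx = np.concatenate([distinct, [len(sorted_scores) - 1]])
    points = np.concatenate([[[0.0, 0.0]],
                             np.stack([fps[idx] / nneg, tps[idx] / npos], axis=1)])
    return points, float(auc)


# ---------------------------------------------------------------------------
# lesion-level tally


def lesion_level_tally(detections: list[Detection], records: list[VOCRecord],
                       iou_threshold: float = 0.5) -> ConfusionCounts:
    """Lesion-level confusion counts from retained malignant detections.

    A malignant ground-truth lesion is TP when any of its slices carries a
    retained malignant detection at IoU >= threshold, else FN.  A benign
    lesion with such an overlapping malignant detection counts FP, else
    TN.  Malignant detections overlapping no annotation at all also count
    FP, capped at one per disjoint overlap cluster per image.
    """
    known_images = {rec.image_id for rec in records}
    for det in detections:
        if det.image_id not in known_images:
            raise ValueError(f"detection references unknown image {det.image_id!r}")
    ann_by_image: dict[str, list[LesionAnnotation]] = {
        rec.image_id: list(rec.annotations) for rec in records}
    lesion_labels: dict[str, int] = {}
    for rec in records:
        for ann in rec.annotations:
            lesion_labels[ann.lesion_id] = ann.label
    hit: set[str] = set()
    stray_by_image: dict[str, list[Box]] = {}
    for det in detections:
        if det.label != MALIGNANT:
            continue
        overlapped = False
        for ann in ann_by_image[det.image_id]:
            if iou(det.box, ann.box) >= iou_threshold:
                hit.add(ann.lesion_id)
                overlapped = True
        if not overlapped:
            stray_by_image.setdefault(det.image_id, []).append(det.box)
    counts = ConfusionCounts()
    for lesion_id, label in lesion_labels.items():
        found = lesion_id in hit
        if label == MALIGNANT:
            counts.TP += found
            counts.FN += not found
        else:
            counts.FP += found
            counts.TN += not found
    # stray detections: one FP per disjoint cluster per image
    for boxes in stray_by_image.values():
        arr = boxes_to_array(boxes)
        n = len(arr)
        adj = iou_matrix(arr, arr) > 0
        seen = np.zeros(n, dtype=bool)
        for i in range(n):
            if seen[i]:
                continue
            stack = [i]
            while stack:
                j = stack.pop()
                if seen[j]:
                    continue
                seen[j] = True
                stack.extend(np.where(adj[j] & ~seen)[0].tolist())
            counts.FP += 1
    return counts


# ---------------------------------------------------------------------------
# 3D quadrant localization


class QuadrantLabel(str, Enum):
    OUTSIDE_UP = "outside_up"
    OUTSIDE_DOWN = "outside_down"
    INSIDE_UP = "inside_up"
    INSIDE_DOWN = "inside_down"


class Laterality(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class BreastGeometry:
    """Midlines needed for four-quadrant localization.

    Y_mid is the sagittal breast midline in *anatomical* y (superior
    positive); y_orientation maps image rows to anatomical y
    (anatomical_y = y_orientation * row, -1 when superior lies at smaller
    row indices).  x_Rmid/x_Lmid are the axial midlines of the right/left
    breast and x_mid the midline between the breasts, all in image x.
    """

    Y_mid: float
    x_Rmid: float
    x_Lmid: float
    x_mid: float
    axial_baseline: float = 0.0
    y_orientation: int = -1

    def __post_init__(self):
        if not (self.x_Rmid < self.x_mid < self.x_Lmid):
            raise ValueError("geometry requires x_Rmid < x_mid < x_Lmid")

    def anatomical_y(self, row: float) -> float:
        return self.y_orientation * row


def box_center(b: Box) -> tuple[float, float]:
    """Arithmetic midpoint of the box corners."""
    return ((b.x_min + b.x_max) / 2.0, (b.y_min + b.y_max) / 2.0)


def locate_quadrant(sag_center: tuple[float, float],
                    ax_center: tuple[float, float],
                    g: BreastGeometry) -> QuadrantLabel:
    """Four-quadrant label from sagittal and axial ROI centers.

    up <=> anatomical y_sag > Y_mid (ties go down); outside <=> x_ax
    strictly left of x_Rmid or strictly right of x_Lmid (midline ties go
    inside).  Exactly one label holds for every point.
    """
    y_sag = g.anatomical_y(sag_center[1])
    x_ax = ax_center[0]
    up = y_sag > g.Y_mid
    outside = (x_ax < g.x_Rmid) or (x_ax > g.x_Lmid)
    if outside:
        return QuadrantLabel.OUTSIDE_UP if up else QuadrantLabel.OUTSIDE_DOWN
    return QuadrantLabel.INSIDE_UP if up else QuadrantLabel.INSIDE_DOWN


def laterality(x_ax: float, g: BreastGeometry, flip: bool = False) -> Laterality:
    """Left breast iff x_ax < x_mid, else right (x_ax == x_mid counts
    right).  `flip` swaps the convention for mirrored acquisitions."""
    left = x_ax < g.x_mid
    if flip:
        left = not left
    return Laterality.LEFT if left else Laterality.RIGHT


@dataclass
class CaseReport:
    """One flat per-lesion record: diagnosis, 3D quadrant and laterality."""

    lesion_id: str
    detected: bool
    laterality: str | None = None
    quadrant: str | None = None
    diagnosis: str | None = None
    axial_center: tuple[float, float] | None = None
    sagittal_center: tuple[float, float] | None = None
    axial_malignant_score: float | None = None
    sagittal_malignant_score: float | None = None

    def as_row(self) -> dict:
        row = {"lesion_id": self.lesion_id, "detected": self.detected,
               "laterality": self.laterality, "quadrant": self.quadrant,
               "diagnosis": self.diagnosis,
               "axial_malignant_score": self.axial_malignant_score,
               "sagittal_malignant_score": self.sagittal_malignant_score}
        for name, c in (("axial", self.axial_center), ("sagittal", self.sagittal_center)):
            row[f"{name}_x"] = None if c is None else c[0]
            row[f"{name}_y"] = None if c is None else c[1]
        return row


def build_case_report(lesion_id: str,
                      axial: Detection | None,
                      sagittal: Detection | None,
                      g: BreastGeometry,
                      malignant_threshold: float = 0.5) -> CaseReport:
    """Combine the two planes of one lesion into a report.

    A plane calls the lesion malignant when its retained detection is
    malignant with score above the threshold; the lesion diagnosis is the
    OR over available planes.  The quadrant needs both planes; laterality
    needs only the axial center.  With no detection in either plane the
    lesion is reported undetected (not benign).
    """
    if axial is None and sagittal is None:
        return CaseReport(lesion_id=lesion_id, detected=False)

    def malignant_score(det: Detection | None) -> float | None:
        if det is None:
            return None
        return det.score if det.label == MALIGNANT else 0.0

    ax_score = malignant_score(axial)
    sag_score = malignant_score(sagittal)
    is_mal = any(s is not None and s > malignant_threshold
                 for s in (ax_score, sag_score))
    report = CaseReport(
        lesion_id=lesion_id, detected=True,
        diagnosis="malignant" if is_mal else "benign",
        axial_center=box_center(axial.box) if axial else None,
        sagittal_center=box_center(sagittal.box) if sagittal else None,
        axial_malignant_score=ax_score,
        sagittal_malignant_score=sag_score,
    )
    if report.axial_center is not None:
        report.laterality = laterality(report.axial_center[0], g).value
    if report.axial_center is not None and report.sagittal_center is not None:
        report.quadrant = locate_quadrant(report.sagittal_center,
                                          report.axial_center, g).value
    return report
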
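"""The package's built-in desk-scale study: phantom dataset -> training ->
detection, diagnosis and 3D localization metrics.

The study conditions are fixed: 145 dual-plane phantom cases at 128x128
(100 train / 15 val / 30 test, i.e. 200 training slices), the `tiny`
backbone with a 24-channel feature pyramid, and 15 epochs of batch-1 SGD.
The learning rate (0.01) is the desk-scale counterpart of the full-scale
recipe's 1e-5, which presumes an ImageNet-pretrained VGG16; a randomly
initialized tiny backbone needs a correspondingly larger step.
"""
from __future__ import annotations

import logging
import tempfile
from pathlib import Path

import pandas as pd

from . import pdn
from .dataset_io import MALIGNANT, RunConfig, load_split
from .detector import iou
from .eval3d import (BreastGeometry, CaseReport, Detection, build_case_report,
                     confusion_rates, lesion_level_tally, map50, roc_auc)
from .phantom import PhantomSpec, generate_dataset, load_geometry_table

log = logging.getLogger("bcrcnn")

STUDY_N_CASES = 145
STUDY_SPLIT = (100, 15, 30)
STUDY_IMAGE_SIZE = (128, 128)
STUDY_EPOCHS = 15


def tiny_config(seed: int, **overrides) -> RunConfig:
    """The desk-scale configuration used by the built-in study."""
    kw = dict(backbone_preset="tiny", use_fpn=True, fpn_channels=24,
              fpn_base_scales=(16, 32, 64, 128, 256), short_side=128,
              learning_rate=0.01, epochs=STUDY_EPOCHS, seed=seed)
    kw.update(overrides)
    return RunConfig(**kw)


def study_spec(seed: int) -> PhantomSpec:
    return PhantomSpec(seed=seed, n_cases=STUDY_N_CASES,
                       image_size=STUDY_IMAGE_SIZE)


def build_reports(detections: list[Detection], manifest: pd.DataFrame,
                  geometries: dict[str, BreastGeometry], records: dict,
                  iou_threshold: float = 0.5,
                  malignant_threshold: float = 0.5) -> list[CaseReport]:
    """Match retained detections to annotated lesions and build one
    dual-plane case report per lesion."""
    by_image: dict[str, list[Detection]] = {}
    for d in detections:
        by_image.setdefault(d.image_id, []).append(d)
    reports = []
    for lesion_id, group in manifest.groupby("lesion_id"):
        case = group["case"].iloc[0]
        per_plane: dict[str, Detection | None] = {}
        for _, row in group.iterrows():
            rec = records.get(row["image_id"])
            if rec is None:
                continue
            gt = next((a for a in rec.annotations if a.lesion_id == lesion_id), None)
            if gt is None:
                continue
            best, best_iou = None, 0.0
            for d in by_image.get(row["image_id"], []):
                v = iou(d.box, gt.box)
                if v >= iou_threshold and v > best_iou:
                    best, best_iou = d, v
            per_plane[row["plane"]] = best
        reports.append(build_case_report(
            lesion_id, per_plane.get("axial"), per_plane.get("sagittal"),
            geometries[case], malignant_threshold))
    return reports


def run_study(seed: int, data_dir: str | Path | None = None,
              epochs: int = STUDY_EPOCHS) -> dict:
    """Generate the phantom dataset, train, and measure everything.

    Returns a flat dict of the study's headline numbers: loss decrease,
    lesion-level sensitivity and false-positive rate, slice-level
    benign/malignant AUC, mAP50, and quadrant/laterality agreement of
    detected lesions with the generator's ground truth.
    """
    own_dir = data_dir is None
    if own_dir:
        data_dir = tempfile.mkdtemp(prefix="bcrcnn_study_")
    data_dir = Path(data_dir)
    spec = study_spec(seed)
    manifest = generate_dataset(spec, data_dir, split_counts=STUDY_SPLIT)
    cfg = tiny_config(seed + 1, epochs=epochs)
    result = pdn.train(cfg, data_dir)

    records = load_split(data_dir, "test")
    diagnoses, detections = pdn.diagnose_slices(result.model, records)

    tally = lesion_level_tally(detections, records)
    rates = confusion_rates(tally)
    slice_scores = [d.malignant_score for d in diagnoses]
    slice_labels = [any(a.label == MALIGNANT for a in r.annotations)
                    for r in records]
    _, auc = roc_auc(slice_scores, slice_labels)

    test_manifest = manifest[manifest["split"] == "test"]
    geometries = load_geometry_table(data_dir)
    reports = build_reports(detections, test_manifest, geometries,
                            {r.image_id: r for r in records},
                            malignant_threshold=cfg.malignant_threshold)
    truth_q = dict(zip(test_manifest["lesion_id"], test_manifest["quadrant"]))
    truth_l = dict(zip(test_manifest["lesion_id"], test_manifest["laterality"]))
    located = [r for r in reports if r.detected and r.quadrant is not None]
    q_ok = sum(r.quadrant == truth_q[r.lesion_id] for r in located)
    l_ok = sum(r.laterality == truth_l[r.lesion_id] for r in located)

    history = result.history
    metrics = {
        "first_epoch_loss": float(history["total"].iloc[0]),
        "final_epoch_loss": float(history["total"].iloc[-1]),
        "loss_decreased": bool(history["total"].iloc[-1] < history["total"].iloc[0]),
        "lesion_sensitivity": rates["sensitivity"],
        "lesion_fpr": rates["fpr"],
        "slice_auc": float(auc),
        "map50": map50(detections, records),
        "n_test_lesions": int(test_manifest["lesion_id"].nunique()),
        "n_located": len(located),
        "quadrant_accuracy": q_ok / len(located) if located else float("nan"),
        "laterality_accuracy": l_ok / len(located) if located else float("nan"),
        "tally": {"TP": tally.TP, "FP": tally.FP, "TN": tally.TN, "FN": tally.FN},
    }
    log.info("study metrics: %s", metrics)
    return metrics
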
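"""Second-stage precise deep network (PDN), the composite loss, and the
training loop.

The PDN refines each first-stage ROI with the regression parameters of its
highest-scoring class, re-pools the refined box from the P2-P4 pyramid
levels (size bins: sqrt(area) < 64 -> P2, 64..128 -> P3, > 128 -> P4) with
a 7x7 ROI align, passes it through three extra channel-preserving 3x3 conv
layers that share no weights with the detection head, and classifies with
a final fully connected layer into background / benign / malignant.  A
candidate is retained as a malignant positive when its malignant score
strictly exceeds the threshold (0.5 by default); benign detections use the
same rule symmetrically.

The training objective is the sum of five terms:

    total = rpn_cls + rpn_loc + roi_cls + roi_loc + pdn_cls

with binary cross-entropy for RPN objectness, K-way cross-entropy for the
ROI and PDN classifiers (the PDN term is computed on *refined* boxes),
and smooth-L1 on encoded deltas for positive samples only.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .dataset_io import (BACKGROUND, BENIGN, MALIGNANT, Box, RunConfig,
                         VOCRecord, boxes_to_array,
                         load_split, read_image)
from .detector import (FPN, AnchorGrid, DetectionHead, DetectionHeadOutput,
                       FeaturePyramid, ProposalSet, RPNHead,
                       anchor_shapes_for_level, assign_fpn_level,
                       build_anchor_grid, clip_boxes, decode_deltas,
                       detection_head, encode_deltas, iou_matrix,
                       make_backbone, nms, pad_to_multiple, propose,
                       roi_align_stack, single_level_shapes)
from .eval3d import Detection
from .preprocess import RawImage, estimate_background, subtract_background

log = logging.getLogger("bcrcnn")

PIXEL_SCALE = 128.0  # raw intensities are divided by this before the backbone


# ---------------------------------------------------------------------------
# data types


@dataclass
class DetectionCandidate:
    """One ROI through both stages: first-stage scores and deltas, the
    class-conditionally refined box, and the final PDN scores."""

    proposal: Box
    roi_scores: np.ndarray     # (K,)
    roi_deltas: np.ndarray     # (4K,)
    first_label: int
    refined_box: Box
    pdn_scores: np.ndarray     # (K,)
    final_label: int


@dataclass(frozen=True)
class LossBreakdown:
    rpn_cls_loss: float
    rpn_loc_loss: float
    roi_cls_loss: float
    roi_loc_loss: float
    pdn_cls_loss: float
    total: float

    @classmethod
    def from_terms(cls, rpn_cls, rpn_loc, roi_cls, roi_loc, pdn_cls):
        terms = [float(np.asarray(x).reshape(-1)[0])
                 for x in (rpn_cls, rpn_loc, roi_cls, roi_loc, pdn_cls)]
        return cls(*terms, total=sum(terms))


@dataclass
class SliceDiagnosis:
    """Per-slice verdict: retained detections and the malignant flag."""

    image_id: str
    plane: str
    detections: list[Detection]
    malignant_threshold: float = 0.5
    slice_malignant: bool = field(init=False)
    malignant_score: float = 0.0   # max malignant probability over candidates

    def __post_init__(self):
        self.slice_malignant = any(
            d.label == MALIGNANT and d.score > self.malignant_threshold
            for d in self.detections)


# ---------------------------------------------------------------------------
# class-conditional refinement and level binning


def refine_rois(head_out: DetectionHeadOutput, proposals: ProposalSet,
                image_size: tuple[float, float]
                ) -> tuple[np.ndarray, np.ndarray]:
    """Refine each proposal with the deltas of its argmax class.

    Returns (first_labels (N,), refined_boxes (N,4)).  Background-labelled
    candidates keep their proposal box unchanged; ties in the argmax break
    toward the lower class index.
    """
    scores = np.asarray(head_out.roi_scores)
    deltas = np.asarray(head_out.roi_deltas)
    n, k = scores.shape
    labels = scores.argmax(axis=1)
    refined = proposals.boxes.copy()
    fg = labels != BACKGROUND
    if fg.any():
        rows = np.where(fg)[0]
        cols = (labels[rows, None] * 4 + np.arange(4)[None, :])
        sel = deltas[rows[:, None], cols]
        refined[rows] = decode_deltas(proposals.boxes[rows], sel, image_size)
    return labels, refined


def assign_pdn_level(box: Box | np.ndarray) -> str:
    """Size bin of a refined ROI: sqrt(w*h) < 64 -> P2, 64..128 (inclusive)
    -> P3, > 128 -> P4."""
    b = box.as_array() if isinstance(box, Box) else np.asarray(box, dtype=np.float64)
    w, h = b[2] - b[0], b[3] - b[1]
    if w <= 0 or h <= 0:
        raise ValueError("assign_pdn_level requires a positive-area box")
    size = np.sqrt(w * h)
    if size < 64.0:
        return "P2"
    if size <= 128.0:
        return "P3"
    return "P4"


# ---------------------------------------------------------------------------
# PDN network


class PDNNetwork(nn.Module):
    """Three channel-preserving 3x3 conv layers plus one final FCL.

    Weights are independent of the detection head; the convs specialize
    the pooled features for classification before the K-way softmax.
    """

    num_extra_convs = 3

    def __init__(self, channels: int, num_classes: int, pooled_size: int,
                 rng: np.random.Generator):
        self.convs = [nn.Conv2d(channels, channels, 3, rng)
                      for _ in range(self.num_extra_convs)]
        self.fc = nn.Linear(channels * pooled_size * pooled_size, num_classes,
                            rng, std=0.01)

    def extract(self, pooled: "nn.Tensor") -> "nn.Tensor":
        h = pooled
        for conv in self.convs:
            h = nn.relu(conv(h))
        return h

    def classify(self, feats: "nn.Tensor") -> "nn.Tensor":
        n = feats.shape[0]
        return self.fc(nn.reshape(feats, (n, -1)))


def pdn_features(pyramid: FeaturePyramid, refined_boxes: np.ndarray,
                 net: PDNNetwork, pooled_size: int = 7) -> "nn.Tensor":
    """Pool each refined box from its size-binned pyramid level (7x7 ROI
    align) and run the three extra conv layers.  Gradients flow into the
    pyramid features; box coordinates are constants."""
    refined_boxes = np.asarray(refined_boxes, dtype=np.float64).reshape(-1, 4)
    n = refined_boxes.shape[0]
    names = pyramid.names
    if len(names) == 1:
        levels = [names[0]] * n
    else:
        levels = [assign_pdn_level(b) for b in refined_boxes]
    order = []
    chunks = []
    for name in sorted(set(levels)):
        idx = [i for i, lv in enumerate(levels) if lv == name]
        order.extend(idx)
        feat, stride = pyramid.levels[name]
        chunks.append(roi_align_stack(feat, stride, refined_boxes[idx],
                                      pooled_size))
    stacked = chunks[0] if len(chunks) == 1 else nn.concat(chunks, axis=0)
    inverse = np.argsort(np.asarray(order))
    pooled = nn.take_rows(stacked, inverse)
    return net.extract(pooled)


def pdn_classify(feats: "nn.Tensor", net: PDNNetwork, refined_boxes: np.ndarray,
                 malignant_threshold: float = 0.5, nms_threshold: float = 0.3
                 ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, Box, int, float]]]:
    """Final classification of refined candidates.

    Returns (pdn_scores (N,K), final_labels (N,), retained) where retained
    is a list of (candidate_index, box, label, score) for detections whose
    argmax class is a lesion class with score strictly above the
    threshold, after class-wise NMS.
    """
    logits = net.classify(feats)
    scores = nn.softmax(logits.data.astype(np.float64), axis=1)
    labels = scores.argmax(axis=1)
    retained: list[tuple[int, Box, int, float]] = []
    boxes = np.asarray(refined_boxes, dtype=np.float64).reshape(-1, 4)
    for cls in (BENIGN, MALIGNANT):
        idx = np.where((labels == cls) & (scores[:, cls] > malignant_threshold))[0]
        if len(idx) == 0:
            continue
        keep = nms(boxes[idx], scores[idx, cls], nms_threshold)
        for j in keep:
            i = int(idx[j])
            retained.append((i, Box(*boxes[i]), cls, float(scores[i, cls])))
    retained.sort(key=lambda t: -t[3])
    return scores, labels, retained


# ---------------------------------------------------------------------------
# losses


@dataclass
class LossInputs:
    """Sampled predictions (probability space) and their targets.

    Probability entries may be autodiff tensors (training) or plain
    arrays (testing); loc entries hold encoded-delta predictions for the
    positive samples only, with `*_norm` the sample counts used as
    normalizers.
    """

    rpn_obj_probs: object          # (S,) P(foreground)
    rpn_obj_targets: np.ndarray    # (S,) in {0, 1}
    rpn_loc_pred: object           # (P, 4) encoded deltas
    rpn_loc_targets: np.ndarray
    rpn_loc_norm: float
    roi_cls_probs: object          # (R, K)
    roi_cls_targets: np.ndarray    # (R,)
    roi_loc_pred: object           # (Q, 4)
    roi_loc_targets: np.ndarray
    roi_loc_norm: float
    pdn_cls_probs: object          # (R2, K)
    pdn_cls_targets: np.ndarray


def compute_losses(inputs: LossInputs) -> tuple[LossBreakdown, "nn.Tensor"]:
    """The five-term composite loss and its scalar total (for backward).

    Perfect predictions (one-hot correct scores, exact boxes) yield an
    exactly zero breakdown; empty positive sets zero the loc terms.
    """
    zero = nn.Tensor(np.zeros(()))

    def loc_term(pred, target, norm, name):
        pred_t = nn.as_tensor(pred)
        if pred_t.data.size == 0:
            log.info("compute_losses: no positive samples for %s, term is 0", name)
            return zero
        return nn.smooth_l1(pred_t, target, normalizer=max(norm, 1.0))

    rpn_cls = nn.bce_probs(inputs.rpn_obj_probs, inputs.rpn_obj_targets)
    rpn_loc = loc_term(inputs.rpn_loc_pred, inputs.rpn_loc_targets,
                       inputs.rpn_loc_norm, "rpn_loc")
    roi_cls = nn.nll_loss(inputs.roi_cls_probs, inputs.roi_cls_targets)
    roi_loc = loc_term(inputs.roi_loc_pred, inputs.roi_loc_targets,
                       inputs.roi_loc_norm, "roi_loc")
    pdn_cls = nn.nll_loss(inputs.pdn_cls_probs, inputs.pdn_cls_targets)
    total = nn.add(nn.add(nn.add(nn.add(rpn_cls, rpn_loc), roi_cls), roi_loc),
                   pdn_cls)
    breakdown = LossBreakdown.from_terms(
        rpn_cls.data, rpn_loc.data, roi_cls.data, roi_loc.data, pdn_cls.data)
    return breakdown, total


# ---------------------------------------------------------------------------
# target assignment and sampling


def _sample_balanced(pos: np.ndarray, neg: np.ndarray, batch: int,
                     pos_fraction: float, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Subsample positives/negatives to at most `batch` with a positive cap."""
    max_pos = int(batch * pos_fraction)
    if len(pos) > max_pos:
        pos = rng.choice(pos, size=max_pos, replace=False)
    n_neg = min(len(neg), batch - len(pos))
    if len(neg) > n_neg:
        neg = rng.choice(neg, size=n_neg, replace=False)
    return np.sort(pos), np.sort(neg)


def assign_anchor_targets(anchors: np.ndarray, gt_boxes: np.ndarray,
                          cfg: RunConfig, rng: np.random.Generator):
    """RPN training targets: sampled anchor indices, objectness targets,
    positive indices and their encoded deltas.

    Positives: IoU >= iou_threshold with any ground truth, plus the best
    anchor of each ground-truth box.  Negatives: IoU < negative_iou.
    """
    if len(gt_boxes) == 0:
        neg = rng.choice(len(anchors), size=min(cfg.rpn_batch_size, len(anchors)),
                         replace=False)
        neg = np.sort(neg)
        return neg, np.zeros(len(neg)), np.empty(0, np.intp), np.empty((0, 4))
    ious = iou_matrix(anchors, gt_boxes)
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(len(anchors)), best_gt]
    pos_mask = best_iou >= cfg.iou_threshold
    # guarantee each ground truth its best-matching anchor
    per_gt_best = ious.argmax(axis=0)
    pos_mask[per_gt_best[ious.max(axis=0) > 0]] = True
    neg_mask = best_iou < cfg.negative_iou
    neg_mask &= ~pos_mask
    pos, neg = _sample_balanced(np.where(pos_mask)[0], np.where(neg_mask)[0],
                                cfg.rpn_batch_size, cfg.positive_fraction, rng)
    sampled = np.concatenate([pos, neg])
    obj_targets = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    delta_targets = (encode_deltas(anchors[pos], gt_boxes[best_gt[pos]])
                     if len(pos) else np.empty((0, 4)))
    return sampled, obj_targets, pos.astype(np.intp), delta_targets


def assign_roi_targets(proposals: np.ndarray, gt_boxes: np.ndarray,
                       gt_labels: np.ndarray, cfg: RunConfig,
                       rng: np.random.Generator):
    """ROI-head training targets over (proposals + appended ground truth).

    Returns (sampled indices, class labels, positive positions within the
    sample, encoded deltas to the matched ground truth).
    """
    if len(gt_boxes) == 0:
        idx = rng.choice(len(proposals), size=min(cfg.roi_batch_size, len(proposals)),
                         replace=False)
        idx = np.sort(idx)
        return idx, np.zeros(len(idx), np.intp), np.empty(0, np.intp), np.empty((0, 4))
    ious = iou_matrix(proposals, gt_boxes)
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(len(proposals)), best_gt]
    pos_mask = best_iou >= cfg.iou_threshold
    pos, neg = _sample_balanced(np.where(pos_mask)[0], np.where(~pos_mask)[0],
                                cfg.roi_batch_size, cfg.positive_fraction, rng)
    sampled = np.concatenate([pos, neg])
    labels = np.zeros(len(sampled), dtype=np.intp)
    labels[:len(pos)] = gt_labels[best_gt[pos]]
    deltas = (encode_deltas(proposals[pos], gt_boxes[best_gt[pos]])
              if len(pos) else np.empty((0, 4)))
    return sampled, labels, np.arange(len(pos), dtype=np.intp), deltas


def _labels_for_boxes(boxes: np.ndarray, gt_boxes: np.ndarray,
                      gt_labels: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Class target of each box: matched ground-truth class at
    IoU >= threshold, else background."""
    out = np.zeros(len(boxes), dtype=np.intp)
    if len(gt_boxes) == 0 or len(boxes) == 0:
        return out
    ious = iou_matrix(boxes, gt_boxes)
    best = ious.argmax(axis=1)
    hit = ious[np.arange(len(boxes)), best] >= iou_threshold
    out[hit] = gt_labels[best[hit]]
    return out


def _gather_rows_cols(x: "nn.Tensor", rows: np.ndarray, cols: np.ndarray
                      ) -> "nn.Tensor":
    """x[rows[i], cols[i, j]] -> (len(rows), cols.shape[1]) with gradients."""
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    out = x.data[rows[:, None], cols]

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (rows[:, None], cols), g)
        return (gx,)

    return nn.Tensor(out, (x,), bwd)


# ---------------------------------------------------------------------------
# the assembled two-stage model


class BCRCNN(nn.Module):
    """Backbone + (optional) FPN + RPN + detection head + PDN."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.backbone = make_backbone(cfg.backbone_preset, rng)
        if cfg.use_fpn:
            self.fpn = FPN(self.backbone.stage_channels, cfg.fpn_channels, rng)
            feat_ch = cfg.fpn_channels
            self.num_shapes = 6   # two neighbour scales x three ratios
        else:
            self.fpn = None
            feat_ch = self.backbone.stage_channels["C4"]
            self.num_shapes = 9   # three scales x three ratios
        self.feat_channels = feat_ch
        self.rpn = RPNHead(feat_ch, self.num_shapes, rng)
        self.head = DetectionHead(feat_ch * cfg.pooled_size ** 2,
                                  cfg.num_classes, rng)
        self.pdn = PDNNetwork(feat_ch, cfg.num_classes, cfg.pooled_size, rng)

    # -- feature extraction ------------------------------------------------

    def extract_pyramid(self, pixels: np.ndarray) -> FeaturePyramid:
        padded = pad_to_multiple(np.asarray(pixels, dtype=np.float64), 32)
        x = nn.Tensor(padded[None, None] / PIXEL_SCALE)
        stages = self.backbone.forward_stages(x)
        if self.fpn is not None:
            return self.fpn.forward(stages)
        return FeaturePyramid({"C4": (stages["C4"], self.backbone.terminal_stride)})

    def rpn_levels(self, pyramid: FeaturePyramid) -> list[str]:
        return pyramid.names  # P2..P6 in pyramid mode, the single map otherwise

    def pooling_levels(self, pyramid: FeaturePyramid) -> list[str]:
        names = pyramid.names
        return [n for n in names if n != "P6"] if len(names) > 1 else names

    def anchor_grid_for(self, pyramid: FeaturePyramid, name: str) -> AnchorGrid:
        feat, stride = pyramid.levels[name]
        fh, fw = feat.shape[2], feat.shape[3]
        if self.fpn is not None:
            k = int(name[1])
            base = self.cfg.fpn_base_scales[k - 2]
            shapes = anchor_shapes_for_level(base)
        else:
            shapes = single_level_shapes(self.cfg.anchor_scales)
        return build_anchor_grid((fh, fw), stride, shapes=shapes)

    def _rpn_forward_all(self, pyramid: FeaturePyramid):
        objs, regs, anchors = [], [], []
        for name in self.rpn_levels(pyramid):
            obj, reg = self.rpn.forward(pyramid.feature(name))
            objs.append(obj)
            regs.append(reg)
            anchors.append(self.anchor_grid_for(pyramid, name).anchors)
        return (nn.concat(objs, axis=0), nn.concat(regs, axis=0),
                np.concatenate(anchors, axis=0))

    def _pool_detection(self, pyramid: FeaturePyramid, boxes: np.ndarray
                        ) -> "nn.Tensor":
        """ROI-align boxes from their assigned pyramid level (canonical
        size 160, k0=4) for the detection head."""
        names = self.pooling_levels(pyramid)
        if len(names) == 1:
            feat, stride = pyramid.levels[names[0]]
            return roi_align_stack(feat, stride, boxes, self.cfg.pooled_size)
        levels = [f"P{assign_fpn_level(b, self.cfg.canonical_roi_size)}"
                  for b in boxes]
        order, chunks = [], []
        for name in sorted(set(levels)):
            idx = [i for i, lv in enumerate(levels) if lv == name]
            order.extend(idx)
            feat, stride = pyramid.levels[name]
            chunks.append(roi_align_stack(feat, stride, boxes[idx],
                                          self.cfg.pooled_size))
        stacked = chunks[0] if len(chunks) == 1 else nn.concat(chunks, axis=0)
        return nn.take_rows(stacked, np.argsort(np.asarray(order)))

    # -- training ----------------------------------------------------------

    def forward_train(self, pixels: np.ndarray, gt_boxes: np.ndarray,
                      gt_labels: np.ndarray, rng: np.random.Generator
                      ) -> tuple[LossBreakdown, "nn.Tensor"]:
        cfg = self.cfg
        h, w = pixels.shape
        image_size = (float(w), float(h))
        pyramid = self.extract_pyramid(pixels)
        obj_t, reg_t, anchors = self._rpn_forward_all(pyramid)

        # RPN targets
        sampled, obj_targets, pos_idx, rpn_delta_targets = assign_anchor_targets(
            anchors, gt_boxes, cfg, rng)
        rpn_obj_probs = nn.sigmoid_t(nn.take_rows(obj_t, sampled))
        rpn_loc_pred = nn.take_rows(reg_t, pos_idx)

        # proposals (no gradient through boxes) + appended ground truth
        prop = propose(obj_t.data, reg_t.data, anchors, image_size, cfg)
        cand_boxes = prop.boxes[:prop.n_valid]
        if len(gt_boxes):
            cand_boxes = np.concatenate([cand_boxes, gt_boxes])
        roi_idx, roi_labels, roi_pos, roi_delta_targets = assign_roi_targets(
            cand_boxes, gt_boxes, gt_labels, cfg, rng)
        roi_boxes = cand_boxes[roi_idx]

        pooled = self._pool_detection(pyramid, roi_boxes)
        cls_logits, delta_t = self.head.forward(pooled)
        roi_cls_probs = nn.softmax_t(cls_logits)
        # class-conditional deltas of the positives' target class
        pos_classes = roi_labels[roi_pos]
        cols = pos_classes[:, None] * 4 + np.arange(4)[None, :]
        roi_loc_pred = _gather_rows_cols(delta_t, roi_pos, cols)

        # PDN on refined boxes (boxes are constants; features carry grads)
        head_out = DetectionHeadOutput(
            roi_scores=nn.softmax(cls_logits.data.astype(np.float64), axis=1),
            roi_deltas=delta_t.data.astype(np.float64))
        _, refined = refine_rois(
            head_out, ProposalSet(roi_boxes, np.zeros(len(roi_boxes)),
                                  len(roi_boxes)), image_size)
        refined = _ensure_min_size(refined, image_size)
        pdn_labels = _labels_for_boxes(refined, gt_boxes, gt_labels,
                                       cfg.iou_threshold)
        feats = pdn_features(pyramid, refined, self.pdn, cfg.pooled_size)
        pdn_probs = nn.softmax_t(self.pdn.classify(feats))

        inputs = LossInputs(
            rpn_obj_probs=rpn_obj_probs, rpn_obj_targets=obj_targets,
            rpn_loc_pred=rpn_loc_pred, rpn_loc_targets=rpn_delta_targets,
            rpn_loc_norm=len(sampled),
            roi_cls_probs=roi_cls_probs, roi_cls_targets=roi_labels,
            roi_loc_pred=roi_loc_pred, roi_loc_targets=roi_delta_targets,
            roi_loc_norm=len(roi_idx),
            pdn_cls_probs=pdn_probs, pdn_cls_targets=pdn_labels)
        return compute_losses(inputs)

    # -- inference ---------------------------------------------------------

    def predict(self, pixels: np.ndarray) -> tuple[list[DetectionCandidate],
                                                   list[tuple[int, Box, int, float]],
                                                   float]:
        """Full two-stage inference on one slice.

        Returns (all candidates, retained detections as (index, box, label,
        score), slice malignant score = max PDN malignant probability).
        """
        cfg = self.cfg
        h, w = pixels.shape
        image_size = (float(w), float(h))
        pyramid = self.extract_pyramid(pixels)
        obj_t, reg_t, anchors = self._rpn_forward_all(pyramid)
        prop = propose(obj_t.data, reg_t.data, anchors, image_size, cfg)
        pooled = self._pool_detection(pyramid, prop.boxes)
        head_out = detection_head(self.head, pooled)
        first_labels, refined = refine_rois(head_out, prop, image_size)
        refined = _ensure_min_size(refined, image_size)
        feats = pdn_features(pyramid, refined, self.pdn, cfg.pooled_size)
        pdn_scores, final_labels, retained = pdn_classify(
            feats, self.pdn, refined, cfg.malignant_threshold,
            cfg.detection_nms_threshold)
        candidates = [DetectionCandidate(
            proposal=Box(*prop.boxes[i]),
            roi_scores=head_out.roi_scores[i],
            roi_deltas=head_out.roi_deltas[i],
            first_label=int(first_labels[i]),
            refined_box=Box(*refined[i]),
            pdn_scores=pdn_scores[i],
            final_label=int(final_labels[i]))
            for i in range(len(prop.boxes))]
        slice_score = float(pdn_scores[:, MALIGNANT].max()) if len(pdn_scores) else 0.0
        return candidates, retained, slice_score


def _ensure_min_size(boxes: np.ndarray, image_size, min_side: float = 2.0
                     ) -> np.ndarray:
    """Expand degenerate refined boxes so ROI align stays well-posed."""
    out = clip_boxes(boxes, image_size)
    w, h = image_size
    for d, bound in ((0, w), (1, h)):
        lo, hi = out[:, d], out[:, d + 2]
        small = hi - lo < min_side
        if small.any():
            c = (lo[small] + hi[small]) / 2
            c = np.clip(c, min_side / 2, bound - min_side / 2)
            out[small, d] = c - min_side / 2
            out[small, d + 2] = c + min_side / 2
    return out


# ---------------------------------------------------------------------------
# dual-plane fusion


def fuse_dual_plane(axial: SliceDiagnosis | None,
                    sagittal: SliceDiagnosis | None) -> str:
    """Lesion-level verdict: malignant iff either plane is malignant;
    benign otherwise; 'undetected' when neither plane was evaluated."""
    if axial is None and sagittal is None:
        return "undetected"
    flags = [d.slice_malignant for d in (axial, sagittal) if d is not None]
    return "malignant" if any(flags) else "benign"


# ---------------------------------------------------------------------------
# preprocessing used by train/eval (phantom-scale: no rescale by default)


def _prepare_pixels(record: VOCRecord, short_side: int | None) -> np.ndarray:
    img = RawImage(read_image(record.image_path))
    img = subtract_background(img, estimate_background(img))
    if short_side is not None and min(img.shape) != short_side:
        from .preprocess import rescale_to_short_side
        img, _ = rescale_to_short_side(img, short_side)
    return img.pixels


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainResult:
    model: BCRCNN
    history: pd.DataFrame
    best_epoch: int


def train(cfg: RunConfig, data_dir: str | Path,
          checkpoint_path: str | Path | None = None,
          rescale: bool = False) -> TrainResult:
    """Batch-1 SGD training with per-epoch loss logging and best-on-
    validation checkpointing.

    The optimizer follows the configured recipe (momentum, weight decay,
    learning rate, epochs); every randomized step (shuffling, sampling)
    draws from a generator seeded by cfg.seed, so two runs with the same
    seed produce identical loss histories.
    """
    data_dir = Path(data_dir)
    train_records = load_split(data_dir, "train")
    if not train_records:
        raise ValueError("training split is empty")
    try:
        val_records = load_split(data_dir, "val")
    except FileNotFoundError:
        val_records = []
    rng = np.random.default_rng(cfg.seed)
    model = BCRCNN(cfg, np.random.default_rng(rng.integers(2 ** 31)))
    opt = nn.SGD(model.parameters(), lr=cfg.learning_rate,
                 momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    short_side = cfg.short_side if rescale else None
    cache = {r.image_id: (_prepare_pixels(r, short_side),
                          boxes_to_array([a.box for a in r.annotations]),
                          np.array([a.label for a in r.annotations], dtype=np.intp))
             for r in train_records + val_records}

    history_rows = []
    best_val = np.inf
    best_epoch = -1
    best_state = None
    terms = ("rpn_cls_loss", "rpn_loc_loss", "roi_cls_loss", "roi_loc_loss",
             "pdn_cls_loss", "total")
    for epoch in range(cfg.epochs):
        t0 = time.time()
        order = rng.permutation(len(train_records))
        sums = np.zeros(len(terms))
        for i in order:
            rec = train_records[i]
            pixels, gt_boxes, gt_labels = cache[rec.image_id]
            opt.zero_grad()
            breakdown, total = model.forward_train(pixels, gt_boxes, gt_labels, rng)
            total.backward()
            opt.step()
            sums += [getattr(breakdown, t) for t in terms]
        means = sums / len(train_records)
        row = dict(zip(terms, means))
        row["epoch"] = epoch
        # validation loss (forward only, fixed sampling stream)
        if val_records:
            vrng = np.random.default_rng(cfg.seed + 7919)
            vsum = 0.0
            for rec in val_records:
                pixels, gt_boxes, gt_labels = cache[rec.image_id]
                vb, _ = model.forward_train(pixels, gt_boxes, gt_labels, vrng)
                vsum += vb.total
            row["val_total"] = vsum / len(val_records)
        else:
            row["val_total"] = row["total"]
        history_rows.append(row)
        log.info("epoch=%d total=%.4f val_total=%.4f secs=%.1f",
                 epoch, row["total"], row["val_total"], time.time() - t0)
        if row["val_total"] < best_val:
            best_val = row["val_total"]
            best_epoch = epoch
            best_state = [p.data.copy() for p in model.parameters()]
    if best_state is not None:
        for p, s in zip(model.parameters(), best_state):
            p.data = s
    history = pd.DataFrame(history_rows)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return TrainResult(model=model, history=history, best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: BCRCNN, path: str | Path) -> None:
    """Flat named-array container with a config echo."""
    import json
    from dataclasses import asdict
    arrays = {name: t.data for name, t in model.named_parameters()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> BCRCNN:
    import json
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["__config__"]).decode())
    for key in ("anchor_scales", "fpn_base_scales", "lesions_per_case"):
        if key in cfg_dict and isinstance(cfg_dict[key], list):
            cfg_dict[key] = tuple(cfg_dict[key])
    cfg = RunConfig(**cfg_dict)
    model = BCRCNN(cfg)
    params = dict(model.named_parameters())
    for name in params:
        params[name].data = data[name].astype(np.float32)
    return model


# ---------------------------------------------------------------------------
# evaluation pipeline


def diagnose_slices(model: BCRCNN, records: list[VOCRecord],
                    rescale: bool = False) -> tuple[list[SliceDiagnosis],
                                                    list[Detection]]:
    """Run inference over records; returns per-slice diagnoses and the
    flat list of retained detections."""
    diagnoses = []
    detections = []
    short_side = model.cfg.short_side if rescale else None
    for rec in records:
        pixels = _prepare_pixels(rec, short_side)
        _, retained, slice_score = model.predict(pixels)
        plane = rec.annotations[0].plane.value if rec.annotations else "axial"
        dets = [Detection(image_id=rec.image_id, box=box, label=label,
                          score=score, plane=plane)
                for _, box, label, score in retained]
        diag = SliceDiagnosis(image_id=rec.image_id, plane=plane,
                              detections=dets,
                              malignant_threshold=model.cfg.malignant_threshold)
        diag.malignant_score = slice_score
        diagnoses.append(diag)
        detections.extend(dets)
    return diagnoses, detections
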
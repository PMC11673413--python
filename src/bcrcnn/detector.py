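"""First detection stage: box geometry, anchors, backbone, FPN, RPN,
proposal generation, ROI align, and the detection head.

All box arithmetic uses the package-wide half-open convention, so widths
and areas need no +1 terms.  Anchors are centered on feature-map cell
centers ((i+0.5)*stride) with the three aspect ratios 1:2, 1:1 and 2:1;
in pyramid mode each level carries two geometric neighbour scales
(s/sqrt2, s*sqrt2 -> 6 shapes per location) while the single-level
detector keeps the classic nine anchor shapes (3 scales x 3 ratios).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dataset_io import Box, RunConfig

RATIOS = (0.5, 1.0, 2.0)  # width/height: 1:2, 1:1, 2:1
FPN_LEVELS = ("P2", "P3", "P4", "P5", "P6")
FPN_STRIDES = {"P2": 4, "P3": 8, "P4": 16, "P5": 32, "P6": 64}


def _as_box_array(b) -> np.ndarray:
    if isinstance(b, Box):
        return b.as_array()
    return np.asarray(b, dtype=np.float64)


def iou(a, b) -> float:
    """Intersection-over-union of two half-open boxes; 0 for disjoint."""
    a, b = _as_box_array(a), _as_box_array(b)
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter <= 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return float(inter / (area_a + area_b - inter))


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N,4) vs (M,4) box arrays."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix = np.maximum(0.0, np.minimum(a[:, None, 2], b[None, :, 2])
                    - np.maximum(a[:, None, 0], b[None, :, 0]))
    iy = np.maximum(0.0, np.minimum(a[:, None, 3], b[None, :, 3])
                    - np.maximum(a[:, None, 1], b[None, :, 1]))
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def nms(boxes, scores, threshold: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, score-descending.

    Ties in score are broken by original index (lower index wins), which
    keeps the result deterministic.
    """
    arr = np.asarray([_as_box_array(b) for b in boxes], dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("nms threshold must lie in [0, 1]")
    order = np.lexsort((np.arange(len(scores)), -scores))
    kept: list[int] = []
    suppressed = np.zeros(len(scores), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(int(i))
        remaining = order[~suppressed[order]]
        ious = iou_matrix(arr[i:i + 1], arr[remaining])[0]
        suppressed[remaining[ious > threshold]] = True
        suppressed[i] = True
    return kept


def encode_deltas(anchors, targets) -> np.ndarray:
    """Parameterize targets relative to anchors as (tx, ty, tw, th).

    tx = (cx_t - cx_a)/w_a, ty likewise; tw = log(w_t/w_a), th likewise.
    Accepts single boxes or (N,4) arrays; returns matching shape.
    """
    a = _as_box_array(anchors).reshape(-1, 4)
    t = _as_box_array(targets).reshape(-1, 4)
    wa, ha = a[:, 2] - a[:, 0], a[:, 3] - a[:, 1]
    if np.any(wa <= 0) or np.any(ha <= 0):
        raise ValueError("anchors must have positive width and height")
    wt, ht = t[:, 2] - t[:, 0], t[:, 3] - t[:, 1]
    cxa, cya = a[:, 0] + wa / 2, a[:, 1] + ha / 2
    cxt, cyt = t[:, 0] + wt / 2, t[:, 1] + ht / 2
    out = np.stack([(cxt - cxa) / wa, (cyt - cya) / ha,
                    np.log(wt / wa), np.log(ht / ha)], axis=1)
    single = isinstance(anchors, Box) or _as_box_array(anchors).ndim == 1
    return out[0] if single else out


def decode_deltas(anchors, deltas, image_size: tuple[float, float] | None = None
                  ) -> np.ndarray:
    """Invert encode_deltas; optionally clip to (width, height) image bounds."""
    a = _as_box_array(anchors).reshape(-1, 4)
    d = np.asarray(deltas, dtype=np.float64).reshape(-1, 4)
    wa, ha = a[:, 2] - a[:, 0], a[:, 3] - a[:, 1]
    if np.any(wa <= 0) or np.any(ha <= 0):
        raise ValueError("anchors must have positive width and height")
    # algebraically identical to the center/size form, but written so that
    # zero deltas reproduce the anchor bit-exactly
    ew, eh = np.exp(d[:, 2]), np.exp(d[:, 3])
    out = np.stack([a[:, 0] + wa * (d[:, 0] + (1 - ew) / 2),
                    a[:, 1] + ha * (d[:, 1] + (1 - eh) / 2),
                    a[:, 2] + wa * (d[:, 0] + (ew - 1) / 2),
                    a[:, 3] + ha * (d[:, 1] + (eh - 1) / 2)], axis=1)
    if image_size is not None:
        out = clip_boxes(out, image_size)
    return out


def clip_boxes(boxes: np.ndarray, image_size: tuple[float, float]) -> np.ndarray:
    """Clip (N,4) boxes to [0, width] x [0, height]."""
    w, h = image_size
    out = np.asarray(boxes, dtype=np.float64).copy().reshape(-1, 4)
    out[:, [0, 2]] = np.clip(out[:, [0, 2]], 0.0, w)
    out[:, [1, 3]] = np.clip(out[:, [1, 3]], 0.0, h)
    return out


# ---------------------------------------------------------------------------
# anchors and pyramid bookkeeping


@dataclass
class AnchorGrid:
    anchors: np.ndarray            # (H*W*A, 4), location-major then shape
    shapes: list[tuple[float, float]]  # (scale, ratio) per shape
    feature_shape: tuple[int, int]
    stride: int


def anchor_shapes_for_level(base_scale: float) -> list[tuple[float, float]]:
    """The two geometric neighbour scales of a pyramid level, x 3 ratios."""
    return [(s, r) for s in (base_scale / math.sqrt(2), base_scale * math.sqrt(2))
            for r in RATIOS]


def single_level_shapes(scales) -> list[tuple[float, float]]:
    return [(float(s), r) for s in scales for r in RATIOS]


def build_anchor_grid(feature_shape: tuple[int, int], stride: int,
                      scales=None, ratios=RATIOS,
                      shapes: list[tuple[float, float]] | None = None) -> AnchorGrid:
    """Tile anchor boxes over a feature map.

    Either explicit `shapes` [(scale, ratio), ...] or `scales` x `ratios`
    may be given.  An anchor of (scale s, ratio r) has area s^2 and
    width/height = r, centered at ((col+0.5)*stride, (row+0.5)*stride).
    """
    if shapes is None:
        if scales is None or len(scales) == 0:
            raise ValueError("anchor scales must be non-empty")
        shapes = [(float(s), float(r)) for s in scales for r in ratios]
    h, w = feature_shape
    ws = np.array([s * math.sqrt(r) for s, r in shapes])
    hs = np.array([s / math.sqrt(r) for s, r in shapes])
    cy = (np.arange(h) + 0.5) * stride
    cx = (np.arange(w) + 0.5) * stride
    cyy, cxx = np.meshgrid(cy, cx, indexing="ij")
    centers = np.stack([cxx.ravel(), cyy.ravel()], axis=1)  # (H*W, 2)
    boxes = np.empty((h * w, len(shapes), 4), dtype=np.float64)
    boxes[:, :, 0] = centers[:, None, 0] - ws[None, :] / 2
    boxes[:, :, 1] = centers[:, None, 1] - hs[None, :] / 2
    boxes[:, :, 2] = centers[:, None, 0] + ws[None, :] / 2
    boxes[:, :, 3] = centers[:, None, 1] + hs[None, :] / 2
    return AnchorGrid(boxes.reshape(-1, 4), shapes, (h, w), stride)


@dataclass
class FeaturePyramid:
    """Named multi-resolution feature maps with per-level strides.

    `levels` maps level name -> (feature, stride); features may be raw
    arrays or autodiff tensors of shape (1, C, H, W).  Single-level mode
    holds one entry.
    """

    levels: dict[str, tuple[object, int]]

    def __post_init__(self):
        strides = [s for _, s in self.levels.values()]
        if len(strides) > 1:
            ordered = sorted(strides)
            for a, b in zip(ordered, ordered[1:]):
                if b != 2 * a:
                    raise ValueError(f"pyramid strides must double per level: {ordered}")

    def feature(self, name: str):
        return self.levels[name][0]

    def stride(self, name: str) -> int:
        return self.levels[name][1]

    @property
    def names(self) -> list[str]:
        return sorted(self.levels, key=lambda k: self.levels[k][1])


def assign_fpn_level(box: Box | np.ndarray, canonical_size: int = 160,
                     k0: int = 4) -> int:
    """Pyramid level for an ROI: k = clamp(floor(k0 + log2(sqrt(wh)/canonical)), 2, 5)."""
    b = _as_box_array(box)
    w, h = b[2] - b[0], b[3] - b[1]
    if w <= 0 or h <= 0:
        raise ValueError("assign_fpn_level requires a positive-area box")
    k = math.floor(k0 + math.log2(math.sqrt(w * h) / canonical_size))
    return int(min(5, max(2, k)))


# ---------------------------------------------------------------------------
# ROI align


def _bilinear_plan_many(boxes: np.ndarray, stride: float, fh: int, fw: int,
                        pooled: int, sampling: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour indices and weights for every bilinear sample of N ROIs.

    Returns idx (N*pooled^2*sampling^2, 4) into the flattened (fh*fw) map
    and matching weights, sample-major within each box.  Feature pixel
    (r, c) is treated as a point sample at continuous feature coordinate
    (c+0.5, r+0.5); samples sit on a regular sampling x sampling grid
    inside each bin.
    """
    b = np.asarray(boxes, dtype=np.float64).reshape(-1, 4) / stride
    n = b.shape[0]
    bw = (b[:, 2] - b[:, 0]) / pooled
    bh = (b[:, 3] - b[:, 1]) / pooled
    off = (np.arange(sampling) + 0.5) / sampling
    grid = (np.arange(pooled)[:, None] + off[None, :]).ravel()   # (P*S,)
    xs = b[:, 0, None] + grid[None, :] * bw[:, None]             # (N, P*S)
    ys = b[:, 1, None] + grid[None, :] * bh[:, None]
    # bin-major sample coordinates (N, P_i, P_j, S_s, S_t): x varies with
    # the bin column j and sample column t, y with bin row i and sample row s
    xs = xs.reshape(n, pooled, sampling)
    ys = ys.reshape(n, pooled, sampling)
    shape = (n, pooled, pooled, sampling, sampling)
    sx = np.broadcast_to(xs[:, None, :, None, :], shape)
    sy = np.broadcast_to(ys[:, :, None, :, None], shape)
    u = np.clip(sx.reshape(-1) - 0.5, 0.0, fw - 1.0)
    v = np.clip(sy.reshape(-1) - 0.5, 0.0, fh - 1.0)
    c0 = np.minimum(u.astype(np.intp), fw - 1)
    r0 = np.minimum(v.astype(np.intp), fh - 1)
    c1 = np.minimum(c0 + 1, fw - 1)
    r1 = np.minimum(r0 + 1, fh - 1)
    fu = u - c0
    fv = v - r0
    idx = np.stack([r0 * fw + c0, r0 * fw + c1, r1 * fw + c0, r1 * fw + c1], axis=1)
    wts = np.stack([(1 - fu) * (1 - fv), fu * (1 - fv),
                    (1 - fu) * fv, fu * fv], axis=1)
    return idx, wts


def roi_align(feature: np.ndarray, stride: float, box: Box | np.ndarray,
              pooled_size: int = 7, sampling: int = 2) -> np.ndarray:
    """Quantization-free ROI pooling of one box from a (C,H,W) feature map.

    The box is divided into pooled_size^2 equal bins; each bin averages
    sampling^2 regularly spaced bilinear samples.  No coordinate is ever
    rounded.
    """
    b = _as_box_array(box)
    feature = np.asarray(feature, dtype=np.float64)
    if feature.ndim == 2:
        feature = feature[None]
    c, fh, fw = feature.shape
    fb = b / stride
    if fb[2] <= 0 or fb[3] <= 0 or fb[0] >= fw or fb[1] >= fh:
        raise ValueError(f"box {b} lies fully outside the {fh}x{fw} feature map")
    if (b[2] - b[0]) <= 0 or (b[3] - b[1]) <= 0:
        raise ValueError("roi_align requires a positive-area box")
    idx, wts = _bilinear_plan_many(b[None], stride, fh, fw, pooled_size, sampling)
    flat = feature.reshape(c, fh * fw)
    # flat[:, idx] -> (C, S, 4); weights (S, 4)
    samples = np.einsum("csj,sj->cs", flat[:, idx], wts)
    out = samples.reshape(c, pooled_size * pooled_size, sampling * sampling).mean(axis=2)
    return out.reshape(c, pooled_size, pooled_size)


def roi_align_stack(feature: "nn.Tensor", stride: float, boxes: np.ndarray,
                    pooled_size: int = 7, sampling: int = 2) -> "nn.Tensor":
    """Differentiable ROI align of many boxes from one (1,C,H,W) tensor.

    Box coordinates are constants; gradients flow into the feature map.
    Returns a tensor of shape (N, C, pooled, pooled).
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    n = boxes.shape[0]
    _, c, fh, fw = feature.shape
    if n == 0:
        return nn.Tensor(np.zeros((0, c, pooled_size, pooled_size)))
    idx, wts = _bilinear_plan_many(boxes, stride, fh, fw, pooled_size, sampling)
    flat = nn.reshape(feature, (c, fh * fw))
    # weighted_gather works on (L, C) row-major features
    xt = _transpose2d(flat)
    gathered = nn.weighted_gather(xt, idx, wts)   # (N*S, C)
    s = pooled_size * pooled_size
    k = sampling * sampling
    g = nn.reshape(gathered, (n, s, k, c))
    pooled = _mean_axis2(g)                        # (N, S, C)
    out = _transpose_nsc_to_ncs(pooled, n, s, c)
    return nn.reshape(out, (n, c, pooled_size, pooled_size))


def _transpose2d(x: "nn.Tensor") -> "nn.Tensor":
    data = x.data.T.copy()
    return nn.Tensor(data, (x,), lambda g: (g.T.copy(),))


def _mean_axis2(x: "nn.Tensor") -> "nn.Tensor":
    n, s, k, c = x.shape
    out = x.data.mean(axis=2)

    def bwd(g):
        return (np.broadcast_to(g[:, :, None, :] / k, (n, s, k, c)).copy(),)

    return nn.Tensor(out, (x,), bwd)


def _transpose_nsc_to_ncs(x: "nn.Tensor", n: int, s: int, c: int) -> "nn.Tensor":
    out = x.data.transpose(0, 2, 1).copy()
    return nn.Tensor(out, (x,), lambda g: (g.transpose(0, 2, 1).copy(),))


# ---------------------------------------------------------------------------
# backbone networks


class TinyBackbone(nn.Module):
    """Four-stage convolutional backbone for CPU-scale experiments.

    Stages C2..C5 at strides 4/8/16/32 with 16/24/32/32 channels;
    well under a million parameters.  The stride-16 C4 map doubles as the
    single-level feature when the pyramid is disabled.
    """

    stage_channels = {"C2": 16, "C3": 24, "C4": 32, "C5": 32}
    terminal_stride = 16

    def __init__(self, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(1, 8, 3, rng)
        self.conv2 = nn.Conv2d(8, 16, 3, rng)
        self.conv3 = nn.Conv2d(16, 16, 3, rng)
        self.conv4 = nn.Conv2d(16, 24, 3, rng)
        self.conv5 = nn.Conv2d(24, 32, 3, rng)
        self.conv6 = nn.Conv2d(32, 32, 3, rng)

    def forward_stages(self, x: "nn.Tensor") -> dict[str, "nn.Tensor"]:
        h = nn.relu(self.conv1(x))
        h = nn.max_pool2x(h)
        h = nn.relu(self.conv2(h))
        h = nn.max_pool2x(h)
        c2 = nn.relu(self.conv3(h))
        h = nn.max_pool2x(c2)
        c3 = nn.relu(self.conv4(h))
        h = nn.max_pool2x(c3)
        c4 = nn.relu(self.conv5(h))
        h = nn.max_pool2x(c4)
        c5 = nn.relu(self.conv6(h))
        return {"C2": c2, "C3": c3, "C4": c4, "C5": c5}


class VGG16Backbone(nn.Module):
    """The 13-convolution VGG-16 feature extractor (blocks 2-2-3-3-3).

    Stage taps: C2 = conv3_3 (stride 4), C3 = conv4_3 (stride 8),
    C4 = conv5_3 (stride 16, the terminal single-level map), C5 = pooled
    conv5_3 (stride 32).  `load_npz` accepts a flat named-array file of
    pretrained weights; a 3-channel first conv is reduced to grayscale by
    averaging over the input-channel axis.
    """

    stage_channels = {"C2": 256, "C3": 512, "C4": 512, "C5": 512}
    terminal_stride = 16
    _plan = [(2, 64), (2, 128), (3, 256), (3, 512), (3, 512)]

    def __init__(self, rng: np.random.Generator):
        self.convs: list[nn.Conv2d] = []
        in_ch = 1
        for n_layers, out_ch in self._plan:
            for _ in range(n_layers):
                self.convs.append(nn.Conv2d(in_ch, out_ch, 3, rng))
                in_ch = out_ch

    def forward_stages(self, x: "nn.Tensor") -> dict[str, "nn.Tensor"]:
        taps = {}
        i = 0
        h = x
        for block, (n_layers, _) in enumerate(self._plan):
            for _ in range(n_layers):
                h = nn.relu(self.convs[i](h))
                i += 1
            if block == 2:
                taps["C2"] = h
            elif block == 3:
                taps["C3"] = h
            elif block == 4:
                taps["C4"] = h
            if block < 4:
                h = nn.max_pool2x(h)
        taps["C5"] = nn.max_pool2x(taps["C4"])
        return taps

    def load_npz(self, path) -> None:
        data = np.load(path)
        for i, conv in enumerate(self.convs):
            w = data[f"conv{i}.weight"]
            if w.shape[1] == 3 and conv.weight.data.shape[1] == 1:
                w = w.mean(axis=1, keepdims=True)
            conv.weight.data = w.astype(np.float32)
            conv.bias.data = data[f"conv{i}.bias"].astype(np.float32)


def make_backbone(preset: str, rng: np.random.Generator):
    if preset == "tiny":
        return TinyBackbone(rng)
    if preset == "vgg16":
        return VGG16Backbone(rng)
    raise ValueError(f"unknown backbone preset: {preset!r}")


def backbone_forward(backbone, image: np.ndarray) -> np.ndarray:
    """Run a raw 2D image through a backbone; returns the stride-16 map.

    The image is zero-padded on the bottom/right to a multiple of 32 so
    every pooling stage divides evenly.
    """
    image = np.asarray(image, dtype=np.float64)
    if min(image.shape) < 16:
        raise ValueError("image smaller than one backbone stride cell")
    x = nn.Tensor(pad_to_multiple(image, 32)[None, None])
    return backbone.forward_stages(x)["C4"].data[0]


def pad_to_multiple(image: np.ndarray, multiple: int) -> np.ndarray:
    h, w = image.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw)))
    return image


# ---------------------------------------------------------------------------
# feature pyramid network


class FPN(nn.Module):
    """Lateral 1x1 projections + top-down nearest-neighbour upsampling,
    followed by 3x3 smoothing convs; P6 is a stride-2 subsample of P5."""

    def __init__(self, stage_channels: dict[str, int], out_channels: int,
                 rng: np.random.Generator):
        self.out_channels = out_channels
        self.lateral = [nn.Conv2d(stage_channels[c], out_channels, 1, rng)
                        for c in ("C2", "C3", "C4", "C5")]
        self.smooth = [nn.Conv2d(out_channels, out_channels, 3, rng)
                       for _ in range(4)]

    def forward(self, stages: dict[str, "nn.Tensor"]) -> FeaturePyramid:
        names = ("C2", "C3", "C4", "C5")
        shapes = [stages[n].shape[2:] for n in names]
        for (h1, w1), (h0, w0) in zip(shapes[1:], shapes[:-1]):
            if (h0, w0) != (2 * h1, 2 * w1):
                raise ValueError("backbone stages must halve resolution per level")
        laterals = [lat(stages[n]) for lat, n in zip(self.lateral, names)]
        merged = [None] * 4
        merged[3] = laterals[3]
        for i in (2, 1, 0):
            merged[i] = nn.add(laterals[i], nn.upsample2x(merged[i + 1]))
        outs = [smooth(m) for smooth, m in zip(self.smooth, merged)]
        levels = {f"P{k}": (outs[k - 2], FPN_STRIDES[f"P{k}"]) for k in range(2, 6)}
        levels["P6"] = (nn.subsample2(outs[3]), FPN_STRIDES["P6"])
        return FeaturePyramid(levels)


def fpn_forward(fpn: FPN, stages: dict[str, "nn.Tensor"]) -> FeaturePyramid:
    return fpn.forward(stages)


# ---------------------------------------------------------------------------
# region proposal network


class RPNHead(nn.Module):
    """3x3 conv trunk with 1x1 objectness and box-delta heads, shared
    across pyramid levels."""

    def __init__(self, in_channels: int, num_shapes: int, rng: np.random.Generator):
        self.num_shapes = num_shapes
        self.trunk = nn.Conv2d(in_channels, in_channels, 3, rng)
        self.obj = nn.Conv2d(in_channels, num_shapes, 1, rng)
        self.reg = nn.Conv2d(in_channels, 4 * num_shapes, 1, rng)

    def forward(self, feature: "nn.Tensor") -> tuple["nn.Tensor", "nn.Tensor"]:
        """Returns objectness logits (H*W*A,) and deltas (H*W*A, 4) in the
        same location-major-then-shape order as build_anchor_grid."""
        h = nn.relu(self.trunk(feature))
        obj = self.obj(h)     # (1, A, H, W)
        reg = self.reg(h)     # (1, 4A, H, W)
        a = self.num_shapes
        _, _, fh, fw = obj.shape
        obj_flat = nn.reshape(_to_hwa(obj, a, 1, fh, fw), (fh * fw * a,))
        reg_flat = nn.reshape(_to_hwa(reg, a, 4, fh, fw), (fh * fw * a, 4))
        return obj_flat, reg_flat


def _to_hwa(x: "nn.Tensor", a: int, k: int, fh: int, fw: int) -> "nn.Tensor":
    """(1, A*k, H, W) -> (H, W, A, k) with gradients."""
    out = x.data.reshape(a, k, fh, fw).transpose(2, 3, 0, 1).copy()

    def bwd(g):
        return (g.transpose(2, 3, 0, 1).reshape(1, a * k, fh, fw).copy(),)

    return nn.Tensor(out, (x,), bwd)


def rpn_forward(head: RPNHead, features: list["nn.Tensor"]
                ) -> tuple[list["nn.Tensor"], list["nn.Tensor"]]:
    """Apply the shared RPN head to every level."""
    outs = [head.forward(f) for f in features]
    return [o for o, _ in outs], [r for _, r in outs]


@dataclass
class ProposalSet:
    """Top region proposals: boxes clipped to the image, sorted by
    descending objectness.  When fewer than the requested count survive
    suppression the last proposal is repeated (`n_valid` marks the
    boundary); the pairwise-IoU guarantee applies to the valid prefix."""

    boxes: np.ndarray       # (num_candidates, 4)
    objectness: np.ndarray  # (num_candidates,)
    n_valid: int


def propose(objectness: np.ndarray, deltas: np.ndarray, anchors: np.ndarray,
            image_size: tuple[float, float], cfg: RunConfig,
            num_candidates: int | None = None) -> ProposalSet:
    """Decode, clip, filter and suppress anchors into a fixed-size proposal set."""
    num = num_candidates if num_candidates is not None else cfg.num_candidates
    objectness = np.asarray(objectness, dtype=np.float64).ravel()
    deltas = np.asarray(deltas, dtype=np.float64).reshape(-1, 4)
    order = np.argsort(-objectness, kind="stable")[:cfg.pre_nms_top_n]
    boxes = decode_deltas(anchors[order], deltas[order], image_size)
    scores = objectness[order]
    ok = (boxes[:, 2] - boxes[:, 0] >= 2.0) & (boxes[:, 3] - boxes[:, 1] >= 2.0)
    boxes, scores = boxes[ok], scores[ok]
    if len(boxes) == 0:
        # degenerate fallback: one whole-image proposal
        w, h = image_size
        boxes = np.array([[0.0, 0.0, w, h]])
        scores = np.array([0.0])
    keep = nms(boxes, scores, cfg.rpn_nms_threshold)[:num]
    boxes, scores = boxes[keep], scores[keep]
    n_valid = len(boxes)
    if n_valid < num:
        pad = num - n_valid
        boxes = np.concatenate([boxes, np.repeat(boxes[-1:], pad, axis=0)])
        scores = np.concatenate([scores, np.repeat(scores[-1:], pad)])
    return ProposalSet(boxes[:num], scores[:num], min(n_valid, num))


# ---------------------------------------------------------------------------
# detection head


@dataclass
class DetectionHeadOutput:
    """Per-candidate softmax scores (N, K) and class-conditional regression
    deltas (N, 4K): with K=3 and 300 candidates, [300, 3] and [300, 12]."""

    roi_scores: np.ndarray
    roi_deltas: np.ndarray
    cls_logits: object = field(default=None, repr=False)   # nn.Tensor at train time
    delta_tensor: object = field(default=None, repr=False)


class DetectionHead(nn.Module):
    """Two parallel fully connected layers on flattened pooled features:
    one emits the 4K regression parameters, the other the K class scores."""

    def __init__(self, in_features: int, num_classes: int, rng: np.random.Generator):
        self.num_classes = num_classes
        self.cls = nn.Linear(in_features, num_classes, rng, std=0.01)
        self.reg = nn.Linear(in_features, 4 * num_classes, rng, std=0.001)

    def forward(self, pooled: "nn.Tensor") -> tuple["nn.Tensor", "nn.Tensor"]:
        n = pooled.shape[0]
        flat = nn.reshape(pooled, (n, -1))
        return self.cls(flat), self.reg(flat)


def detection_head(head: DetectionHead, pooled: "nn.Tensor") -> DetectionHeadOutput:
    cls_logits, delta_t = head.forward(pooled)
    scores = nn.softmax(cls_logits.data.astype(np.float64), axis=1)
    return DetectionHeadOutput(roi_scores=scores,
                               roi_deltas=delta_t.data.astype(np.float64),
                               cls_logits=cls_logits, delta_tensor=delta_t)
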
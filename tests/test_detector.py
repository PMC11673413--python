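"""Box geometry, anchors, ROI align, backbone/FPN/RPN/head contracts."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrcnn import nn
from bcrcnn.dataset_io import Box, RunConfig
from bcrcnn.detector import (FPN, DetectionHead, RPNHead,
                             VGG16Backbone, assign_fpn_level,
                             backbone_forward, build_anchor_grid,
                             decode_deltas, detection_head, encode_deltas,
                             iou, iou_matrix, make_backbone, nms, propose,
                             roi_align, single_level_shapes)


def random_boxes(rng, n, lim=100.0):
    x1 = rng.uniform(0, lim * 0.8, n)
    y1 = rng.uniform(0, lim * 0.8, n)
    w = rng.uniform(1.0, lim * 0.4, n)
    h = rng.uniform(1.0, lim * 0.4, n)
    return np.stack([x1, y1, x1 + w, y1 + h], axis=1)


class TestIoU:
    def test_identical_boxes(self):
        assert iou(Box(1, 2, 7, 9), Box(1, 2, 7, 9)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(Box(0, 0, 5, 5), Box(10, 10, 20, 20)) == 0.0

    def test_quarter_overlap_arithmetic(self):
        # inter 25, union 100 + 100 - 25 = 175
        assert iou(Box(0, 0, 10, 10), Box(5, 5, 15, 15)) \
            == pytest.approx(25 / 175)

    def test_symmetry_and_shapely_agreement(self, rng):
        from shapely.geometry import box as sbox
        a = random_boxes(rng, 200)
        b = random_boxes(rng, 200)
        for p, q in zip(a, b):
            expected = sbox(*p).intersection(sbox(*q)).area \
                / sbox(*p).union(sbox(*q)).area
            assert iou(p, q) == pytest.approx(expected, abs=1e-9)
            assert iou(p, q) == iou(q, p)

    def test_matrix_matches_scalar(self, rng):
        a, b = random_boxes(rng, 20), random_boxes(rng, 15)
        m = iou_matrix(a, b)
        for i in range(20):
            for j in range(15):
                assert m[i, j] == pytest.approx(iou(a[i], b[j]))


def nms_oracle(boxes, scores, threshold):
    """Brute-force reference: explicit greedy suppression."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    kept, dead = [], set()
    for i in order:
        if i in dead:
            continue
        kept.append(i)
        for j in order:
            if j not in dead and j != i and iou(boxes[j], boxes[i]) > threshold:
                dead.add(j)
        dead.add(i)
    return kept


class TestNMS:
    def test_single_box_kept(self):
        assert nms([Box(0, 0, 5, 5)], [0.9], 0.5) == [0]

    def test_duplicate_keeps_higher_score(self):
        b = Box(0, 0, 5, 5)
        assert nms([b, b], [0.3, 0.8], 0.5) == [1]

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 30))
            boxes = random_boxes(rng, n, lim=40.0)
            scores = rng.uniform(0, 1, n)
            thr = float(rng.uniform(0.1, 0.9))
            assert nms(boxes, scores, thr) == nms_oracle(boxes, scores, thr)


class TestDeltas:
    def test_zero_deltas_decode_to_anchor_bit_exactly(self, rng):
        anchors = random_boxes(rng, 50)
        decoded = decode_deltas(anchors, np.zeros((50, 4)))
        assert np.array_equal(decoded, anchors)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.5, 200.0), min_size=8, max_size=8))
    def test_encode_decode_roundtrip(self, vals):
        a = np.array([[vals[0], vals[1], vals[0] + vals[2], vals[1] + vals[3]]])
        t = np.array([[vals[4], vals[5], vals[4] + vals[6], vals[5] + vals[7]]])
        out = decode_deltas(a, encode_deltas(a, t))
        assert np.allclose(out, t, atol=1e-6)

    def test_closed_form_doubling(self):
        out = decode_deltas(np.array([[0.0, 0.0, 10.0, 10.0]]),
                            np.array([[0.0, 0.0, math.log(2), math.log(2)]]))
        np.testing.assert_allclose(out[0], [-5, -5, 15, 15], atol=1e-9)

    def test_degenerate_anchor_rejected(self):
        with pytest.raises(ValueError):
            encode_deltas(np.array([[0, 0, 0, 5.0]]), np.array([[0, 0, 1, 1.0]]))


class TestAnchors:
    def test_single_level_has_nine_shapes(self):
        grid = build_anchor_grid((4, 4), 16, scales=(128, 256, 512))
        assert len(grid.shapes) == 9
        assert grid.anchors.shape == (4 * 4 * 9, 4)

    def test_fpn_level_has_six_shapes(self):
        from bcrcnn.detector import anchor_shapes_for_level
        shapes = anchor_shapes_for_level(64.0)
        assert len(shapes) == 6
        scales = sorted({s for s, _ in shapes})
        assert scales == pytest.approx([64 / math.sqrt(2), 64 * math.sqrt(2)])

    def test_anchor_centered_on_cell_center_with_unit_ratio(self):
        grid = build_anchor_grid((2, 2), 16, shapes=[(16.0, 1.0)])
        a = grid.anchors[0]
        np.testing.assert_allclose(a, [0, 0, 16, 16])  # centered at (8, 8)
        assert a[2] - a[0] == pytest.approx(16)

    def test_count_is_locations_times_shapes(self):
        for h, w, s in [(3, 5, 2), (7, 7, 6), (1, 9, 9)]:
            grid = build_anchor_grid((h, w), 8,
                                     shapes=[(16.0, r) for r in
                                             np.linspace(0.5, 2, s)])
            assert len(grid.anchors) == h * w * s

    def test_ratio_preserves_area(self):
        grid = build_anchor_grid((1, 1), 16, shapes=[(32.0, 0.5), (32.0, 2.0)])
        for a in grid.anchors:
            assert (a[2] - a[0]) * (a[3] - a[1]) == pytest.approx(32 ** 2)

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            build_anchor_grid((2, 2), 16, scales=())


class TestFPNLevelAssignment:
    @pytest.mark.parametrize("side,expected", [(160, 4), (40, 2), (1280, 5),
                                               (80, 3), (320, 5)])
    def test_canonical_examples(self, side, expected):
        assert assign_fpn_level(Box(0, 0, side, side)) == expected

    def test_monotone_in_area(self, rng):
        sides = np.sort(rng.uniform(1, 2000, 200))
        levels = [assign_fpn_level(Box(0, 0, s, s)) for s in sides]
        assert all(a <= b for a, b in zip(levels, levels[1:]))

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            assign_fpn_level(Box(0, 0, 0, 10))


def roi_align_oracle(feature, stride, box, pooled, sampling=2):
    """Independent double-loop bilinear implementation."""
    c, fh, fw = feature.shape
    x1, y1, x2, y2 = [v / stride for v in box]
    bw, bh = (x2 - x1) / pooled, (y2 - y1) / pooled
    out = np.zeros((c, pooled, pooled))
    for i in range(pooled):
        for j in range(pooled):
            acc = np.zeros(c)
            for s in range(sampling):
                for t in range(sampling):
                    y = y1 + (i + (s + 0.5) / sampling) * bh
                    x = x1 + (j + (t + 0.5) / sampling) * bw
                    u = min(max(x - 0.5, 0.0), fw - 1.0)
                    v = min(max(y - 0.5, 0.0), fh - 1.0)
                    c0, r0 = int(u), int(v)
                    c1, r1 = min(c0 + 1, fw - 1), min(r0 + 1, fh - 1)
                    fu, fv = u - c0, v - r0
                    acc += ((1 - fu) * (1 - fv) * feature[:, r0, c0]
                            + fu * (1 - fv) * feature[:, r0, c1]
                            + (1 - fu) * fv * feature[:, r1, c0]
                            + fu * fv * feature[:, r1, c1])
            out[:, i, j] = acc / sampling ** 2
    return out


class TestRoiAlign:
    def test_constant_map_gives_constant_bins(self):
        f = np.full((2, 10, 10), 3.25)
        out = roi_align(f, 4.0, Box(3, 5, 30, 37), pooled_size=7)
        np.testing.assert_allclose(out, 3.25)

    def test_linear_ramp_matches_analytic_mean(self):
        f = np.tile(np.arange(16, dtype=float)[None, None, :], (1, 16, 1))
        out = roi_align(f, 1.0, Box(2, 2, 10, 10), pooled_size=4)
        np.testing.assert_allclose(out[0, 0], [2.5, 4.5, 6.5, 8.5], atol=1e-5)

    def test_default_output_is_7x7(self):
        out = roi_align(np.ones((3, 8, 8)), 4.0, Box(0, 0, 20, 20))
        assert out.shape == (3, 7, 7)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            f = rng.normal(size=(2, 12, 14))
            box = random_boxes(rng, 1, lim=40.0)[0]
            got = roi_align(f, 4.0, box, pooled_size=5)
            want = roi_align_oracle(f, 4.0, box, pooled=5)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_fully_outside_box_rejected(self):
        with pytest.raises(ValueError):
            roi_align(np.ones((1, 8, 8)), 4.0, Box(100, 100, 120, 120))


class TestBackbone:
    def test_stride16_spatial_arithmetic(self):
        net = make_backbone("tiny", np.random.default_rng(0))
        fmap = backbone_forward(net, np.zeros((128, 160)))
        assert fmap.shape[1:] == (8, 10)

    def test_tiny_parameter_budget(self):
        net = make_backbone("tiny", np.random.default_rng(0))
        assert sum(p.data.size for p in net.parameters()) < 1_000_000

    def test_zero_input_gives_constant_map(self):
        net = make_backbone("tiny", np.random.default_rng(0))
        fmap = backbone_forward(net, np.zeros((64, 64)))
        for ch in fmap:
            assert np.allclose(ch, ch.ravel()[0])

    def test_vgg16_has_thirteen_convs_with_standard_widths(self):
        net = VGG16Backbone(np.random.default_rng(0))
        assert len(net.convs) == 13
        assert [c.weight.data.shape[0] for c in net.convs] == \
            [64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512]

    def test_too_small_image_rejected(self):
        net = make_backbone("tiny", np.random.default_rng(0))
        with pytest.raises(ValueError):
            backbone_forward(net, np.zeros((8, 8)))


class TestFPN:
    def _stages(self, rng, channels, base=32):
        return {name: nn.Tensor(rng.normal(size=(1, ch, base >> i, base >> i)))
                for i, (name, ch) in enumerate(channels.items())}

    def test_zero_stages_give_zero_pyramid(self):
        ch = {"C2": 8, "C3": 8, "C4": 8, "C5": 8}
        fpn = FPN(ch, 8, np.random.default_rng(0))
        stages = {k: nn.Tensor(np.zeros((1, 8, 32 >> i, 32 >> i)))
                  for i, k in enumerate(ch)}
        pyr = fpn.forward(stages)
        for name in pyr.names:
            np.testing.assert_allclose(pyr.feature(name).data, 0.0)

    def test_level_shapes_and_strides(self, rng):
        ch = {"C2": 4, "C3": 6, "C4": 8, "C5": 8}
        fpn = FPN(ch, 8, np.random.default_rng(0))
        pyr = fpn.forward(self._stages(rng, ch))
        assert pyr.names == ["P2", "P3", "P4", "P5", "P6"]
        assert pyr.feature("P2").shape == (1, 8, 32, 32)  # C2 spatial dims
        assert [pyr.stride(n) for n in pyr.names] == [4, 8, 16, 32, 64]

    def test_lateral_path_isolated_when_deeper_stages_zero(self, rng):
        """Identity laterals + zero deeper stages -> P2 == smoothed C2."""
        ch = {"C2": 8, "C3": 8, "C4": 8, "C5": 8}
        fpn = FPN(ch, 8, np.random.default_rng(0))
        for lat in fpn.lateral:
            lat.weight.data = np.eye(8, dtype=np.float32).reshape(8, 8, 1, 1)
            lat.bias.data = np.zeros(8, dtype=np.float32)
        stages = self._stages(rng, ch)
        for name in ("C3", "C4", "C5"):
            stages[name] = nn.Tensor(np.zeros(stages[name].shape))
        pyr = fpn.forward(stages)
        want = fpn.smooth[0](stages["C2"]).data
        np.testing.assert_allclose(pyr.feature("P2").data, want, atol=1e-5)

    def test_mismatched_resolutions_rejected(self, rng):
        ch = {"C2": 4, "C3": 4, "C4": 4, "C5": 4}
        fpn = FPN(ch, 4, np.random.default_rng(0))
        stages = self._stages(rng, ch)
        stages["C3"] = nn.Tensor(np.zeros((1, 4, 15, 15)))
        with pytest.raises(ValueError):
            fpn.forward(stages)


class TestProposalsAndHead:
    def _setup(self, rng, num_candidates=300):
        cfg = RunConfig(backbone_preset="tiny", num_candidates=num_candidates)
        grid = build_anchor_grid((16, 16), 8,
                                 shapes=single_level_shapes((16, 32, 64)))
        n = len(grid.anchors)
        obj = rng.normal(size=n)
        deltas = rng.normal(scale=0.1, size=(n, 4))
        return cfg, grid, obj, deltas

    def test_exactly_num_candidates_proposals(self, rng):
        cfg, grid, obj, deltas = self._setup(rng)
        prop = propose(obj, deltas, grid.anchors, (128.0, 128.0), cfg)
        assert prop.boxes.shape == (300, 4)

    def test_sorted_descending_objectness(self, rng):
        cfg, grid, obj, deltas = self._setup(rng)
        prop = propose(obj, deltas, grid.anchors, (128.0, 128.0), cfg)
        valid = prop.objectness[:prop.n_valid]
        assert np.all(np.diff(valid) <= 1e-12)

    def test_valid_prefix_respects_nms_bound(self, rng):
        cfg, grid, obj, deltas = self._setup(rng)
        prop = propose(obj, deltas, grid.anchors, (128.0, 128.0), cfg)
        boxes = prop.boxes[:prop.n_valid]
        m = iou_matrix(boxes, boxes)
        np.fill_diagonal(m, 0.0)
        assert m.max() <= cfg.rpn_nms_threshold + 1e-9

    def test_boxes_clipped_to_image(self, rng):
        cfg, grid, obj, deltas = self._setup(rng)
        prop = propose(obj, deltas, grid.anchors, (100.0, 90.0), cfg)
        assert prop.boxes[:, [0, 2]].min() >= 0 and prop.boxes[:, [0, 2]].max() <= 100
        assert prop.boxes[:, [1, 3]].min() >= 0 and prop.boxes[:, [1, 3]].max() <= 90

    @pytest.mark.parametrize("k,shapes", [(3, (300, 12)), (2, (300, 8))])
    def test_head_output_shapes(self, rng, k, shapes):
        head = DetectionHead(4 * 49, k, np.random.default_rng(0))
        pooled = nn.Tensor(rng.normal(size=(300, 4, 7, 7)))
        out = detection_head(head, pooled)
        assert out.roi_deltas.shape == shapes
        assert out.roi_scores.shape == (300, k)

    def test_score_rows_sum_to_one(self, rng):
        head = DetectionHead(4 * 49, 3, np.random.default_rng(0))
        out = detection_head(head, nn.Tensor(rng.normal(size=(50, 4, 7, 7))))
        np.testing.assert_allclose(out.roi_scores.sum(axis=1), 1.0, atol=1e-5)


class TestRPNHead:
    def test_output_lengths_match_anchor_count(self, rng):
        head = RPNHead(8, 6, np.random.default_rng(0))
        obj, reg = head.forward(nn.Tensor(rng.normal(size=(1, 8, 10, 12))))
        assert obj.shape == (10 * 12 * 6,)
        assert reg.shape == (10 * 12 * 6, 4)
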
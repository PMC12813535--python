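import itertools

import numpy as np
import pytest

from cytoseg.detect import (AnchorSet, BoxDetection, Detector, DetectorConfig,
                            assign_and_sample, build_backbone_fpn, decode_boxes,
                            detect_instances, effective_receptive_span, encode_boxes,
                            generate_anchors, iou, nms, train_detector)
from cytoseg.synthgen import generate_dataset, small_cell_config


def pixel_iou(box_a, box_b, canvas=32) -> float:
    """Brute-force IoU oracle: rasterise both boxes on an integer grid."""
    def raster(b):
        m = np.zeros((canvas, canvas), bool)
        m[int(b[0]):int(b[2]), int(b[1]):int(b[3])] = True
        return m
    a, b = raster(box_a), raster(box_b)
    union = np.logical_or(a, b).sum()
    return np.logical_and(a, b).sum() / union if union else 0.0


def nms_reference(dets, thresh):
    """Exhaustive O(n^2) NMS reference."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept = []
    for i in order:
        if all(iou(dets[i].box, dets[j].box) <= thresh for j in kept):
            kept.append(i)
    return [dets[i] for i in kept]


class TestReceptiveSpan:
    @pytest.mark.parametrize("k,r,expected", [(3, 1, 3), (3, 2, 5), (1, 5, 1), (5, 2, 9)])
    def test_closed_form(self, k, r, expected):
        assert effective_receptive_span(k, r) == expected

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            effective_receptive_span(0, 1)


class TestIoU:
    def test_identity_and_disjoint(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0
        assert iou((0, 0, 5, 5), (6, 6, 9, 9)) == 0.0

    def test_known_overlap(self):
        assert abs(iou((0, 0, 10, 10), (5, 5, 15, 15)) - 1 / 7) < 1e-12

    def test_matches_pixel_counting_on_random_boxes(self, rng):
        for _ in range(50):
            a = np.sort(rng.integers(0, 32, size=4).reshape(2, 2), axis=0)
            b = np.sort(rng.integers(0, 32, size=4).reshape(2, 2), axis=0)
            box_a = (a[0, 0], a[0, 1], a[1, 0] + 1, a[1, 1] + 1)
            box_b = (b[0, 0], b[0, 1], b[1, 0] + 1, b[1, 1] + 1)
            assert abs(iou(box_a, box_b) - pixel_iou(box_a, box_b)) < 1e-12

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 5), (0, 0, 1, 1))


class TestAnchors:
    def test_grid_count_single_level(self):
        cfg = DetectorConfig(fpn_levels=1, anchor_scales=((16.0,),))
        anchors = generate_anchors((64, 64), cfg)
        # stride 4 at the only level -> 16x16 grid
        assert len(anchors) == 16 * 16

    def test_two_scales_double_the_count(self):
        c1 = DetectorConfig(fpn_levels=1, anchor_scales=((16.0,),))
        c2 = DetectorConfig(fpn_levels=1, anchor_scales=((16.0, 24.0),))
        assert len(generate_anchors((64, 64), c2)) == 2 * len(generate_anchors((64, 64), c1))

    def test_anchors_clipped_to_image(self):
        cfg = DetectorConfig(fpn_levels=2, anchor_scales=((32.0,), (64.0,)))
        boxes = generate_anchors((64, 64), cfg).boxes
        assert boxes.min() >= 0 and boxes.max() <= 64


class TestAssignAndSample:
    def grid_cfg(self, **kw):
        return DetectorConfig(fpn_levels=1, anchor_scales=((16.0,),), **kw)

    def test_empty_gt_all_negative(self, rng):
        anchors = generate_anchors((64, 64), self.grid_cfg())
        labels, pos, neg = assign_and_sample(anchors, np.zeros((0, 4)), self.grid_cfg(), rng)
        assert pos.size == 0 and np.all(labels == 0)

    def test_anchor_equal_to_gt_is_positive(self, rng):
        cfg = self.grid_cfg()
        anchors = generate_anchors((64, 64), cfg)
        gt = anchors.boxes[37:38].copy()
        labels, pos, _neg = assign_and_sample(anchors, gt, cfg, rng)
        assert labels[37] == 1 and 37 in pos

    def test_partition_matches_exhaustive_iou_matrix(self, rng):
        # 16-anchor toy grid: a 64x64 image at stride 16
        cfg = DetectorConfig(fpn_levels=1, anchor_scales=((20.0,),))
        anchors = AnchorSet(image_size=(64, 64))
        stride = 16
        boxes = []
        for i in range(4):
            for j in range(4):
                cy, cx = (i + 0.5) * stride, (j + 0.5) * stride
                boxes.append([cy - 10, cx - 10, cy + 10, cx + 10])
        anchors.levels.append((stride, np.clip(np.array(boxes), 0, 64)))
        gt = np.array([[14.0, 14.0, 40.0, 40.0]])
        labels, _pos, _neg = assign_and_sample(anchors, gt, cfg, rng)
        best_i = None
        best_v = -1.0
        for i, b in enumerate(anchors.boxes):
            v = iou(tuple(b), tuple(gt[0]))
            expect = 1 if v >= cfg.pos_iou_thresh else (0 if v < cfg.neg_iou_thresh else -1)
            if v > best_v:
                best_v, best_i = v, i
            if expect != 1 and i != best_i:
                assert labels[i] == expect
        assert labels[best_i] == 1

    def test_sampled_ratio_respected(self, rng):
        cfg = self.grid_cfg(pos_neg_ratio=3)
        anchors = generate_anchors((64, 64), cfg)
        gt = anchors.boxes[5:6].copy()
        _labels, pos, neg = assign_and_sample(anchors, gt, cfg, rng)
        assert pos.size <= cfg.max_positives
        assert neg.size <= pos.size * 3 + 1


class TestNMS:
    def test_single_detection_kept(self):
        d = [BoxDetection((0, 0, 5, 5), 0.4)]
        assert nms(d, 0.5) == d

    def test_identical_boxes_keep_highest(self):
        d = [BoxDetection((0, 0, 5, 5), 0.8), BoxDetection((0, 0, 5, 5), 0.9)]
        kept = nms(d, 0.5)
        assert len(kept) == 1 and kept[0].score == 0.9

    def test_matches_exhaustive_reference_on_random_sets(self, rng):
        for _ in range(100):
            dets = []
            for _k in range(6):
                r0, c0 = rng.integers(0, 20, size=2)
                h, w = rng.integers(3, 12, size=2)
                dets.append(BoxDetection((r0, c0, r0 + h, c0 + w), float(rng.random())))
            got = nms(dets, 0.4)
            want = nms_reference(dets, 0.4)
            assert [d.box for d in got] == [d.box for d in want]

    def test_order_invariance_with_distinct_scores(self, rng):
        dets = [BoxDetection((i, i, i + 6, i + 6), 0.1 * (i + 1)) for i in range(5)]
        base = [d.box for d in nms(dets, 0.3)]
        for perm in itertools.permutations(range(5)):
            shuffled = [dets[i] for i in perm]
            assert [d.box for d in nms(shuffled, 0.3)] == base


class TestBoxCoding:
    def test_encode_decode_round_trip(self, rng):
        anchors = np.array([[0, 0, 16, 16], [8, 8, 40, 40]], float)
        gt = np.array([[2, 1, 18, 15], [10, 12, 38, 44]], float)
        assert np.allclose(decode_boxes(anchors, encode_boxes(anchors, gt)), gt)


class TestBackbone:
    def test_pyramid_shapes_and_common_channels(self):
        cfg = DetectorConfig(fpn_levels=3)
        bb = build_backbone_fpn(cfg, seed=0)
        ps = bb.forward(np.random.default_rng(0).random((1, 3, 64, 64)))
        assert [p.shape[2:] for p in ps] == [(16, 16), (8, 8), (4, 4)]
        assert len({p.shape[1] for p in ps}) == 1

    def test_dilation_preserves_spatial_shape(self):
        x = np.random.default_rng(0).random((1, 3, 64, 64))
        shapes = []
        for rate in (1, 2):
            bb = build_backbone_fpn(DetectorConfig(fpn_levels=2, dilation_rate=rate), seed=0)
            shapes.append([p.shape for p in bb.forward(x)])
        assert shapes[0] == shapes[1]

    def test_dilation_enlarges_receptive_field_analytically(self):
        # compose per-layer spans: rf' = rf + (span-1) * stride_so_far
        def backbone_rf(dilation):
            rf, stride = 1, 1
            layers = [(3, 1, 1), (2, 1, 2),          # stem conv + pool
                      (3, 1, 1), (2, 1, 2),          # stage 0
                      (3, dilation, 1), (2, 1, 2)]   # final stage (dilated) + pool
            for k, d, s in layers:
                span = k + (k - 1) * (d - 1)
                rf += (span - 1) * stride
                stride *= s
            return rf
        assert backbone_rf(2) > backbone_rf(1)


class TestEndToEndDetection:
    def test_score_threshold_filters_everything_at_one(self):
        cfg = DetectorConfig(fpn_levels=2, score_thresh=1.0)
        det = Detector(cfg, seed=0)
        img = np.random.default_rng(0).random((64, 64, 3))
        assert detect_instances(det, img) == []

    def test_returned_scores_respect_threshold(self):
        cfg = DetectorConfig(fpn_levels=2, score_thresh=0.3)
        det = Detector(cfg, seed=0)
        img = np.random.default_rng(0).random((64, 64, 3))
        assert all(d.score >= 0.3 for d in detect_instances(det, img))

    def test_trained_detector_finds_single_cells(self):
        # majority of seeds must detect exactly one cell with box IoU >= 0.5
        # on >= 80% of held-out single-cell images
        def run(seed):
            cfg = small_cell_config(64, seed=3, n_cells_range=(1, 1))
            pairs = generate_dataset(cfg, 40)
            ds = []
            for img, gt in pairs[:30]:
                boxes, masks = [], []
                for iid, m in gt.cyto_masks.items():
                    rr, cc = np.nonzero(m)
                    boxes.append([rr.min(), cc.min(), rr.max() + 1, cc.max() + 1])
                    masks.append(m)
                ds.append((img.pixels, np.array(boxes, float), masks))
            dcfg = DetectorConfig(fpn_levels=2, anchor_scales=((24.0,), (40.0,)),
                                  neg_iou_thresh=0.4, score_thresh=0.7, nms_iou=0.2)
            model = Detector(dcfg, seed=seed)
            train_detector(model, ds, steps=800, learning_rate=0.05, seed=seed,
                           box_loss_weight=2.0)
            good = 0
            for img, gt in pairs[30:]:
                dets = detect_instances(model, img)
                iid = gt.cells[0][0]
                rr, cc = np.nonzero(gt.cyto_masks[iid])
                gtb = (rr.min(), cc.min(), rr.max() + 1, cc.max() + 1)
                if len(dets) == 1 and iou(dets[0].box, gtb) >= 0.5:
                    good += 1
            return good >= 8
        assert sum(run(s) for s in (0, 1, 2)) >= 2
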
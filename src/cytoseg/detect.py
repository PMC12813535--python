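"""Instance detection: dilated-convolution FPN backbone, anchor assignment
with positive/negative ratio control, NMS and per-ROI mask prediction.

The detector is a deliberately small Mask R-CNN-style pipeline sized for CPU
training on synthetic data:

* a bottom-up backbone of strided (pooled) conv stages whose **final** stage
  uses dilated convolutions (default dilation rate 2, kernel 3x3 — the
  published setting) to enlarge the receptive field without extra
  parameters;
* a feature pyramid: 1x1 lateral projections to a common channel width,
  top-down nearest-neighbour upsampling with addition, and a 3x3 smoothing
  convolution per level (strides 4, 8, 16, ...);
* one square anchor per configured scale per grid position per level;
  anchors are labelled positive at IoU >= ``pos_iou_thresh`` to some ground
  truth, negative below ``neg_iou_thresh`` to all, ignored in between, and
  the training minibatch subsamples negatives to a fixed positive:negative
  ratio (default 1:3) to counter box-level class imbalance;
* a shared head per level predicting objectness and box offsets
  (centre/size offsets normalised by anchor size, smooth-L1 loss), and a
  class-agnostic mask head on 14x14 bilinearly ROI-aligned crops of the
  finest pyramid level.

Boxes are ``(row_min, col_min, row_max, col_max)`` half-open pixel
coordinates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imgio import HEImage
from . import nnet
from .nnet import Conv2d, NearestUpsample2x2, MaxPool2x2, Param, ReLU, SGD

__all__ = [
    "DetectorConfig", "BoxDetection", "AnchorSet", "Detector",
    "effective_receptive_span", "build_backbone_fpn", "generate_anchors",
    "iou", "assign_and_sample", "nms", "detect_instances", "train_detector",
]

MASK_SIZE = 14


@dataclass(frozen=True)
class DetectorConfig:
    dilation_rate: int = 2
    kernel_size: int = 3
    fpn_levels: int = 3
    fpn_channels: int = 32
    anchor_scales: tuple[tuple[float, ...], ...] | None = None  # per level
    pos_iou_thresh: float = 0.5
    neg_iou_thresh: float = 0.3
    pos_neg_ratio: int = 3  # negatives per positive
    max_positives: int = 16
    nms_iou: float = 0.5
    score_thresh: float = 0.5
    mask_thresh: float = 0.5

    def __post_init__(self) -> None:
        if self.dilation_rate < 1:
            raise ValueError("dilation_rate must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if not (0.0 <= self.neg_iou_thresh <= self.pos_iou_thresh <= 1.0):
            raise ValueError("need 0 <= neg_iou_thresh <= pos_iou_thresh <= 1")
        for name in ("nms_iou", "score_thresh", "mask_thresh"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fpn_levels < 1 or self.pos_neg_ratio < 1 or self.max_positives < 1:
            raise ValueError("invalid detector configuration")
        if self.anchor_scales is not None:
            if len(self.anchor_scales) != self.fpn_levels:
                raise ValueError("anchor_scales needs one scale tuple per level")
            if len({len(s) for s in self.anchor_scales}) != 1:
                raise ValueError("each level needs the same number of anchor scales")

    def scales(self) -> tuple[tuple[float, ...], ...]:
        if self.anchor_scales is not None:
            return self.anchor_scales
        return tuple((4.0 * 2 ** lv * 4.0,) for lv in range(self.fpn_levels))

    def strides(self) -> tuple[int, ...]:
        return tuple(4 * 2 ** lv for lv in range(self.fpn_levels))


@dataclass
class BoxDetection:
    box: tuple[float, float, float, float]  # (row_min, col_min, row_max, col_max)
    score: float
    mask: np.ndarray | None = None  # full-image binary raster

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.box
        if not (r0 < r1 and c0 < c1):
            raise ValueError(f"degenerate box {self.box}")


@dataclass
class AnchorSet:
    """Per-level anchor boxes with stride metadata; boxes clipped to the image."""

    image_size: tuple[int, int]
    levels: list[tuple[int, np.ndarray]] = field(default_factory=list)  # (stride, (K,4))

    @property
    def boxes(self) -> np.ndarray:
        if not self.levels:
            return np.zeros((0, 4))
        return np.concatenate([b for _s, b in self.levels], axis=0)

    def __len__(self) -> int:
        return sum(b.shape[0] for _s, b in self.levels)


def effective_receptive_span(kernel_size: int, dilation_rate: int) -> int:
    """Span in pixels of one dilated kernel: ``k + (k-1)(r-1)``."""
    if kernel_size < 1 or dilation_rate < 1:
        raise ValueError("kernel_size and dilation_rate must be >= 1")
    return kernel_size + (kernel_size - 1) * (dilation_rate - 1)


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two half-open boxes; 0 when disjoint."""
    ra0, ca0, ra1, ca1 = box_a
    rb0, cb0, rb1, cb1 = box_b
    if ra0 >= ra1 or ca0 >= ca1 or rb0 >= rb1 or cb0 >= cb1:
        raise ValueError("degenerate box")
    ir = max(0.0, min(ra1, rb1) - max(ra0, rb0))
    ic = max(0.0, min(ca1, cb1) - max(ca0, cb0))
    inter = ir * ic
    union = (ra1 - ra0) * (ca1 - ca0) + (rb1 - rb0) * (cb1 - cb0) - inter
    return inter / union if union > 0 else 0.0


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """(K, M) pairwise IoU, vectorised."""
    if boxes_a.size == 0 or boxes_b.size == 0:
        return np.zeros((boxes_a.shape[0], boxes_b.shape[0]))
    a = boxes_a[:, None, :]
    b = boxes_b[None, :, :]
    ir = np.clip(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]), 0, None)
    ic = np.clip(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]), 0, None)
    inter = ir * ic
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    union = area_a + area_b - inter
    return np.where(union > 0, inter / union, 0.0)


def generate_anchors(image_size: tuple[int, int], config: DetectorConfig) -> AnchorSet:
    """One square anchor per scale per stride-grid position per level,
    clipped to the image bounds."""
    h, w = image_size
    out = AnchorSet(image_size=(h, w))
    for stride, scales in zip(config.strides(), config.scales()):
        gh, gw = h // stride, w // stride
        cy = (np.arange(gh) + 0.5) * stride
        cx = (np.arange(gw) + 0.5) * stride
        boxes = []
        for s in scales:
            half = s / 2.0
            yy, xx = np.meshgrid(cy, cx, indexing="ij")
            b = np.stack([yy - half, xx - half, yy + half, xx + half], axis=-1).reshape(-1, 4)
            boxes.append(b)
        # interleave scales per position: anchor index = pos * n_scales + scale
        lvl = np.stack(boxes, axis=1).reshape(-1, 4)
        lvl[:, 0] = np.clip(lvl[:, 0], 0, h)
        lvl[:, 1] = np.clip(lvl[:, 1], 0, w)
        lvl[:, 2] = np.clip(lvl[:, 2], 0, h)
        lvl[:, 3] = np.clip(lvl[:, 3], 0, w)
        out.levels.append((stride, lvl))
    return out


def assign_and_sample(
    anchors: AnchorSet,
    gt_boxes: np.ndarray,
    config: DetectorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label every anchor and sample a training subset.

    Returns ``(labels, pos_idx, neg_idx)`` where ``labels`` is +1 / 0 / -1
    (positive / negative / ignore) over the flattened anchor list.  The
    best-IoU anchor for each ground-truth box is forced positive.  Sampled
    positives are capped at ``max_positives``; sampled negatives are drawn
    at random (under ``rng``) to respect ``pos_neg_ratio``.
    """
    boxes = anchors.boxes
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    k = boxes.shape[0]
    if gt_boxes.shape[0] == 0:
        labels = np.zeros(k, dtype=np.int64)
        neg_idx = np.arange(k)
        return labels, np.zeros(0, dtype=np.int64), neg_idx
    mat = iou_matrix(boxes, gt_boxes)
    best = mat.max(axis=1)
    labels = np.full(k, -1, dtype=np.int64)
    labels[best < config.neg_iou_thresh] = 0
    labels[best >= config.pos_iou_thresh] = 1
    labels[mat.argmax(axis=0)] = 1  # best anchor per gt always positive
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    rng = rng or np.random.default_rng()
    if pos_idx.size > config.max_positives:
        pos_idx = np.sort(rng.choice(pos_idx, config.max_positives, replace=False))
    n_neg = min(neg_idx.size, max(1, pos_idx.size) * config.pos_neg_ratio)
    if neg_idx.size > n_neg:
        neg_idx = np.sort(rng.choice(neg_idx, n_neg, replace=False))
    return labels, pos_idx, neg_idx


def nms(detections: list[BoxDetection], nms_iou: float) -> list[BoxDetection]:
    """Greedy non-maximum suppression; kept set in descending score order,
    score ties broken by lower input index."""
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].score, i))
    kept: list[int] = []
    for i in order:
        if all(iou(detections[i].box, detections[j].box) <= nms_iou for j in kept):
            kept.append(i)
    return [detections[i] for i in kept]


# -- box parameterisation -------------------------------------------------

def encode_boxes(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Centre/size offsets of gt relative to anchors, normalised by anchor size."""
    ah = anchors[:, 2] - anchors[:, 0]
    aw = anchors[:, 3] - anchors[:, 1]
    acy = (anchors[:, 0] + anchors[:, 2]) / 2
    acx = (anchors[:, 1] + anchors[:, 3]) / 2
    gh = gt[:, 2] - gt[:, 0]
    gw = gt[:, 3] - gt[:, 1]
    gcy = (gt[:, 0] + gt[:, 2]) / 2
    gcx = (gt[:, 1] + gt[:, 3]) / 2
    return np.stack([
        (gcy - acy) / ah, (gcx - acx) / aw, np.log(gh / ah), np.log(gw / aw),
    ], axis=1)


def decode_boxes(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    ah = anchors[:, 2] - anchors[:, 0]
    aw = anchors[:, 3] - anchors[:, 1]
    acy = (anchors[:, 0] + anchors[:, 2]) / 2
    acx = (anchors[:, 1] + anchors[:, 3]) / 2
    cy = acy + deltas[:, 0] * ah
    cx = acx + deltas[:, 1] * aw
    h = ah * np.exp(np.clip(deltas[:, 2], -4, 4))
    w = aw * np.exp(np.clip(deltas[:, 3], -4, 4))
    return np.stack([cy - h / 2, cx - w / 2, cy + h / 2, cx + w / 2], axis=1)


def smooth_l1(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Value and derivative of the smooth-L1 (Huber, delta=1) penalty."""
    ax = np.abs(x)
    val = np.where(ax < 1.0, 0.5 * x * x, ax - 0.5)
    grad = np.where(ax < 1.0, x, np.sign(x))
    return val, grad


# -- ROI align ------------------------------------------------------------

class RoiAlign:
    """Bilinear 14x14 ROI crop from a single feature level, with backward."""

    def __init__(self, stride: int, out_size: int = MASK_SIZE):
        self.stride = stride
        self.out = out_size
        self._cache = None

    def forward(self, feat: np.ndarray, box: tuple[float, float, float, float]) -> np.ndarray:
        c, fh, fw = feat.shape
        r0, c0, r1, c1 = box
        n = self.out
        ys = (r0 + (np.arange(n) + 0.5) * (r1 - r0) / n) / self.stride - 0.5
        xs = (c0 + (np.arange(n) + 0.5) * (c1 - c0) / n) / self.stride - 0.5
        ys = np.clip(ys, 0, fh - 1)
        xs = np.clip(xs, 0, fw - 1)
        y0 = np.floor(ys).astype(int)
        x0 = np.floor(xs).astype(int)
        y1 = np.minimum(y0 + 1, fh - 1)
        x1 = np.minimum(x0 + 1, fw - 1)
        wy = (ys - y0)[:, None]
        wx = (xs - x0)[None, :]
        f00 = feat[:, y0[:, None], x0[None, :]]
        f01 = feat[:, y0[:, None], x1[None, :]]
        f10 = feat[:, y1[:, None], x0[None, :]]
        f11 = feat[:, y1[:, None], x1[None, :]]
        out = (f00 * (1 - wy) * (1 - wx) + f01 * (1 - wy) * wx
               + f10 * wy * (1 - wx) + f11 * wy * wx)
        self._cache = (feat.shape, y0, y1, x0, x1, wy, wx)
        return out

    def backward(self, dout: np.ndarray, dfeat: np.ndarray) -> None:
        _shape, y0, y1, x0, x1, wy, wx = self._cache
        for (yy, ww_y) in ((y0, 1 - wy), (y1, wy)):
            for (xx, ww_x) in ((x0, 1 - wx), (x1, wx)):
                g = dout * ww_y * ww_x
                np.add.at(dfeat, (slice(None), yy[:, None], xx[None, :]), g)


# -- backbone + FPN -------------------------------------------------------

class BackboneFPN:
    """Bottom-up stages (last one dilated) plus a top-down feature pyramid."""

    def __init__(self, config: DetectorConfig, rng: np.random.Generator, in_ch: int = 3):
        self.config = config
        fc = config.fpn_channels
        self.stem = (Conv2d(in_ch, 16, 3, rng), ReLU(), MaxPool2x2())
        self.stages = []
        ch = 16
        for lv in range(config.fpn_levels):
            out_ch = 32 + 16 * lv
            last = lv == config.fpn_levels - 1
            conv = Conv2d(ch, out_ch, config.kernel_size if last else 3, rng,
                          dilation=config.dilation_rate if last else 1)
            self.stages.append((conv, ReLU(), MaxPool2x2()))
            ch = out_ch
        self.laterals = [Conv2d(32 + 16 * lv, fc, 1, rng) for lv in range(config.fpn_levels)]
        self.smooth = [Conv2d(fc, fc, 3, rng) for _ in range(config.fpn_levels)]
        self.ups = [NearestUpsample2x2() for _ in range(config.fpn_levels - 1)]

    def params(self) -> list[Param]:
        ps: list[Param] = []
        ps += self.stem[0].params()
        for conv, _r, _p in self.stages:
            ps += conv.params()
        for c in self.laterals + self.smooth:
            ps += c.params()
        return ps

    def named_params(self) -> dict[str, Param]:
        out: dict[str, Param] = {"stem.w": self.stem[0].w, "stem.b": self.stem[0].b}
        for i, (conv, _r, _p) in enumerate(self.stages):
            out[f"stage{i}.w"], out[f"stage{i}.b"] = conv.w, conv.b
        for i, c in enumerate(self.laterals):
            out[f"lat{i}.w"], out[f"lat{i}.b"] = c.w, c.b
        for i, c in enumerate(self.smooth):
            out[f"smooth{i}.w"], out[f"smooth{i}.b"] = c.w, c.b
        return out

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """(N, 3, H, W) -> pyramid [P0 (stride 4), P1 (stride 8), ...]."""
        conv, relu, pool = self.stem
        x = pool.forward(relu.forward(conv.forward(x)))
        cs = []
        for conv, relu, pool in self.stages:
            x = pool.forward(relu.forward(conv.forward(x)))
            cs.append(x)
        lats = [lat.forward(c) for lat, c in zip(self.laterals, cs)]
        ps = [None] * len(lats)
        ps[-1] = lats[-1]
        for i in range(len(lats) - 2, -1, -1):
            ps[i] = lats[i] + self.ups[i].forward(ps[i + 1])
        return [s.forward(p) for s, p in zip(self.smooth, ps)]

    def backward(self, dps: list[np.ndarray]) -> None:
        dps = [s.backward(dp) for s, dp in zip(self.smooth, dps)]
        dlats = [None] * len(dps)
        carry = None
        for i in range(len(dps)):
            d = dps[i] if carry is None else dps[i] + carry
            dlats[i] = d
            if i < len(dps) - 1:
                carry = self.ups[i].backward(d)
            # note: carry contributes to the next (coarser) level's gradient
        dcs = [lat.backward(d) for lat, d in zip(self.laterals, dlats)]
        dx = None
        for (conv, relu, pool), dc in zip(reversed(self.stages), reversed(dcs)):
            d = dc if dx is None else dc + dx
            dx = conv.backward(relu.backward(pool.backward(d)))
        conv, relu, pool = self.stem
        conv.backward(relu.backward(pool.backward(dx)))


def build_backbone_fpn(config: DetectorConfig, seed: int = 0) -> BackboneFPN:
    return BackboneFPN(config, np.random.default_rng(seed))


class Detector:
    """FPN backbone + shared objectness/box head + class-agnostic mask head."""

    def __init__(self, config: DetectorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        fc = config.fpn_channels
        self.backbone = BackboneFPN(config, rng)
        a = len(config.scales()[0])
        self.n_anchors_per_pos = a
        self.head_conv = Conv2d(fc, fc, 3, rng)
        self.head_relu = ReLU()
        self.obj_conv = Conv2d(fc, a, 1, rng)
        self.box_conv = Conv2d(fc, 4 * a, 1, rng)
        self.mask_convs = (Conv2d(fc, fc, 3, rng), ReLU(), Conv2d(fc, fc, 3, rng), ReLU(),
                           Conv2d(fc, 1, 1, rng))

    def params(self) -> list[Param]:
        ps = self.backbone.params()
        for c in (self.head_conv, self.obj_conv, self.box_conv,
                  self.mask_convs[0], self.mask_convs[2], self.mask_convs[4]):
            ps += c.params()
        return ps

    def named_params(self) -> dict[str, Param]:
        out = self.backbone.named_params()
        heads = {
            "head": self.head_conv, "obj": self.obj_conv, "box": self.box_conv,
            "mask0": self.mask_convs[0], "mask1": self.mask_convs[2],
            "mask2": self.mask_convs[4],
        }
        for k, c in heads.items():
            out[f"{k}.w"], out[f"{k}.b"] = c.w, c.b
        return out

    def save(self, path) -> None:
        nnet.save_params(path, self.named_params())

    def load(self, path) -> None:
        nnet.load_params(path, self.named_params())

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray):
        """Returns (pyramid, per-level head activations, flat obj logits,
        flat box deltas) with the flat order matching generate_anchors."""
        ps = self.backbone.forward(x)
        self._head_caches = []
        obj_flat, box_flat = [], []
        a = self.n_anchors_per_pos
        for p in ps:
            hc = Conv2d.__new__(Conv2d)  # shared weights, per-level cache
            hc.__dict__ = dict(self.head_conv.__dict__)
            relu = ReLU()
            oc = Conv2d.__new__(Conv2d)
            oc.__dict__ = dict(self.obj_conv.__dict__)
            bc = Conv2d.__new__(Conv2d)
            bc.__dict__ = dict(self.box_conv.__dict__)
            h = relu.forward(hc.forward(p))
            obj = oc.forward(h)  # (1, A, gh, gw)
            box = bc.forward(h)  # (1, 4A, gh, gw)
            self._head_caches.append((hc, relu, oc, bc, obj.shape, box.shape))
            _n, _a, gh, gw = obj.shape
            obj_flat.append(obj[0].transpose(1, 2, 0).reshape(-1))  # pos-major, scale-minor
            box_flat.append(box[0].reshape(a, 4, gh, gw).transpose(2, 3, 0, 1).reshape(-1, 4))
        return ps, np.concatenate(obj_flat), np.concatenate(box_flat)

    def backward_heads(self, dobj_flat: np.ndarray, dbox_flat: np.ndarray,
                       extra_dps: list[np.ndarray] | None = None) -> None:
        """Backprop flat head gradients (and optional extra pyramid grads,
        e.g. from the mask head) down through the backbone."""
        a = self.n_anchors_per_pos
        dps = []
        off = 0
        for (hc, relu, oc, bc, obj_shape, box_shape) in self._head_caches:
            _n, _ca, gh, gw = obj_shape
            k = gh * gw * a
            dobj = dobj_flat[off:off + k].reshape(gh, gw, a).transpose(2, 0, 1)[None]
            dbox = dbox_flat[off:off + k].reshape(gh, gw, a, 4).transpose(2, 3, 0, 1)
            dbox = dbox.reshape(1, 4 * a, gh, gw)
            off += k
            dh = oc.backward(dobj) + bc.backward(dbox)
            dp = hc.backward(relu.backward(dh))
            # fold the per-level gradients back into the shared parameters
            for shared, local in ((self.head_conv, hc), (self.obj_conv, oc), (self.box_conv, bc)):
                if shared.w is not local.w:
                    shared.w.grad += local.w.grad
                    shared.b.grad += local.b.grad
            dps.append(dp)
        if extra_dps is not None:
            dps = [d + e for d, e in zip(dps, extra_dps)]
        self.backbone.backward(dps)

    def mask_forward(self, roi_feat: np.ndarray) -> np.ndarray:
        c1, r1, c2, r2, c3 = self.mask_convs
        x = roi_feat[None]
        return c3.forward(r2.forward(c2.forward(r1.forward(c1.forward(x)))))[0, 0]

    def mask_backward(self, dlogits: np.ndarray) -> np.ndarray:
        c1, r1, c2, r2, c3 = self.mask_convs
        d = c3.backward(dlogits[None, None])
        d = c1.backward(r1.backward(c2.backward(r2.backward(d))))
        return d[0]


def _resize_mask(mask: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize used to rasterise 14x14 mask probabilities
    into a box."""
    h, w = mask.shape
    oh, ow = out_shape
    ri = np.clip((np.arange(oh) + 0.5) * h / oh, 0, h - 1).astype(int)
    ci = np.clip((np.arange(ow) + 0.5) * w / ow, 0, w - 1).astype(int)
    return mask[ri[:, None], ci[None, :]]


def _crop_resize_gt_mask(gt_mask: np.ndarray, box, out: int = MASK_SIZE) -> np.ndarray:
    r0, c0, r1, c1 = box
    h, w = gt_mask.shape
    ys = np.clip((r0 + (np.arange(out) + 0.5) * (r1 - r0) / out).astype(int), 0, h - 1)
    xs = np.clip((c0 + (np.arange(out) + 0.5) * (c1 - c0) / out).astype(int), 0, w - 1)
    return gt_mask[ys[:, None], xs[None, :]].astype(np.float64)


def train_detector(
    model: Detector,
    dataset: list[tuple[np.ndarray, np.ndarray, list[np.ndarray]]],
    steps: int,
    learning_rate: float = 0.01,
    l2_lambda: float = 1e-4,
    seed: int = 0,
    box_loss_weight: float = 1.0,
    mask_loss_weight: float = 1.0,
    grad_clip: float | None = 5.0,
) -> list[float]:
    """Train on ``(image HxWx3, gt_boxes (M,4), gt_masks)`` samples for a
    fixed number of single-image SGD steps; returns the per-step loss history.

    Objectness uses binary cross-entropy over the sampled anchor subset, box
    regression smooth-L1 on positives, and the mask head binary
    cross-entropy on ground-truth ROIs (teacher forcing).
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(seed)
    opt = SGD(model.params(), lr=learning_rate, l2_lambda=l2_lambda, grad_clip=grad_clip)
    cfg = model.config
    anchors_cache: dict[tuple[int, int], AnchorSet] = {}
    history: list[float] = []
    for step in range(steps):
        img, gt_boxes, gt_masks = dataset[int(rng.integers(len(dataset)))]
        hw = img.shape[:2]
        anchors = anchors_cache.setdefault(hw, generate_anchors(hw, cfg))
        _labels, pos_idx, neg_idx = assign_and_sample(anchors, gt_boxes, cfg, rng)
        x = img.transpose(2, 0, 1)[None]
        ps, obj_flat, box_flat = model.forward(x)
        boxes = anchors.boxes
        dobj = np.zeros_like(obj_flat)
        dbox = np.zeros_like(box_flat)
        n_samp = pos_idx.size + neg_idx.size
        loss = 0.0
        # objectness BCE
        for idx_set, target in ((pos_idx, 1.0), (neg_idx, 0.0)):
            if idx_set.size == 0:
                continue
            z = obj_flat[idx_set]
            p = nnet.sigmoid(z)
            loss += float(np.sum(-(target * np.log(np.maximum(p, 1e-12))
                                   + (1 - target) * np.log(np.maximum(1 - p, 1e-12))))) / n_samp
            dobj[idx_set] = (p - target) / n_samp
        # box regression on positives
        if pos_idx.size and gt_boxes.size:
            mat = iou_matrix(boxes[pos_idx], gt_boxes)
            tgt = encode_boxes(boxes[pos_idx], gt_boxes[mat.argmax(axis=1)])
            diff = box_flat[pos_idx] - tgt
            val, grad = smooth_l1(diff)
            loss += box_loss_weight * float(val.mean())
            dbox[pos_idx] = box_loss_weight * grad / val.size
        # mask head on gt ROIs from the finest level
        extra = [np.zeros_like(p) for p in ps]
        if len(gt_masks):
            stride0 = cfg.strides()[0]
            for gt_box, gt_mask in zip(gt_boxes, gt_masks):
                ra = RoiAlign(stride0)
                feat = ps[0][0]
                roi = ra.forward(feat, tuple(gt_box))
                logits = model.mask_forward(roi)
                p = nnet.sigmoid(logits)
                t = _crop_resize_gt_mask(gt_mask, gt_box)
                loss += mask_loss_weight * float(np.mean(
                    -(t * np.log(np.maximum(p, 1e-12))
                      + (1 - t) * np.log(np.maximum(1 - p, 1e-12))))) / len(gt_masks)
                dlog = mask_loss_weight * (p - t) / (p.size * len(gt_masks))
                droi = model.mask_backward(dlog)
                ra.backward(droi, extra[0][0])
        opt.zero_grad()
        model.backward_heads(dobj, dbox, extra)
        opt.step()
        history.append(loss)
    return history


def detect_instances(
    model: Detector,
    image: HEImage | np.ndarray,
    config: DetectorConfig | None = None,
    max_pre_nms: int = 200,
) -> list[BoxDetection]:
    """Score anchors, decode boxes, threshold, NMS, and predict a full-image
    binary mask per kept detection."""
    cfg = config or model.config
    px = image.pixels if isinstance(image, HEImage) else np.asarray(image, dtype=np.float64)
    h, w = px.shape[:2]
    anchors = generate_anchors((h, w), model.config)
    ps, obj_flat, box_flat = model.forward(px.transpose(2, 0, 1)[None])
    scores = nnet.sigmoid(obj_flat)
    keep = np.flatnonzero(scores >= cfg.score_thresh)
    if keep.size == 0:
        return []
    keep = keep[np.argsort(-scores[keep], kind="stable")][:max_pre_nms]
    decoded = decode_boxes(anchors.boxes[keep], box_flat[keep])
    decoded[:, 0] = np.clip(decoded[:, 0], 0, h)
    decoded[:, 1] = np.clip(decoded[:, 1], 0, w)
    decoded[:, 2] = np.clip(decoded[:, 2], 0, h)
    decoded[:, 3] = np.clip(decoded[:, 3], 0, w)
    dets = []
    for b, s in zip(decoded, scores[keep]):
        if b[2] - b[0] >= 2 and b[3] - b[1] >= 2:
            dets.append(BoxDetection(box=tuple(b), score=float(s)))
    kept = nms(dets, cfg.nms_iou)
    stride0 = model.config.strides()[0]
    for det in kept:
        ra = RoiAlign(stride0)
        roi = ra.forward(ps[0][0], det.box)
        probs = nnet.sigmoid(model.mask_forward(roi))
        r0, c0, r1, c1 = (int(round(v)) for v in det.box)
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, h), min(c1, w)
        full = np.zeros((h, w), dtype=bool)
        if r1 > r0 and c1 > c0:
            full[r0:r1, c0:c1] = _resize_mask(probs, (r1 - r0, c1 - c0)) >= cfg.mask_thresh
        det.mask = full
    return kept


def detection_probmap(
    detections: list[BoxDetection], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterise detections into a 2-class HxWx2 probability map for fusion:
    foreground probability = max detection score covering the pixel."""
    fg = np.zeros(shape, dtype=np.float64)
    for det in detections:
        if det.mask is not None:
            np.maximum(fg, np.where(det.mask, det.score, 0.0), out=fg)
    return np.stack([1.0 - fg, fg], axis=-1)
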
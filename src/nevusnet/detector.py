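"""Lesion detection network: lightweight backbone, attention neck, NMS-free
dual-assignment head.

The network follows a three-stage single-class design:

* **Backbone** — a PP-LCNet-style stack: 3x3/2 stem convolution, depthwise
  separable blocks (H-Swish throughout), 5x5 kernels with squeeze-and-
  excitation at the tail, an SPPF block (serial 5x5 max-pools) and an
  SE-style global recalibration (the "PSA" slot) at 1/32 resolution.
  Feature taps at strides 8/16/32 give the P3/P4/P5 pyramid.  A global-
  average-pool + 1x1 projection head (1280 channels at full width) exists
  for classification pre-training but is unused by detection training.
* **Neck** — a path-aggregation pyramid: top-down upsample+concat with C2f
  split-merge fusion, bottom-up separable stride-2 reduction (SCDown), and
  a multidimensional collaborative attention block before each of the three
  output nodes.
* **Head** — decoupled classification and box branches per scale, duplicated
  for one-to-many (training-only) and one-to-one label assignment.  Box
  regression decodes a 16-bin discrete distribution (DFL) per side and is
  optimised with the Shape-IoU loss; inference keeps only the one-to-one
  branch and applies no NMS.

Every component can be toggled independently (backbone family, attention
on/off, Shape-IoU vs CIoU) to reproduce single-module ablations.

The default "tiny" width profile targets CPU training on 64-160 px synthetic
images; the full-scale 640 px profile is available through the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import boxlosses as bl
from ._autograd import (SGD, BatchNorm2d, Conv2d, Module, Parameter, Tensor,
                        concat, conv2d, cosine_lr, hswish, log, maximum,
                        maxpool2d, relu, sigmoid, softmax, tensor,
                        upsample_nearest2d)
from .mca import MCA, MCAConfig

__all__ = [
    "BackboneConfig",
    "DetectorConfig",
    "TrainConfig",
    "DetectorOutput",
    "AssignmentResult",
    "PPLCNetBackbone",
    "CSPBaselineBackbone",
    "PANeck",
    "NevusDetector",
    "assign_targets",
    "train_step",
    "infer",
    "fit",
    "hswish",
    "ablation_variants",
    "build_detector",
]

STRIDES = (8, 16, 32)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackboneConfig:
    """Channel plan for the backbone taps (P3/P4/P5) and the stem."""

    stem_channels: int = 8
    p2_channels: int = 16
    p3_channels: int = 24
    p4_channels: int = 32
    p5_channels: int = 48
    cls_proj_channels: int = 128  # 1280 at full width


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation defaults (full-scale profile): 640 px input, batch 64,
    100 epochs, SGD momentum 0.9 / weight decay 5e-4, cosine LR 0.01 ->
    1e-5, early stop after 15 stagnant validation checks (validation every
    5 epochs)."""

    img_size: int = 640
    batch_size: int = 64
    epochs: int = 100
    lr0: float = 0.01
    lr1: float = 1e-5
    momentum: float = 0.9
    weight_decay: float = 5e-4
    val_every: int = 5
    patience: int = 15
    box_gain: float = 7.5
    cls_gain: float = 0.5
    dfl_gain: float = 1.5


@dataclass(frozen=True)
class DetectorConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    neck_channels: int = 32
    reg_max: int = 16
    # ablation toggles
    use_pp_lcnet: bool = True
    use_mca: bool = True
    use_shape_iou: bool = True
    mca: MCAConfig = field(default_factory=MCAConfig)
    shape_iou: bl.ShapeIoUParams = field(default_factory=bl.ShapeIoUParams)
    # assignment
    topk: int = 10
    alpha: float = 1.0
    beta: float = 6.0
    conf_thresh: float = 0.5


@dataclass
class DetectorOutput:
    """Decoded detections for one image, scores sorted descending."""

    boxes: list[bl.BBox]
    scores: np.ndarray
    class_ids: np.ndarray


@dataclass
class AssignmentResult:
    """anchor_gt: per-anchor assigned gt index (-1 = negative)."""

    anchor_gt: np.ndarray
    positives: np.ndarray  # anchor indices


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ConvBNAct(Module):
    def __init__(self, cin, cout, k=3, stride=1, groups=1, rng=None, act=True):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, padding=k // 2,
                           groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return hswish(y) if self.act else y


class SEBlock(Module):
    """Squeeze-and-excitation channel recalibration (reduction 4)."""

    def __init__(self, c, rng=None):
        super().__init__()
        cr = max(c // 4, 2)
        self.fc1 = Conv2d(c, cr, 1, rng=rng)
        self.fc2 = Conv2d(cr, c, 1, rng=rng)

    def forward(self, x):
        s = x.mean(axis=(2, 3), keepdims=True)
        s = relu(self.fc1(s))
        s = sigmoid(self.fc2(s))
        return x * s


class DepthwiseSeparable(Module):
    """Depthwise k x k + pointwise 1x1, H-Swish, optional SE."""

    def __init__(self, cin, cout, k=3, stride=1, use_se=False, rng=None):
        super().__init__()
        self.dw = ConvBNAct(cin, cin, k, stride=stride, groups=cin, rng=rng)
        self.se = SEBlock(cin, rng=rng) if use_se else None
        self.pw = ConvBNAct(cin, cout, 1, rng=rng)

    def forward(self, x):
        y = self.dw(x)
        if self.se is not None:
            y = self.se(y)
        return self.pw(y)


class SPPF(Module):
    """Serial 5x5 max-pool pyramid with concatenation."""

    def __init__(self, c, rng=None):
        super().__init__()
        ch = max(c // 2, 4)
        self.cv1 = ConvBNAct(c, ch, 1, rng=rng)
        self.cv2 = ConvBNAct(ch * 4, c, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        p1 = maxpool2d(y, 5, stride=1, padding=2)
        p2 = maxpool2d(p1, 5, stride=1, padding=2)
        p3 = maxpool2d(p2, 5, stride=1, padding=2)
        return self.cv2(concat([y, p1, p2, p3], axis=1))


class Bottleneck(Module):
    def __init__(self, c, rng=None):
        super().__init__()
        self.cv1 = ConvBNAct(c, c, 3, rng=rng)
        self.cv2 = ConvBNAct(c, c, 3, rng=rng)

    def forward(self, x):
        return x + self.cv2(self.cv1(x))


class C2f(Module):
    """Split-merge fusion: 1x1 expand, split halves, bottleneck on one half,
    concatenate all branches, 1x1 merge."""

    def __init__(self, cin, cout, rng=None):
        super().__init__()
        self.ch = max(cout // 2, 4)
        self.cv1 = ConvBNAct(cin, 2 * self.ch, 1, rng=rng)
        self.m = Bottleneck(self.ch, rng=rng)
        self.cv2 = ConvBNAct(3 * self.ch, cout, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.ch]
        b = y[:, self.ch:]
        return self.cv2(concat([a, b, self.m(b)], axis=1))


class SCDown(Module):
    """Separable stride-2 reduction: depthwise 3x3/2 + pointwise 1x1."""

    def __init__(self, cin, cout, rng=None):
        super().__init__()
        self.dw = ConvBNAct(cin, cin, 3, stride=2, groups=cin, rng=rng,
                            act=False)
        self.pw = ConvBNAct(cin, cout, 1, rng=rng)

    def forward(self, x):
        return self.pw(self.dw(x))


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

class PPLCNetBackbone(Module):
    """Depthwise-separable backbone with 5x5 + SE tail, SPPF and SE-style
    global recalibration at 1/32.  Taps at strides 8, 16, 32."""

    def __init__(self, cfg: BackboneConfig, rng=None):
        super().__init__()
        c = cfg
        self.cfg = cfg
        self.stem = ConvBNAct(3, c.stem_channels, 3, stride=2, rng=rng)
        # first four depthwise-separable groups stay at 1/4 and 1/8
        self.s1a = DepthwiseSeparable(c.stem_channels, c.p2_channels,
                                      stride=2, rng=rng)          # 1/4
        self.s1b = DepthwiseSeparable(c.p2_channels, c.p2_channels, rng=rng)
        self.s2a = DepthwiseSeparable(c.p2_channels, c.p3_channels,
                                      stride=2, rng=rng)          # 1/8
        self.s2b = DepthwiseSeparable(c.p3_channels, c.p3_channels, rng=rng)
        self.s3a = DepthwiseSeparable(c.p3_channels, c.p4_channels,
                                      stride=2, rng=rng)          # 1/16
        self.s3b = DepthwiseSeparable(c.p4_channels, c.p4_channels, rng=rng)
        # 5x5 large-kernel tail with SE at 1/32
        self.s4a = DepthwiseSeparable(c.p4_channels, c.p5_channels, k=5,
                                      stride=2, use_se=True, rng=rng)  # 1/32
        self.s4b = DepthwiseSeparable(c.p5_channels, c.p5_channels, k=5,
                                      use_se=True, rng=rng)
        self.sppf = SPPF(c.p5_channels, rng=rng)
        self.psa = SEBlock(c.p5_channels, rng=rng)  # SE-style "PSA" slot
        # classification-pretrain path (unused by detection)
        self.cls_proj = Conv2d(c.p5_channels, c.cls_proj_channels, 1, rng=rng)

    @property
    def out_channels(self):
        return (self.cfg.p3_channels, self.cfg.p4_channels,
                self.cfg.p5_channels)

    def forward(self, x):
        y = self.stem(x)
        y = self.s1b(self.s1a(y))
        p3 = self.s2b(self.s2a(y))
        p4 = self.s3b(self.s3a(p3))
        p5 = self.s4b(self.s4a(p4))
        p5 = self.psa(self.sppf(p5))
        return p3, p4, p5

    def classify_features(self, x):
        """Global pooled 1x1 projection (classification-pretrain path)."""
        _, _, p5 = self.forward(x)
        return hswish(self.cls_proj(p5.mean(axis=(2, 3), keepdims=True)))


class CSPBaselineBackbone(Module):
    """Reference backbone with dense (non-separable) convolutions and a
    cross-stage split-merge block per stage; same taps and channel plan, used
    as the ablation baseline."""

    def __init__(self, cfg: BackboneConfig, rng=None):
        super().__init__()
        c = cfg
        self.cfg = cfg
        self.stem = ConvBNAct(3, c.stem_channels, 3, stride=2, rng=rng)
        self.d1 = ConvBNAct(c.stem_channels, c.p2_channels, 3, stride=2,
                            rng=rng)
        self.c1 = C2f(c.p2_channels, c.p2_channels, rng=rng)
        self.d2 = ConvBNAct(c.p2_channels, c.p3_channels, 3, stride=2,
                            rng=rng)
        self.c2 = C2f(c.p3_channels, c.p3_channels, rng=rng)
        self.d3 = ConvBNAct(c.p3_channels, c.p4_channels, 3, stride=2,
                            rng=rng)
        self.c3 = C2f(c.p4_channels, c.p4_channels, rng=rng)
        self.d4 = ConvBNAct(c.p4_channels, c.p5_channels, 3, stride=2,
                            rng=rng)
        self.c4 = C2f(c.p5_channels, c.p5_channels, rng=rng)
        self.sppf = SPPF(c.p5_channels, rng=rng)
        self.psa = SEBlock(c.p5_channels, rng=rng)

    @property
    def out_channels(self):
        return (self.cfg.p3_channels, self.cfg.p4_channels,
                self.cfg.p5_channels)

    def forward(self, x):
        y = self.c1(self.d1(self.stem(x)))
        p3 = self.c2(self.d2(y))
        p4 = self.c3(self.d3(p3))
        p5 = self.psa(self.sppf(self.c4(self.d4(p4))))
        return p3, p4, p5


# ---------------------------------------------------------------------------
# neck
# ---------------------------------------------------------------------------

class PANeck(Module):
    """Path-aggregation neck with attention before each output node."""

    def __init__(self, in_channels, width: int, use_mca: bool,
                 mca_cfg: MCAConfig, rng=None):
        super().__init__()
        c3, c4, c5 = in_channels
        self.l3 = ConvBNAct(c3, width, 1, rng=rng)
        self.l4 = ConvBNAct(c4, width, 1, rng=rng)
        self.l5 = ConvBNAct(c5, width, 1, rng=rng)
        self.td4 = C2f(2 * width, width, rng=rng)
        self.td3 = C2f(2 * width, width, rng=rng)
        self.down3 = SCDown(width, width, rng=rng)
        self.bu4 = C2f(2 * width, width, rng=rng)
        self.down4 = SCDown(width, width, rng=rng)
        self.bu5 = C2f(2 * width, width, rng=rng)
        self.use_mca = use_mca
        if use_mca:
            self.mca3 = MCA(width, mca_cfg, rng=rng)
            self.mca4 = MCA(width, mca_cfg, rng=rng)
            self.mca5 = MCA(width, mca_cfg, rng=rng)

    def forward(self, p3, p4, p5):
        l3, l4, l5 = self.l3(p3), self.l4(p4), self.l5(p5)
        t4 = self.td4(concat([upsample_nearest2d(l5), l4], axis=1))
        t3 = self.td3(concat([upsample_nearest2d(t4), l3], axis=1))
        b4 = self.bu4(concat([self.down3(t3), t4], axis=1))
        b5 = self.bu5(concat([self.down4(b4), l5], axis=1))
        if self.use_mca:
            t3, b4, b5 = self.mca3(t3), self.mca4(b4), self.mca5(b5)
        return t3, b4, b5


# ---------------------------------------------------------------------------
# head
# ---------------------------------------------------------------------------

class ScaleHead(Module):
    """Decoupled classification + DFL-regression branch for one scale."""

    def __init__(self, width: int, reg_max: int, rng=None):
        super().__init__()
        self.cls_conv = ConvBNAct(width, width, 3, rng=rng)
        self.cls_out = Conv2d(width, 1, 1, rng=rng)
        self.reg_conv = ConvBNAct(width, width, 3, rng=rng)
        self.reg_out = Conv2d(width, 4 * reg_max, 1, rng=rng)
        # start with low objectness and a box distribution biased to small
        # distances so early decoded boxes are compact
        self.cls_out.bias.data[:] = -4.0
        rb = self.reg_out.bias.data.reshape(4, reg_max)
        rb[:] = np.linspace(2.0, -2.0, reg_max)

    def forward(self, x):
        return (self.cls_out(self.cls_conv(x)),
                self.reg_out(self.reg_conv(x)))


class DualHead(Module):
    def __init__(self, width: int, reg_max: int, rng=None):
        super().__init__()
        self.heads = [ScaleHead(width, reg_max, rng=rng) for _ in STRIDES]

    def forward(self, feats):
        return [h(f) for h, f in zip(self.heads, feats)]


class NevusDetector(Module):
    """Full detector; single class ("nevus")."""

    def __init__(self, cfg: DetectorConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg or DetectorConfig()
        rng = np.random.default_rng(seed)
        bb = (PPLCNetBackbone if self.cfg.use_pp_lcnet
              else CSPBaselineBackbone)
        self.backbone = bb(self.cfg.backbone, rng=rng)
        self.neck = PANeck(self.backbone.out_channels, self.cfg.neck_channels,
                           self.cfg.use_mca, self.cfg.mca, rng=rng)
        self.head_o2m = DualHead(self.cfg.neck_channels, self.cfg.reg_max,
                                 rng=rng)
        self.head_o2o = DualHead(self.cfg.neck_channels, self.cfg.reg_max,
                                 rng=rng)

    # -- plumbing -------------------------------------------------------
    @staticmethod
    def pad_to_stride(images: np.ndarray) -> np.ndarray:
        """Zero-pad NCHW images so H and W are multiples of 32."""
        *_, h, w = images.shape
        ph = (-h) % 32
        pw = (-w) % 32
        if ph or pw:
            images = np.pad(images, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return images

    def features(self, images: np.ndarray | Tensor):
        x = tensor(images)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected NCHW RGB input")
        if x.shape[2] % 32 or x.shape[3] % 32:
            x = Tensor(self.pad_to_stride(x.data))
        p3, p4, p5 = self.backbone(x)
        return self.neck(p3, p4, p5)

    def anchor_points(self, img_hw: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Flattened anchor centres (x, y) in pixels and per-anchor stride."""
        h, w = img_hw
        pts, strides = [], []
        for s in STRIDES:
            hs, ws = h // s, w // s
            ys, xs = np.mgrid[0:hs, 0:ws]
            pts.append(np.stack([(xs.ravel() + 0.5) * s,
                                 (ys.ravel() + 0.5) * s], axis=1))
            strides.append(np.full(hs * ws, s, dtype=np.float64))
        return np.concatenate(pts), np.concatenate(strides)

    def _flatten_head(self, outputs):
        """(cls logits, reg logits) per scale -> (N, A) and (N, A, 4, reg_max)."""
        cls_list, reg_list = [], []
        for cls_map, reg_map in outputs:
            n, _, hs, ws = cls_map.shape
            cls_list.append(cls_map.reshape(n, hs * ws))
            reg_list.append(reg_map.reshape(n, 4, self.cfg.reg_max, hs * ws)
                            .permute(0, 3, 1, 2))
        return concat(cls_list, axis=1), concat(reg_list, axis=1)

    def decode_boxes(self, reg: Tensor, pts: np.ndarray,
                     strides: np.ndarray) -> tuple:
        """DFL expectation -> (cx, cy, w, h) tensors in image pixels."""
        proj = np.arange(self.cfg.reg_max, dtype=np.float64)
        prob = softmax(reg, axis=-1)
        dist = (prob * proj).sum(axis=-1)  # (N, A, 4) ltrb in stride units
        st = strides[None, :, None]
        d = dist * st
        l, t = d[:, :, 0], d[:, :, 1]
        r, b = d[:, :, 2], d[:, :, 3]
        px = pts[None, :, 0]
        py = pts[None, :, 1]
        cx = px + (r - l) * 0.5
        cy = py + (b - t) * 0.5
        w = l + r
        h = t + b
        return cx, cy, w, h

    def forward(self, images):
        feats = self.features(images)
        return (self._flatten_head(self.head_o2m(feats)),
                self._flatten_head(self.head_o2o(feats)))


# ---------------------------------------------------------------------------
# label assignment
# ---------------------------------------------------------------------------

def assign_targets(anchor_boxes: np.ndarray, anchor_scores: np.ndarray,
                   anchor_pts: np.ndarray, gts: list[bl.BBox], mode: str,
                   topk: int = 10, alpha: float = 1.0,
                   beta: float = 6.0) -> AssignmentResult:
    """Task-aligned assignment: rank candidates by score**alpha * IoU**beta.

    one2many keeps the top-k anchors per gt, one2one the single best; ties
    break to the lowest anchor index.  Anchors claimed by several gts go to
    the gt of highest IoU.  Empty gt lists yield all negatives.
    """
    n_anchor = len(anchor_boxes)
    anchor_gt = np.full(n_anchor, -1, dtype=np.int64)
    if not gts:
        return AssignmentResult(anchor_gt, np.empty(0, dtype=np.int64))
    k = topk if mode == "one2many" else 1
    gt_arr = np.stack([g.to_array() for g in gts])
    iou_mat = np.zeros((len(gts), n_anchor))
    for gi, g in enumerate(gt_arr):
        iou_mat[gi] = bl.iou_xywh(anchor_boxes[:, 0], anchor_boxes[:, 1],
                                  np.maximum(anchor_boxes[:, 2], 1e-9),
                                  np.maximum(anchor_boxes[:, 3], 1e-9),
                                  g[0], g[1], g[2], g[3])
    metric = np.power(np.clip(anchor_scores, 1e-12, 1.0), alpha)[None, :] \
        * np.power(iou_mat, beta)
    # centre prior: anchor centre inside the gt box
    inside = np.ones_like(metric, dtype=bool)
    for gi, g in enumerate(gt_arr):
        x1, y1 = g[0] - g[2] / 2, g[1] - g[3] / 2
        x2, y2 = g[0] + g[2] / 2, g[1] + g[3] / 2
        inside[gi] = ((anchor_pts[:, 0] >= x1) & (anchor_pts[:, 0] <= x2)
                      & (anchor_pts[:, 1] >= y1) & (anchor_pts[:, 1] <= y2))
    best_iou = np.full(n_anchor, -1.0)
    for gi in range(len(gts)):
        cand = metric[gi].copy()
        cand[~inside[gi]] = -np.inf
        if not np.isfinite(cand).any() or cand.max() == -np.inf:
            # degenerate gt with no interior anchor: nearest anchor centre
            d = np.hypot(anchor_pts[:, 0] - gt_arr[gi, 0],
                         anchor_pts[:, 1] - gt_arr[gi, 1])
            order = np.argsort(d, kind="stable")[:k]
        else:
            # stable sort on (-metric, index) -> lowest index wins ties
            order = np.argsort(-cand, kind="stable")
            order = order[np.isfinite(cand[order])][:k]
        for ai in order:
            if iou_mat[gi, ai] > best_iou[ai]:
                best_iou[ai] = iou_mat[gi, ai]
                anchor_gt[ai] = gi
    if mode == "one2one":
        # each gt keeps exactly one anchor
        for gi in range(len(gts)):
            mine = np.flatnonzero(anchor_gt == gi)
            if len(mine) > 1:
                keep = mine[np.argmax(metric[gi, mine])]
                anchor_gt[mine] = -1
                anchor_gt[keep] = gi
    return AssignmentResult(anchor_gt, np.flatnonzero(anchor_gt >= 0))


# ---------------------------------------------------------------------------
# losses / training
# ---------------------------------------------------------------------------

def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on raw logits."""
    z = logits
    t = Tensor(targets)
    # log(1 + e^z) = max(z,0) + log(1 + e^{-|z|})
    from ._autograd import absolute, exp as _exp, maximum as _max
    softplus = _max(z, 0.0) + log(1.0 + _exp(-absolute(z)))
    return softplus - z * t


def _head_loss(model: NevusDetector, cls: Tensor, reg: Tensor,
               pts: np.ndarray, strides: np.ndarray,
               gts_batch: list[list[bl.BBox]], mode: str,
               tc: TrainConfig) -> dict:
    cfg = model.cfg
    cxs, cys, ws, hs = model.decode_boxes(reg, pts, strides)
    scores = sigmoid(cls)
    n_img, n_anchor = cls.shape
    targets = np.zeros((n_img, n_anchor))
    pos_img, pos_anchor, pos_gt = [], [], []
    for i, gts in enumerate(gts_batch):
        boxes_np = np.stack([cxs.data[i], cys.data[i],
                             ws.data[i], hs.data[i]], axis=1)
        res = assign_targets(boxes_np, scores.data[i], pts, gts, mode,
                             cfg.topk, cfg.alpha, cfg.beta)
        for ai in res.positives:
            targets[i, ai] = 1.0
            pos_img.append(i)
            pos_anchor.append(ai)
            pos_gt.append(gts[res.anchor_gt[ai]])
    n_pos = max(len(pos_img), 1)
    cls_loss = _bce_with_logits(cls, targets).sum() * (1.0 / n_pos)
    if not pos_img:
        zero = Tensor(np.zeros(()))
        return {"box": zero, "cls": cls_loss, "dfl": zero, "n_pos": 0}
    ii = np.asarray(pos_img)
    aa = np.asarray(pos_anchor)
    gt_arr = np.stack([g.to_array() for g in pos_gt])
    b = (cxs[ii, aa], cys[ii, aa],
         maximum(ws[ii, aa], 1e-6), maximum(hs[ii, aa], 1e-6))
    gt = (gt_arr[:, 0], gt_arr[:, 1], gt_arr[:, 2], gt_arr[:, 3])
    if cfg.use_shape_iou:
        *_, total = bl.shape_iou_terms(b, gt, cfg.shape_iou.scale,
                                       cfg.shape_iou.theta,
                                       cfg.shape_iou.omega_weight)
    else:
        *_, total = bl.ciou_terms(b, gt)
    box_loss = total.mean()
    # DFL: cross-entropy to the two integer bins bracketing each gt distance
    st = strides[aa]
    px, py = pts[aa, 0], pts[aa, 1]
    gl = (px - (gt_arr[:, 0] - gt_arr[:, 2] / 2)) / st
    gtp = (py - (gt_arr[:, 1] - gt_arr[:, 3] / 2)) / st
    gr = ((gt_arr[:, 0] + gt_arr[:, 2] / 2) - px) / st
    gb = ((gt_arr[:, 1] + gt_arr[:, 3] / 2) - py) / st
    dist_t = np.clip(np.stack([gl, gtp, gr, gb], axis=1), 0.0,
                     cfg.reg_max - 1 - 1e-3)
    lo = np.floor(dist_t).astype(int)
    hi = lo + 1
    w_hi = dist_t - lo
    w_lo = 1.0 - w_hi
    reg_pos = reg[ii, aa]                       # (P, 4, reg_max)
    logp = log(softmax(reg_pos, axis=-1) + 1e-12)
    pidx = np.arange(len(ii))[:, None] * np.ones((1, 4), dtype=int)
    sidx = np.ones((len(ii), 1), dtype=int) * np.arange(4)[None, :]
    dfl = -(logp[pidx, sidx, lo] * w_lo + logp[pidx, sidx, hi] * w_hi)
    dfl_loss = dfl.mean()
    return {"box": box_loss, "cls": cls_loss, "dfl": dfl_loss,
            "n_pos": len(pos_img)}


def train_step(model: NevusDetector, images: np.ndarray,
               gts_batch: list[list[bl.BBox]], optimizer: SGD | None = None,
               tc: TrainConfig | None = None) -> dict:
    """One optimisation step on a batch; returns the three loss components.

    images : (N, 3, H, W) normalised floats.  gts_batch : per-image gt boxes
    in pixel coordinates.  With optimizer=None only the forward pass and
    loss evaluation run (no update).
    """
    tc = tc or TrainConfig()
    model.train()
    (cls_m, reg_m), (cls_o, reg_o) = model.forward(images)
    pts, strides = model.anchor_points(images.shape[2:])
    lm = _head_loss(model, cls_m, reg_m, pts, strides, gts_batch,
                    "one2many", tc)
    lo = _head_loss(model, cls_o, reg_o, pts, strides, gts_batch,
                    "one2one", tc)
    box = lm["box"] + lo["box"]
    cls = lm["cls"] + lo["cls"]
    dfl = lm["dfl"] + lo["dfl"]
    total = box * tc.box_gain + cls * tc.cls_gain + dfl * tc.dfl_gain
    if not np.isfinite(total.data):
        raise FloatingPointError("non-finite training loss; aborting step")
    if optimizer is not None:
        optimizer.zero_grad()
        total.backward()
        optimizer.step()
    return {"box": float(box.data), "cls": float(cls.data),
            "dfl": float(dfl.data), "total": float(total.data)}


def infer(model: NevusDetector, image: np.ndarray,
          conf_thresh: float | None = None) -> DetectorOutput:
    """NMS-free inference through the one-to-one branch for one image.

    image : (3, H, W) normalised floats.  Detections below the confidence
    threshold (default 0.5) are dropped; scores come back sorted descending.
    """
    cfg = model.cfg
    if conf_thresh is None:
        conf_thresh = cfg.conf_thresh
    model.eval()
    x = image[None] if image.ndim == 3 else image
    _, (cls_o, reg_o) = model.forward(x)
    pts, strides = model.anchor_points(x.shape[2:])
    scores = sigmoid(cls_o).data[0]
    cxs, cys, ws, hs = model.decode_boxes(reg_o, pts, strides)
    keep = np.flatnonzero(scores >= conf_thresh)
    keep = keep[np.argsort(-scores[keep], kind="stable")]
    boxes = [bl.BBox(float(cxs.data[0, i]), float(cys.data[0, i]),
                     float(max(ws.data[0, i], 1e-6)),
                     float(max(hs.data[0, i], 1e-6))) for i in keep]
    return DetectorOutput(boxes=boxes, scores=scores[keep],
                          class_ids=np.zeros(len(keep), dtype=int))


def fit(model: NevusDetector, images: np.ndarray,
        gts: list[list[bl.BBox]], tc: TrainConfig,
        val_images: np.ndarray | None = None,
        val_gts: list[list[bl.BBox]] | None = None,
        seed: int = 0, log: list | None = None,
        eval_fn=None) -> dict:
    """Mini training loop: SGD + cosine decay, periodic validation with
    best-checkpoint keeping and early stopping on stagnant validation
    mAP@0.5.  Returns {"best_map": float, "log": rows}."""
    rng = np.random.default_rng(seed)
    opt = SGD(model.parameters(), lr=tc.lr0, momentum=tc.momentum,
              weight_decay=tc.weight_decay)
    n = len(images)
    steps_per_epoch = max(1, int(np.ceil(n / tc.batch_size)))
    total_steps = steps_per_epoch * tc.epochs
    step = 0
    best_map, best_state, stagnant = -1.0, None, 0
    history = log if log is not None else []
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        ep = {"box": 0.0, "cls": 0.0, "dfl": 0.0}
        for b0 in range(0, n, tc.batch_size):
            idx = order[b0:b0 + tc.batch_size]
            opt.lr = cosine_lr(step, total_steps, tc.lr0, tc.lr1)
            losses = train_step(model, images[idx],
                                [gts[i] for i in idx], opt, tc)
            for k in ep:
                ep[k] += losses[k] * len(idx) / n
            step += 1
        row = {"epoch": epoch, **{k: round(v, 5) for k, v in ep.items()}}
        if (val_images is not None and eval_fn is not None
                and (epoch + 1) % tc.val_every == 0):
            m = eval_fn(model, val_images, val_gts)
            row["map50"] = m
            if m > best_map:
                best_map, best_state, stagnant = m, model.state_dict(), 0
            else:
                stagnant += tc.val_every
            if stagnant >= tc.patience:
                history.append(row)
                break
        history.append(row)
    if best_state is not None:
        model.load_state_dict(best_state)
    return {"best_map": best_map, "log": history}


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

def ablation_variants(base: DetectorConfig | None = None) -> dict[str, DetectorConfig]:
    """The five single-toggle configurations: baseline, each module alone,
    and the full model."""
    base = base or DetectorConfig()
    off = replace(base, use_pp_lcnet=False, use_mca=False,
                  use_shape_iou=False)
    return {
        "baseline": off,
        "pp_lcnet": replace(off, use_pp_lcnet=True),
        "mca": replace(off, use_mca=True),
        "shape_iou": replace(off, use_shape_iou=True),
        "full": base,
    }


def build_detector(variant: str = "full", seed: int = 0,
                   base: DetectorConfig | None = None) -> NevusDetector:
    return NevusDetector(ablation_variants(base)[variant], seed=seed)
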
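"""Bounding-box geometry and shape-aware regression losses.

Boxes are axis-aligned, centre-form ``(cx, cy, w, h)``, units-agnostic
(pixels or normalised coordinates — the caller keeps them consistent).

The Shape-IoU loss augments the plain IoU objective with

* width/height weights ``ww, hh`` derived from the ground-truth aspect ratio
  raised to a dataset-level ``scale`` exponent (``ww + hh = 2`` identically);
* a centre-distance penalty normalised by the squared diagonal of the
  minimum enclosing axis-aligned rectangle, cross-weighted by ``hh`` on the
  x-offset and ``ww`` on the y-offset;
* a shape-difference term ``Omega = sum_t (1 - exp(-omega_t))**theta`` over
  t in {w, h}, with ``omega_w = hh * |w - w_gt| / max(w, w_gt)`` (and the
  mirrored expression for h), ``theta = 4`` by default.

``L = 1 - IoU + distance_shape + 0.5 * Omega_shape``.

The cross-weighting (height weight on horizontal terms and vice versa) is
deliberate and kept exactly as defined.  All functions accept either plain
numpy arrays or autodiff tensors, so the same code path yields analytic
gradients during detector training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, absolute, clamp, exp, maximum, minimum

__all__ = [
    "BBox",
    "ShapeIoUParams",
    "LossBreakdown",
    "iou",
    "shape_weights",
    "shape_distance",
    "shape_omega",
    "shape_iou_loss",
    "ciou_loss",
    "iou_xywh",
    "shape_iou_terms",
    "ciou_terms",
]

_EPS = 1e-9


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in centre form."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box width/height must be positive, got "
                             f"w={self.w}, h={self.h}")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @property
    def area(self) -> float:
        return self.w * self.h

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "BBox":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    def to_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.w, self.h], dtype=np.float64)


@dataclass(frozen=True)
class ShapeIoUParams:
    """Parameters of the Shape-IoU loss.

    scale
        Dataset-level size factor applied as an exponent to the ground-truth
        width/height when forming the ``ww``/``hh`` weights.  ``0`` makes
        both weights 1 (neutral default).
    theta
        Exponent of the shape-difference term (default 4).
    omega_weight
        Coefficient on the shape-difference term (default 0.5).
    """

    scale: float = 0.0
    theta: float = 4.0
    omega_weight: float = 0.5

    def __post_init__(self):
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.omega_weight < 0:
            raise ValueError("omega_weight must be >= 0")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-pair decomposition of the Shape-IoU loss."""

    iou: float
    ww: float
    hh: float
    distance_shape: float
    omega_shape: float
    total: float


def _unpack(b: BBox | np.ndarray) -> tuple:
    if isinstance(b, BBox):
        return b.cx, b.cy, b.w, b.h
    arr = np.asarray(b, dtype=np.float64)
    return arr[..., 0], arr[..., 1], arr[..., 2], arr[..., 3]


def _check_valid(*boxes):
    for b in boxes:
        _, _, w, h = _unpack(b)
        if np.any(np.asarray(w) <= 0) or np.any(np.asarray(h) <= 0):
            raise ValueError("invalid box: non-positive width or height")


# ---------------------------------------------------------------------------
# generic core (numpy arrays or autodiff tensors)
# ---------------------------------------------------------------------------

def iou_xywh(cx1, cy1, w1, h1, cx2, cy2, w2, h2):
    """Intersection-over-union of centre-form boxes (array/tensor generic)."""
    ix = maximum(minimum(cx1 + w1 * 0.5, cx2 + w2 * 0.5)
                 - maximum(cx1 - w1 * 0.5, cx2 - w2 * 0.5), 0.0)
    iy = maximum(minimum(cy1 + h1 * 0.5, cy2 + h2 * 0.5)
                 - maximum(cy1 - h1 * 0.5, cy2 - h2 * 0.5), 0.0)
    inter = ix * iy
    union = w1 * h1 + w2 * h2 - inter
    return inter / maximum(union, _EPS)


def _enclosing_sq_diag(cx1, cy1, w1, h1, cx2, cy2, w2, h2):
    cw = maximum(cx1 + w1 * 0.5, cx2 + w2 * 0.5) - minimum(cx1 - w1 * 0.5,
                                                           cx2 - w2 * 0.5)
    ch = maximum(cy1 + h1 * 0.5, cy2 + h2 * 0.5) - minimum(cy1 - h1 * 0.5,
                                                           cy2 - h2 * 0.5)
    return cw * cw + ch * ch


def shape_iou_terms(b, gt, scale: float = 0.0, theta: float = 4.0,
                    omega_weight: float = 0.5):
    """Shape-IoU loss terms for centre-form boxes given as (cx, cy, w, h)
    tuples of arrays or tensors.  Returns (iou, ww, hh, dist, omega, total).
    """
    cx, cy, w, h = b
    gx, gy, gw, gh = gt
    iou_v = iou_xywh(cx, cy, w, h, gx, gy, gw, gh)
    # width/height weights from the ground truth only
    if isinstance(gw, Tensor) or isinstance(gh, Tensor):
        wp, hp = gw ** scale, gh ** scale
    else:
        wp, hp = np.power(gw, scale), np.power(gh, scale)
    denom = wp + hp
    ww = 2.0 * wp / denom
    hh = 2.0 * hp / denom
    c2 = maximum(_enclosing_sq_diag(cx, cy, w, h, gx, gy, gw, gh), _EPS)
    dist = hh * (cx - gx) ** 2 / c2 + ww * (cy - gy) ** 2 / c2
    om_w = hh * absolute(w - gw) / maximum(maximum(w, gw), _EPS)
    om_h = ww * absolute(h - gh) / maximum(maximum(h, gh), _EPS)
    omega = (1.0 - exp(-om_w)) ** theta + (1.0 - exp(-om_h)) ** theta
    total = 1.0 - iou_v + dist + omega_weight * omega
    return iou_v, ww, hh, dist, omega, total


def ciou_terms(b, gt):
    """Complete-IoU loss: 1 - IoU + d^2/c^2 + alpha*v (aspect-ratio term)."""
    cx, cy, w, h = b
    gx, gy, gw, gh = gt
    iou_v = iou_xywh(cx, cy, w, h, gx, gy, gw, gh)
    c2 = maximum(_enclosing_sq_diag(cx, cy, w, h, gx, gy, gw, gh), _EPS)
    d2 = (cx - gx) ** 2 + (cy - gy) ** 2
    if isinstance(w, Tensor) or isinstance(h, Tensor):
        import math
        wv = w if isinstance(w, Tensor) else Tensor(np.asarray(w, float))
        hv = h if isinstance(h, Tensor) else Tensor(np.asarray(h, float))
        ratio = wv / hv
        r0 = ratio.data if isinstance(ratio, Tensor) else ratio
        # first-order expansion of arctan around the current value keeps the
        # gradient exact while the value matches arctan exactly
        atan_lin = Tensor(np.arctan(r0) - r0 / (1 + r0 ** 2)) + ratio * (1.0 / (1 + r0 ** 2))
        gt_atan = np.arctan(np.asarray(gw.data if isinstance(gw, Tensor) else gw, float)
                            / np.asarray(gh.data if isinstance(gh, Tensor) else gh, float))
        v = (4.0 / math.pi ** 2) * (Tensor(gt_atan) - atan_lin) ** 2
        alpha = v.data / np.maximum((1.0 - iou_v.data if isinstance(iou_v, Tensor) else 1.0 - iou_v) + v.data, _EPS)
        total = 1.0 - iou_v + d2 / c2 + Tensor(alpha) * v
        return iou_v, d2 / c2, v, total
    v = (4.0 / np.pi ** 2) * (np.arctan(gw / gh) - np.arctan(w / h)) ** 2
    alpha = v / np.maximum((1.0 - iou_v) + v, _EPS)
    total = 1.0 - iou_v + d2 / c2 + alpha * v
    return iou_v, d2 / c2, v, total


# ---------------------------------------------------------------------------
# BBox-level API
# ---------------------------------------------------------------------------

def iou(a: BBox, b: BBox) -> float:
    """IoU = |A ∩ B| / |A ∪ B|, symmetric, in [0, 1]."""
    _check_valid(a, b)
    return float(iou_xywh(*_unpack(a), *_unpack(b)))


def shape_weights(gt: BBox, scale: float = 0.0) -> tuple[float, float]:
    """Width/height weights (ww, hh) from the ground-truth box.

    ww = 2 (w^s) / (w^s + h^s), hh = 2 (h^s) / (w^s + h^s); ww + hh = 2.
    """
    _check_valid(gt)
    if scale < 0:
        raise ValueError("scale must be >= 0")
    wp, hp = gt.w ** scale, gt.h ** scale
    return 2.0 * wp / (wp + hp), 2.0 * hp / (wp + hp)


def shape_distance(b: BBox, gt: BBox, ww: float, hh: float) -> float:
    """Weighted normalised centre-distance penalty.

    hh * dx^2 / c^2 + ww * dy^2 / c^2 where c is the diagonal of the
    minimum enclosing axis-aligned rectangle of the two boxes.  The height
    weight multiplies the horizontal offset (and vice versa) by definition.
    """
    _check_valid(b, gt)
    c2 = float(_enclosing_sq_diag(*_unpack(b), *_unpack(gt)))
    if c2 < _EPS:
        return 0.0
    return hh * (b.cx - gt.cx) ** 2 / c2 + ww * (b.cy - gt.cy) ** 2 / c2


def shape_omega(b: BBox, gt: BBox, ww: float, hh: float,
                theta: float = 4.0) -> float:
    """Exponentially-saturating width/height discrepancy term in [0, 2)."""
    _check_valid(b, gt)
    om_w = hh * abs(b.w - gt.w) / max(max(b.w, gt.w), _EPS)
    om_h = ww * abs(b.h - gt.h) / max(max(b.h, gt.h), _EPS)
    return (1.0 - np.exp(-om_w)) ** theta + (1.0 - np.exp(-om_h)) ** theta


def shape_iou_loss(b: BBox, gt: BBox,
                   params: ShapeIoUParams | None = None) -> LossBreakdown:
    """Full Shape-IoU loss with its term-by-term breakdown."""
    params = params or ShapeIoUParams()
    _check_valid(b, gt)
    iou_v, ww, hh, dist, omega, total = shape_iou_terms(
        _unpack(b), _unpack(gt), params.scale, params.theta,
        params.omega_weight)
    return LossBreakdown(iou=float(iou_v), ww=float(ww), hh=float(hh),
                         distance_shape=float(dist), omega_shape=float(omega),
                         total=float(total))


def ciou_loss(b: BBox, gt: BBox) -> float:
    """Complete-IoU loss (the stock regression baseline)."""
    _check_valid(b, gt)
    _, _, _, total = ciou_terms(_unpack(b), _unpack(gt))
    return float(total)


def shape_iou_loss_batch(b: np.ndarray, gt: np.ndarray,
                         params: ShapeIoUParams | None = None) -> np.ndarray:
    """Vectorised total loss for (N, 4) centre-form arrays."""
    params = params or ShapeIoUParams()
    b = np.asarray(b, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    _check_valid(b, gt)
    *_, total = shape_iou_terms(_unpack(b), _unpack(gt), params.scale,
                                params.theta, params.omega_weight)
    return total
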
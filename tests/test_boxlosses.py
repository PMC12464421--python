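"""Shape-IoU / CIoU geometry: worked examples, algebraic identities,
independent-oracle equivalence, gradients, and regression behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nevusnet._autograd import Tensor, cosine_lr
from nevusnet import boxlosses as bl
from nevusnet.boxlosses import BBox, ShapeIoUParams

from conftest import random_boxes


def oracle_shape_iou(b, gt, scale=0.0, theta=4.0, omega_weight=0.5):
    """Independent single-expression evaluation of the loss on two boxes.

    Written directly from the defining formulas with plain floats; shares no
    code with the implementation under test."""
    import math
    bx, by, bw, bh = b
    gx, gy, gw, gh = gt
    ix = max(min(bx + bw / 2, gx + gw / 2) - max(bx - bw / 2, gx - gw / 2), 0)
    iy = max(min(by + bh / 2, gy + gh / 2) - max(by - bh / 2, gy - gh / 2), 0)
    inter = ix * iy
    iou = inter / (bw * bh + gw * gh - inter)
    ww = 2 * gw ** scale / (gw ** scale + gh ** scale)
    hh = 2 * gh ** scale / (gw ** scale + gh ** scale)
    cw = max(bx + bw / 2, gx + gw / 2) - min(bx - bw / 2, gx - gw / 2)
    ch = max(by + bh / 2, gy + gh / 2) - min(by - bh / 2, gy - gh / 2)
    c2 = cw ** 2 + ch ** 2
    dist = hh * (bx - gx) ** 2 / c2 + ww * (by - gy) ** 2 / c2
    om_w = hh * abs(bw - gw) / max(bw, gw)
    om_h = ww * abs(bh - gh) / max(bh, gh)
    omega = (1 - math.exp(-om_w)) ** theta + (1 - math.exp(-om_h)) ** theta
    return 1 - iou + dist + omega_weight * omega


class TestIoU:
    def test_identity_and_disjoint(self):
        assert bl.iou(BBox(0, 0, 1, 1), BBox(0, 0, 1, 1)) == 1.0
        assert bl.iou(BBox(0, 0, 1, 1), BBox(5, 5, 1, 1)) == 0.0

    def test_half_offset_unit_boxes(self):
        # overlap 0.5, union 1.5
        v = bl.iou(BBox(0.5, 0.5, 1, 1), BBox(1.0, 0.5, 1, 1))
        assert v == pytest.approx(1 / 3, abs=1e-12)

    def test_symmetric(self, rng):
        boxes = random_boxes(rng, 50)
        for a, b in zip(boxes[:25], boxes[25:]):
            assert bl.iou(BBox(*a), BBox(*b)) == pytest.approx(
                bl.iou(BBox(*b), BBox(*a)), abs=1e-14)

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            BBox(0, 0, -1, 1)
        with pytest.raises(ValueError):
            BBox(0, 0, 1, 0)


class TestShapeWeights:
    def test_scale_zero_neutral(self, rng):
        for b in random_boxes(rng, 30):
            ww, hh = bl.shape_weights(BBox(*b), 0.0)
            assert (ww, hh) == (1.0, 1.0)

    def test_square_neutral_any_scale(self):
        for s in (0.0, 0.5, 1.0, 3.0):
            assert bl.shape_weights(BBox(0, 0, 2, 2), s) == (1.0, 1.0)

    def test_wide_box_scale_one(self):
        ww, hh = bl.shape_weights(BBox(0, 0, 2, 1), 1.0)
        assert ww == pytest.approx(4 / 3, abs=1e-12)
        assert hh == pytest.approx(2 / 3, abs=1e-12)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            bl.shape_weights(BBox(0, 0, 1, 1), -0.1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(w=st.floats(0.01, 50), h=st.floats(0.01, 50),
           scale=st.floats(0, 4))
    def test_weights_sum_to_two(self, w, h, scale):
        ww, hh = bl.shape_weights(BBox(0, 0, w, h), scale)
        assert ww + hh == pytest.approx(2.0, abs=1e-12)


class TestShapeDistance:
    def test_concentric_zero(self):
        assert bl.shape_distance(BBox(1, 1, 2, 3), BBox(1, 1, 5, 1),
                                 1.0, 1.0) == 0.0

    def test_worked_enclosing_box(self):
        # enclosing box x in [-1, 2], y in [-1, 1]: c^2 = 9 + 4 = 13
        v = bl.shape_distance(BBox(0, 0, 2, 2), BBox(1, 0, 2, 2), 1.0, 1.0)
        assert v == pytest.approx(1 / 13, abs=1e-12)

    def test_swap_symmetry_with_fixed_weights(self, rng):
        boxes = random_boxes(rng, 20)
        for a, b in zip(boxes[:10], boxes[10:]):
            assert bl.shape_distance(BBox(*a), BBox(*b), 0.7, 1.3) == \
                pytest.approx(bl.shape_distance(BBox(*b), BBox(*a), 0.7, 1.3),
                              abs=1e-12)


class TestShapeOmega:
    def test_identical_sizes_zero(self):
        assert bl.shape_omega(BBox(0, 0, 2, 3), BBox(5, 5, 2, 3),
                              1.0, 1.0) == 0.0

    def test_half_width_value(self):
        v = bl.shape_omega(BBox(0, 0, 1, 1), BBox(0, 0, 2, 1), 1.0, 1.0)
        assert v == pytest.approx((1 - np.exp(-0.5)) ** 4, abs=1e-12)
        assert v == pytest.approx(0.02397, abs=5e-6)

    def test_monotone_in_width_gap(self):
        vals = [bl.shape_omega(BBox(0, 0, 2 + d, 1), BBox(0, 0, 2, 1),
                               1.0, 1.0) for d in (0.1, 0.5, 1.0, 3.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestShapeIoULoss:
    def test_zero_iff_identical(self, rng):
        assert bl.shape_iou_loss(BBox(1, 2, 3, 4), BBox(1, 2, 3, 4)).total \
            == 0.0
        for b in random_boxes(rng, 20):
            gt = b + [0.01, 0, 0, 0]
            assert bl.shape_iou_loss(BBox(*b), BBox(*gt)).total > 0

    def test_worked_example(self):
        lb = bl.shape_iou_loss(BBox(0.5, 0.5, 1, 1), BBox(0.5, 0.5, 2, 1))
        assert lb.iou == pytest.approx(0.5, abs=1e-12)
        assert lb.distance_shape == 0.0
        assert lb.omega_shape == pytest.approx((1 - np.exp(-0.5)) ** 4,
                                               abs=1e-12)
        assert lb.total == pytest.approx(0.5120, abs=5e-5)

    def test_total_bounded(self, rng):
        boxes = random_boxes(rng, 200)
        for a, b in zip(boxes[:100], boxes[100:]):
            t = bl.shape_iou_loss(BBox(*a), BBox(*b)).total
            assert 0.0 <= t <= 4.0

    def test_oracle_equivalence_1000_pairs(self, rng):
        boxes = random_boxes(rng, 2000)
        scales = rng.uniform(0, 2, 1000)
        worst = 0.0
        for a, b, s in zip(boxes[:1000], boxes[1000:], scales):
            got = bl.shape_iou_loss(BBox(*a), BBox(*b),
                                    ShapeIoUParams(scale=float(s))).total
            want = oracle_shape_iou(a, b, scale=float(s))
            worst = max(worst, abs(got - want))
        assert worst < 1e-9

    def test_batch_matches_elementwise(self, rng):
        a = random_boxes(rng, 32)
        b = random_boxes(rng, 32)
        batch = bl.shape_iou_loss_batch(a, b)
        single = [bl.shape_iou_loss(BBox(*x), BBox(*y)).total
                  for x, y in zip(a, b)]
        np.testing.assert_allclose(batch, single, atol=1e-12)

    def test_gradient_matches_central_differences(self, rng):
        for _ in range(20):
            b0 = random_boxes(rng, 1)[0]
            gt = random_boxes(rng, 1)[0]
            if abs(b0[2] - gt[2]) < 1e-3 or abs(b0[3] - gt[3]) < 1e-3:
                continue  # omega kink: gradient not defined there
            p = [Tensor(np.array([v]), requires_grad=True) for v in b0]
            gt_t = tuple(np.array([v]) for v in gt)
            *_, total = bl.shape_iou_terms(tuple(p), gt_t)
            total.sum().backward()
            eps = 1e-6
            for i in range(4):
                bb = b0.copy()
                bb[i] += eps
                *_, t1 = bl.shape_iou_terms(
                    tuple(np.array([v]) for v in bb), gt_t)
                bb[i] -= 2 * eps
                *_, t2 = bl.shape_iou_terms(
                    tuple(np.array([v]) for v in bb), gt_t)
                fd = (t1[0] - t2[0]) / (2 * eps)
                assert p[i].grad[0] == pytest.approx(fd, abs=1e-4)


class TestCIoU:
    def test_identical_zero(self):
        assert bl.ciou_loss(BBox(1, 1, 2, 3), BBox(1, 1, 2, 3)) == 0.0

    def test_concentric_same_aspect_reduces_to_iou(self):
        b, gt = BBox(0, 0, 1, 2), BBox(0, 0, 2, 4)
        assert bl.ciou_loss(b, gt) == pytest.approx(1 - bl.iou(b, gt),
                                                    abs=1e-12)

    def test_term_decomposition_consistent(self, rng):
        boxes = random_boxes(rng, 100)
        for a, b in zip(boxes[:50], boxes[50:]):
            iou_v, dterm, v, total = bl.ciou_terms(
                (a[0], a[1], a[2], a[3]), (b[0], b[1], b[2], b[3]))
            alpha = v / max((1 - iou_v) + v, 1e-9)
            recomposed = 1 - iou_v + dterm + alpha * v
            assert total == pytest.approx(recomposed, abs=1e-10)


class TestRegressionSimulation:
    """Gradient descent on perturbed boxes under the shape-aware loss."""

    @staticmethod
    def _descend(kind, b0, gt, steps, lr0=0.03):
        p = [Tensor(b0[:, i].copy(), requires_grad=True) for i in range(4)]
        gt_t = tuple(gt[:, i] for i in range(4))
        traj = []
        for i in range(steps):
            lr = cosine_lr(i, steps, lr0, 1e-5)
            if kind == "shape":
                *_, total = bl.shape_iou_terms(tuple(p), gt_t)
            else:
                total = 1.0 - bl.iou_xywh(p[0], p[1], p[2], p[3], *gt_t)
            for q in p:
                q.grad = None
            total.sum().backward()
            for q in p:
                q.data -= lr * q.grad
            p[2].data[:] = np.maximum(p[2].data, 1e-3)
            p[3].data[:] = np.maximum(p[3].data, 1e-3)
            traj.append(bl.iou_xywh(p[0].data, p[1].data, p[2].data,
                                    p[3].data, *gt_t).copy())
        return np.asarray(traj)

    def test_reaches_high_iou_and_beats_plain_iou_on_offsets(self):
        rng = np.random.default_rng(3)
        n = 20
        gt = np.stack([np.full(n, 0.5), np.full(n, 0.5),
                       rng.uniform(0.2, 0.5, n), rng.uniform(0.2, 0.5, n)], 1)
        b0 = np.stack([gt[:, 0] + rng.uniform(-0.15, 0.15, n),
                       gt[:, 1] + rng.uniform(-0.15, 0.15, n),
                       gt[:, 2] * rng.uniform(0.6, 1.6, n),
                       gt[:, 3] * rng.uniform(0.6, 1.6, n)], 1)
        traj = self._descend("shape", b0, gt, 1200)
        assert traj[-1].min() >= 0.99
        # centre-offset initialisations: shape-aware convergence is not
        # slower than plain 1-IoU (which has no gradient once disjoint)
        b1 = gt.copy()
        b1[:, 0] += rng.uniform(-0.2, 0.2, n)
        b1[:, 1] += rng.uniform(-0.2, 0.2, n)
        ts = self._descend("shape", b1, gt, 800)
        tp = self._descend("plain", b1, gt, 800)

        def steps_to(tr, tgt):
            return np.array([np.flatnonzero(tr[:, j] >= tgt)[0]
                             if (tr[:, j] >= tgt).any() else 10 ** 6
                             for j in range(tr.shape[1])])

        assert np.median(steps_to(ts, 0.95)) <= np.median(steps_to(tp, 0.95))
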
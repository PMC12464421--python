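"""Detection evaluation: greedy matching, precision/recall, average
precision and the two headline mAP summaries.

Matching follows the standard single-class protocol: detections are visited
in descending score order and each claims the unmatched ground-truth box of
highest IoU, provided that IoU clears the threshold; every other detection
is a false positive and each ground truth can be matched at most once.
Average precision is the area under the all-point-interpolated
precision-recall curve (the convention of the YOLO ecosystem).  Precision
and recall are additionally reported at a fixed confidence threshold
(default 0.5).  "mAP@0.5:0.95" averages AP over IoU 0.50-0.95 in 0.05
steps; the alias "mAP@0.95" used in some reports refers to the same mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxlosses import BBox, iou

__all__ = ["Detection", "MatchResult", "match", "precision_recall",
           "average_precision", "map_range", "evaluate", "RANGE_THRESHOLDS"]

RANGE_THRESHOLDS = np.round(np.arange(0.50, 0.96, 0.05), 2)


@dataclass(frozen=True)
class Detection:
    image_id: int | str
    box: BBox
    score: float
    class_id: int = 0


@dataclass
class MatchResult:
    tp_flags: np.ndarray          # bool per detection, score-descending order
    scores: np.ndarray            # matching order of tp_flags
    matched_gt: dict = field(default_factory=dict)
    n_gt: int = 0

    @property
    def tp(self) -> int:
        return int(self.tp_flags.sum())

    @property
    def fp(self) -> int:
        return int((~self.tp_flags).sum())


def _group(dets: list[Detection]):
    by_img: dict = {}
    for d in dets:
        by_img.setdefault(d.image_id, []).append(d)
    return by_img


def match(dets: list[Detection], gts: dict | list, iou_thresh: float = 0.5
          ) -> MatchResult:
    """Greedy score-order matching.

    gts may be a list of BBox (single image) or {image_id: [BBox, ...]}.
    """
    if isinstance(gts, list):
        ids = {d.image_id for d in dets}
        if len(ids) > 1:
            raise ValueError("list-form gts requires single-image detections")
        gts = {next(iter(ids)) if ids else 0: gts}
    order = np.argsort([-d.score for d in dets], kind="stable")
    tp = np.zeros(len(dets), dtype=bool)
    scores = np.array([dets[i].score for i in order], dtype=np.float64)
    used: dict = {k: np.zeros(len(v), dtype=bool) for k, v in gts.items()}
    matched: dict = {}
    for rank, di in enumerate(order):
        d = dets[di]
        cand = gts.get(d.image_id, [])
        best_iou, best_gi = 0.0, -1
        for gi, g in enumerate(cand):
            if used[d.image_id][gi]:
                continue
            v = iou(d.box, g)
            if v >= iou_thresh and v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi >= 0:
            used[d.image_id][best_gi] = True
            tp[rank] = True
            matched[(d.image_id, best_gi)] = di
    n_gt = sum(len(v) for v in gts.values())
    return MatchResult(tp_flags=tp, scores=scores, matched_gt=matched,
                       n_gt=n_gt)


def precision_recall(result: MatchResult, conf_thresh: float = 0.5
                     ) -> tuple[float, float]:
    """P and R over detections with score >= conf_thresh (0 on empty
    denominators)."""
    keep = result.scores >= conf_thresh
    tp = int(result.tp_flags[keep].sum())
    fp = int(keep.sum()) - tp
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / result.n_gt if result.n_gt else 0.0
    return p, r


def average_precision(dets: list[Detection], gts: dict,
                      iou_thresh: float = 0.5) -> float:
    """AP: area under the all-point-interpolated PR curve, sweeping all
    confidences."""
    n_gt = sum(len(v) for v in gts.values())
    if n_gt == 0:
        raise ValueError("average precision undefined with zero ground truth")
    if not dets:
        return 0.0
    res = match(dets, gts, iou_thresh)
    tp_cum = np.cumsum(res.tp_flags)
    fp_cum = np.cumsum(~res.tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # envelope + step integration over all points
    r = np.concatenate([[0.0], recall, [1.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.flatnonzero(r[1:] != r[:-1])
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def map_range(dets: list[Detection], gts: dict) -> float:
    """Mean AP over IoU thresholds 0.50:0.05:0.95."""
    return float(np.mean([average_precision(dets, gts, t)
                          for t in RANGE_THRESHOLDS]))


def evaluate(dets: list[Detection], gts: dict, conf_thresh: float = 0.5
             ) -> dict:
    """Evaluation report: mAP@0.5, mAP@0.5:0.95 (alias mAP@0.95), P, R."""
    m50 = average_precision(dets, gts, 0.5)
    mrange = map_range(dets, gts)
    p, r = precision_recall(match(dets, gts, 0.5), conf_thresh)
    return {"mAP@0.5": m50, "mAP@0.5:0.95": mrange, "mAP@0.95": mrange,
            "precision": p, "recall": r}
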
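"""Reverse-exclusion screening logic and its safety statistics.

The detector only knows one class — the benign melanocytic nevus.  The
screening decision is therefore inverted: an image is **low-risk** exactly
when at least one nevus detection reaches the confidence threshold
(inclusive, default 0.5); the absence of a confident detection makes the
case **high-risk** ("non-nevus", refer to biopsy).

On a melanoma-only cohort the error of consequence is the false negative —
a melanoma called nevus.  Following the inverted definitions:

* FN: melanoma classified as nevus (malignant labelled benign);
* TP: melanoma correctly classified as non-nevus (high-risk flagged).

``FNR = FN / (TP + FN)``, with the clinical safety ceiling at 0.5%
(inclusive).  Note that some report tables label the correctly excluded
cases "TN"; the formula above needs the TP reading, so this module uses it
and the report prints both labels.

The reader comparison uses the exact McNemar test: a two-sided binomial
test on the discordant pairs (model hit / reader miss vs. model miss /
reader hit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detector import DetectorOutput

__all__ = ["ScreeningDecision", "ScreeningCounts", "ReaderResult",
           "reverse_exclude", "fnr", "safety_check", "mcnemar_exact",
           "screen_cohort", "summary_report", "SAFETY_CEILING"]

SAFETY_CEILING = 0.005


@dataclass(frozen=True)
class ScreeningDecision:
    image_id: int | str
    label: str                      # "low_risk" | "high_risk"
    top_confidence: float | None

    @property
    def is_low_risk(self) -> bool:
        return self.label == "low_risk"


@dataclass(frozen=True)
class ScreeningCounts:
    """Reverse-exclusion confusion counts on a melanoma-only cohort."""

    n_melanoma: int
    fn: int     # melanoma called nevus
    tp: int     # melanoma called non-nevus (correctly excluded; the
                # "TN" row of some report tables)

    def __post_init__(self):
        if self.fn < 0 or self.tp < 0:
            raise ValueError("counts must be non-negative")
        if self.fn + self.tp != self.n_melanoma:
            raise ValueError("fn + tp must equal n_melanoma")


@dataclass(frozen=True)
class ReaderResult:
    method: str
    miss_flags: np.ndarray          # True where the reader missed the case

    @property
    def fn(self) -> int:
        return int(np.sum(self.miss_flags))


def reverse_exclude(dets: DetectorOutput, image_id: int | str = 0,
                    conf_thresh: float = 0.5) -> ScreeningDecision:
    """Low-risk iff any nevus detection has confidence >= conf_thresh."""
    scores = np.asarray(dets.scores, dtype=float)
    confident = scores[scores >= conf_thresh]
    if confident.size:
        return ScreeningDecision(image_id, "low_risk", float(confident.max()))
    top = float(scores.max()) if scores.size else None
    return ScreeningDecision(image_id, "high_risk", top)


def fnr(counts: ScreeningCounts) -> float:
    """FN / (TP + FN) on a non-empty cohort."""
    if counts.n_melanoma == 0:
        raise ValueError("FNR undefined on an empty cohort")
    return counts.fn / (counts.tp + counts.fn)


def fnr_percent(counts: ScreeningCounts) -> float:
    """FNR as a percentage rounded to 2 decimals (report convention)."""
    return round(100.0 * fnr(counts), 2)


def safety_check(fnr_value: float, ceiling: float = SAFETY_CEILING) -> bool:
    """Pass iff fnr <= ceiling (inclusive)."""
    if not 0.0 <= fnr_value <= 1.0:
        raise ValueError("fnr must lie in [0, 1]")
    return fnr_value <= ceiling


def mcnemar_exact(model_miss: np.ndarray, reader_miss: np.ndarray) -> float:
    """Two-sided exact McNemar p-value on paired miss flags.

    Discordant counts: b = model hit & reader miss, c = model miss & reader
    hit; exact binomial test of b successes in b + c trials at p = 1/2.
    b + c = 0 returns 1 by convention.
    """
    model_miss = np.asarray(model_miss, dtype=bool)
    reader_miss = np.asarray(reader_miss, dtype=bool)
    if model_miss.shape != reader_miss.shape:
        raise ValueError("paired flags must have equal length")
    b = int(np.sum(~model_miss & reader_miss))
    c = int(np.sum(model_miss & ~reader_miss))
    if b + c == 0:
        return 1.0
    return float(stats.binomtest(b, b + c, 0.5).pvalue)


def screen_cohort(decisions: list[ScreeningDecision]) -> ScreeningCounts:
    """Aggregate per-image decisions on a melanoma-only cohort into counts.

    A low-risk call on a melanoma is a miss (FN); high-risk is a correct
    exclusion (TP)."""
    fn = sum(d.is_low_risk for d in decisions)
    n = len(decisions)
    return ScreeningCounts(n_melanoma=n, fn=fn, tp=n - fn)


def summary_report(counts: ScreeningCounts,
                   readers: list[ReaderResult] | None = None,
                   model_miss: np.ndarray | None = None,
                   ceiling: float = SAFETY_CEILING) -> dict:
    """JSON-ready summary; prints both the TP and legacy TN labels for the
    correctly excluded cases."""
    value = fnr(counts)
    out = {
        "n_melanoma": counts.n_melanoma,
        "fn": counts.fn,
        "tp_excluded": counts.tp,
        "tn_legacy_label": counts.tp,
        "fnr": value,
        "fnr_percent": fnr_percent(counts),
        "safety_ceiling_percent": 100.0 * ceiling,
        "safety_pass": safety_check(value, ceiling),
    }
    if readers:
        if model_miss is None:
            raise ValueError("reader comparison needs the model miss flags")
        cmp = {}
        for r in readers:
            rc = ScreeningCounts(len(r.miss_flags), r.fn,
                                 len(r.miss_flags) - r.fn)
            cmp[r.method] = {
                "fn": r.fn,
                "fnr_percent": fnr_percent(rc),
                "mcnemar_p": mcnemar_exact(model_miss, r.miss_flags),
            }
        out["readers"] = cmp
    return out
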
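"""End-to-end synthetic screening study at desk scale.

Runs the whole pipeline on generated data: train the tiny detector profile
on benign-only images, evaluate detection quality on held-out benign
images, then screen a malignant-only external cohort through the
reverse-exclusion rule and summarise the false-negative statistics.  The
default problem sizes (a few hundred 64 px images, ~30 epochs) keep a full
run in the minutes range on one CPU core.
"""

from __future__ import annotations

import numpy as np

from . import detector as dt
from . import metrics as me
from . import screening as sc
from . import synthgen as sg

__all__ = ["build_benign_arrays", "eval_map50", "run_desk_study"]


def _make_samples(n: int, lesion_class: str, canvas: int, seed: int,
                  patient_prefix: str) -> list[sg.SyntheticSample]:
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = sg.random_spec(lesion_class, rng, canvas,
                              patient_id=f"{patient_prefix}{i:05d}")
        out.append(sg.make_sample(spec, canvas,
                                  seed=int(rng.integers(0, 2 ** 31 - 1))))
    return out


def build_benign_arrays(samples: list[sg.SyntheticSample]):
    images = np.stack([sg.normalize(s.image).transpose(2, 0, 1)
                       for s in samples])
    gts = [[s.box] for s in samples]
    return images, gts


def eval_map50(model: dt.NevusDetector, images: np.ndarray, gts) -> float:
    dets, gtd = [], {}
    for i in range(len(images)):
        gtd[i] = gts[i]
        out = dt.infer(model, images[i], conf_thresh=0.001)
        dets.extend(me.Detection(i, b, float(s))
                    for b, s in zip(out.boxes, out.scores))
    return me.average_precision(dets, gtd, 0.5)


def run_desk_study(seed: int = 0, n_benign: int = 220, n_malignant: int = 120,
                   canvas: int = 64, epochs: int = 30, batch_size: int = 8,
                   lr0: float = 0.01, holdout: int = 20) -> dict:
    """Train-benign / screen-malignant rehearsal; returns summary stats.

    The benign pool splits into a training set and ``holdout`` held-out
    images (patient-disjoint by construction: one synthetic patient per
    image).  The malignant cohort is only ever screened, never trained on.
    """
    benign = _make_samples(n_benign, "benign", canvas, seed, "b")
    malignant = _make_samples(n_malignant, "malignant", canvas,
                              seed + 1, "m")
    train, val = benign[:-holdout], benign[-holdout:]
    tr_images, tr_gts = build_benign_arrays(train)
    va_images, va_gts = build_benign_arrays(val)
    model = dt.build_detector("full", seed=seed)
    tc = dt.TrainConfig(img_size=canvas, batch_size=batch_size,
                        epochs=epochs, lr0=lr0, val_every=max(epochs, 1),
                        patience=10 * max(epochs, 1))
    dt.fit(model, tr_images, tr_gts, tc, seed=seed)
    map50 = eval_map50(model, va_images, va_gts)
    # reverse-exclusion screening of the malignant-only external cohort
    decisions = []
    for i, s in enumerate(malignant):
        out = dt.infer(model, sg.normalize(s.image).transpose(2, 0, 1),
                       conf_thresh=0.0)
        decisions.append(sc.reverse_exclude(out, image_id=i,
                                            conf_thresh=0.5))
    counts = sc.screen_cohort(decisions)
    # formula-path identity: recompute FNR from the raw counts
    fnr_value = sc.fnr(sc.ScreeningCounts(counts.n_melanoma, counts.fn,
                                          counts.tp))
    return {
        "n_train": len(train),
        "n_holdout": len(val),
        "n_malignant": len(malignant),
        "holdout_map50": map50,
        "counts": counts,
        "fnr": fnr_value,
        "fnr_percent": round(100.0 * fnr_value, 2),
        "safety_pass": sc.safety_check(fnr_value),
    }
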
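"""Synthetic dermoscopic lesion generator.

Produces skin-toned images with a single pigmented lesion whose geometry and
photometry are controlled by clinically-motivated criteria:

* **benign** lesions satisfy all three benign-nevus rules — radial symmetry
  (boundary oscillation below 10% of the mean radius), homogeneous pigment
  (within-mask RGB variance below ~0.10), and a sharp border (edge blended
  over at most ~2 px);
* **malignant** lesions violate at least one criterion.  The violation set
  always contains a *shape* violation (coarse lobulation through low radial
  harmonics, or fine serration through high harmonics) and may add colour
  heterogeneity (contrasting pigment patches) and/or a blurred border, so
  the reverse-exclusion task is learnable by construction.

Boundaries are radial-harmonic curves r(phi) = R (1 + sum_k a_k
cos(k phi + phi_k)) rasterised as polygons.  Optional dark curvilinear hair
strokes emulate occlusion grades 0 (none) / 1 (sparse vellus) / 2 (dense
terminal).  Everything is deterministic given (spec, seed).

The module also carries the dataset plumbing: the printed augmentation
battery, channel-wise ImageNet standardisation, patient-level 9:1 splitting,
YOLO-format label round-tripping and cohort manifests whose phototype and
hair-grade proportions mirror the reference cohort (phototype II 46.36%,
hair occlusion 6.11% at full scale).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, transform
from skimage.color import hsv2rgb, rgb2hsv

from .boxlosses import BBox

__all__ = [
    "LesionSpec", "SyntheticSample", "AugmentConfig",
    "random_spec", "gen_mask", "render", "make_sample", "augment",
    "normalize", "denormalize", "split_by_patient",
    "write_yolo", "read_yolo", "make_cohort", "generate_dataset",
    "generate_cohort_samples", "IMAGENET_MEAN", "IMAGENET_STD",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

# reference cohort composition (counts at the full 2,405-image scale)
PHOTOTYPE_COUNTS = {"II": 1115, "III": 1290}
HAIR_GRADE_COUNTS = {0: 2258, 1: 104, 2: 43}
SITE_COUNTS = {"extremities": 1176, "trunk": 929, "head_face_neck": 300}

FULL_SCALE_BENIGN = 2040
FULL_SCALE_MELANOMA = 365


@dataclass(frozen=True)
class LesionSpec:
    lesion_class: str                        # "benign" | "malignant"
    radius: float                            # px
    cx: float
    cy: float
    harmonics: tuple = ()                    # (k, amplitude, phase) triples
    base_colour: tuple = (0.42, 0.28, 0.20)  # lesion pigment RGB
    het_patches: int = 0                     # colour-heterogeneity blobs
    het_contrast: float = 0.0
    border_softness: float = 1.0             # px
    hair_grade: int = 0
    patient_id: str = "p0"
    violations: tuple = ()

    def __post_init__(self):
        amp = sum(abs(a) for _, a, _ in self.harmonics)
        if amp >= 0.95:
            raise ValueError("harmonic amplitudes would drive r <= 0")
        if self.lesion_class not in ("benign", "malignant"):
            raise ValueError("lesion_class must be benign or malignant")


@dataclass
class SyntheticSample:
    image: np.ndarray        # (H, W, 3) float in [0, 1]
    mask: np.ndarray         # (H, W) bool
    box: BBox                # tight pixel bbox of the mask
    lesion_class: str
    patient_id: str
    seed: int = 0
    spec: LesionSpec | None = None


@dataclass(frozen=True)
class AugmentConfig:
    """The training-time augmentation battery."""

    hflip_p: float = 0.5
    vflip_p: float = 0.3
    scale_range: tuple = (0.5, 1.2)
    hsv_jitter: tuple = (0.20, 0.30, 0.30)   # H +-20%, S +-30%, V +-30%
    noise_sigma: float = 0.1
    occlusion_max_area: float = 0.20
    occlusion_aspect: tuple = (0.5, 2.0)

    def __post_init__(self):
        for p in (self.hflip_p, self.vflip_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# spec factory
# ---------------------------------------------------------------------------

def random_spec(lesion_class: str, rng: np.random.Generator,
                canvas: int = 64, patient_id: str = "p0",
                hair_grade: int = 0) -> LesionSpec:
    """Draw a lesion spec of the requested class at study-default settings."""
    radius = rng.uniform(0.16, 0.28) * canvas
    margin = 0.34 * canvas
    cx = rng.uniform(margin, canvas - margin)
    cy = rng.uniform(margin, canvas - margin)
    base = np.clip(np.array([0.42, 0.28, 0.20])
                   + rng.normal(0, 0.04, 3), 0.05, 0.8)
    if lesion_class == "benign":
        # amplitude budget keeps the boundary oscillation well under 10%
        harm = tuple((int(k), float(rng.uniform(0.005, 0.018)),
                      float(rng.uniform(0, 2 * np.pi)))
                     for k in rng.choice(np.arange(2, 7), 2, replace=False))
        return LesionSpec("benign", radius, cx, cy, harm,
                          tuple(base), 0, 0.0,
                          border_softness=float(rng.uniform(0.6, 1.6)),
                          hair_grade=hair_grade, patient_id=patient_id,
                          violations=())
    # malignant: always one shape violation; colour/border optional extras
    shape_kind = rng.choice(["lobulation", "serration"])
    if shape_kind == "lobulation":
        ks = rng.choice(np.arange(2, 5), 2, replace=False)
        harm = tuple((int(k), float(rng.uniform(0.14, 0.24)),
                      float(rng.uniform(0, 2 * np.pi))) for k in ks)
    else:
        ks = rng.choice(np.arange(8, 16), 3, replace=False)
        harm = tuple((int(k), float(rng.uniform(0.06, 0.11)),
                      float(rng.uniform(0, 2 * np.pi))) for k in ks)
    violations = [shape_kind]
    het_patches, het_contrast = 0, 0.0
    softness = float(rng.uniform(0.6, 1.6))
    if rng.random() < 0.5:
        violations.append("colour")
        het_patches = int(rng.integers(3, 7))
        het_contrast = float(rng.uniform(0.15, 0.30))
    if rng.random() < 0.4:
        violations.append("border")
        softness = float(rng.uniform(5.0, 9.0))
    return LesionSpec("malignant", radius, cx, cy, harm, tuple(base),
                      het_patches, het_contrast, border_softness=softness,
                      hair_grade=hair_grade, patient_id=patient_id,
                      violations=tuple(violations))


# ---------------------------------------------------------------------------
# mask and rendering
# ---------------------------------------------------------------------------

def gen_mask(spec: LesionSpec, canvas: int = 64, n_points: int = 720
             ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise the harmonic boundary; returns (mask, contour (x, y))."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = np.ones_like(phi)
    for k, a, ph in spec.harmonics:
        r += a * np.cos(k * phi + ph)
    if np.any(r <= 0):
        raise ValueError("harmonic amplitudes drive the radius non-positive")
    r *= spec.radius
    xs = spec.cx + r * np.cos(phi)
    ys = spec.cy + r * np.sin(phi)
    rr, cc = draw.polygon(ys, xs, shape=(canvas, canvas))
    mask = np.zeros((canvas, canvas), dtype=bool)
    mask[rr, cc] = True
    contour = np.stack([xs, ys], axis=1)
    return mask, contour


def _tight_box(mask: np.ndarray) -> BBox:
    rr, cc = np.nonzero(mask)
    x1, x2 = cc.min(), cc.max() + 1
    y1, y2 = rr.min(), rr.max() + 1
    return BBox((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


def _hair_strokes(canvas: int, grade: int, rng: np.random.Generator
                  ) -> np.ndarray:
    """Alpha map of curvilinear dark strokes; grade 0 -> empty."""
    alpha = np.zeros((canvas, canvas))
    n_strokes = {0: 0, 1: rng.integers(2, 5), 2: rng.integers(8, 16)}[grade]
    for _ in range(int(n_strokes)):
        p0 = rng.uniform(0, canvas, 2)
        p2 = rng.uniform(0, canvas, 2)
        p1 = (p0 + p2) / 2 + rng.normal(0, canvas / 5, 2)
        t = np.linspace(0, 1, 4 * canvas)[:, None]
        pts = ((1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2)
        ij = np.round(pts).astype(int)
        ok = np.all((ij >= 0) & (ij < canvas), axis=1)
        alpha[ij[ok, 1], ij[ok, 0]] = 1.0
    if grade == 2:
        alpha = ndimage.grey_dilation(alpha, size=(2, 2))
    return np.clip(ndimage.gaussian_filter(alpha, 0.5) * 1.5, 0, 1)


def render(spec: LesionSpec, mask: np.ndarray, seed: int = 0,
           canvas: int | None = None) -> SyntheticSample:
    """Compose background, pigment field, border blend and hair strokes."""
    canvas = canvas or mask.shape[0]
    rng = np.random.default_rng(seed)
    # procedural skin background: base tone + low-frequency drift + speckle
    tone = np.array([0.80, 0.62, 0.55]) + rng.normal(0, 0.02, 3)
    bg = np.empty((canvas, canvas, 3))
    low = ndimage.gaussian_filter(rng.normal(0, 1, (canvas, canvas)),
                                  canvas / 8)
    low = low / (np.abs(low).max() + 1e-9)
    for c in range(3):
        bg[..., c] = tone[c] + 0.025 * low + rng.normal(0, 0.008,
                                                        (canvas, canvas))
    # lesion pigment field
    col = np.array(spec.base_colour)
    pig = np.tile(col, (canvas, canvas, 1))
    pig += rng.normal(0, 0.01, (canvas, canvas, 3))  # mild texture
    if spec.het_patches:
        rr, cc = np.nonzero(mask)
        for _ in range(spec.het_patches):
            i = rng.integers(0, len(rr))
            pr = rng.uniform(0.12, 0.3) * spec.radius
            blob = np.zeros((canvas, canvas))
            dd, c2 = draw.disk((rr[i], cc[i]), pr, shape=(canvas, canvas))
            blob[dd, c2] = 1.0
            blob = ndimage.gaussian_filter(blob, pr / 3)
            shift = spec.het_contrast * rng.choice([-1.0, 1.0]) \
                * rng.uniform(0.7, 1.3)
            pig += blob[..., None] * shift * np.array([1.0, 0.9, 0.8])
    pig = np.clip(pig, 0.0, 1.0)
    alpha = ndimage.gaussian_filter(mask.astype(float),
                                    max(spec.border_softness, 1e-3) / 2.0)
    alpha = np.clip(alpha, 0, 1)[..., None]
    img = bg * (1 - alpha) + pig * alpha
    hair = _hair_strokes(canvas, spec.hair_grade, rng)[..., None]
    hair_col = np.array([0.12, 0.10, 0.09])
    img = img * (1 - 0.85 * hair) + hair_col * 0.85 * hair
    img = np.clip(img, 0.0, 1.0)
    return SyntheticSample(image=img, mask=mask.copy(), box=_tight_box(mask),
                           lesion_class=spec.lesion_class,
                           patient_id=spec.patient_id, seed=seed, spec=spec)


def make_sample(spec: LesionSpec, canvas: int = 64, seed: int = 0
                ) -> SyntheticSample:
    mask, _ = gen_mask(spec, canvas)
    return render(spec, mask, seed=seed, canvas=canvas)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(sample: SyntheticSample, cfg: AugmentConfig | None = None,
            seed: int = 0) -> SyntheticSample:
    """Apply the augmentation battery; the box and mask track geometry."""
    cfg = cfg or AugmentConfig()
    rng = np.random.default_rng(seed)
    img = sample.image.copy()
    mask = sample.mask.copy()
    h, w = mask.shape
    cx, cy, bw, bh = (sample.box.cx, sample.box.cy,
                      sample.box.w, sample.box.h)
    if rng.random() < cfg.hflip_p:
        img = img[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
        cx = w - cx
    if rng.random() < cfg.vflip_p:
        img = img[::-1].copy()
        mask = mask[::-1].copy()
        cy = h - cy
    s = rng.uniform(*cfg.scale_range)
    if abs(s - 1.0) > 1e-9:
        # inverse map (output -> input): in = out/s + c (1 - 1/s), a zoom
        # by s about the canvas centre
        mat = transform.AffineTransform(
            scale=(1 / s, 1 / s),
            translation=(w / 2 * (1 - 1 / s), h / 2 * (1 - 1 / s)))
        img = transform.warp(img, mat, order=1, mode="edge",
                             preserve_range=True)
        mask = transform.warp(mask.astype(float), mat, order=0,
                              mode="constant", preserve_range=True) > 0.5
        cx = w / 2 + (cx - w / 2) * s
        cy = h / 2 + (cy - h / 2) * s
        bw *= s
        bh *= s
    # HSV jitter
    jh, js, jv = cfg.hsv_jitter
    hsv = rgb2hsv(np.clip(img, 0, 1))
    hsv[..., 0] = np.mod(hsv[..., 0] * (1 + rng.uniform(-jh, jh)), 1.0)
    hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-js, js)), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1 + rng.uniform(-jv, jv)), 0, 1)
    img = hsv2rgb(hsv)
    img = img + rng.normal(0, cfg.noise_sigma, img.shape)
    # rectangular occlusion
    area = rng.uniform(0.0, cfg.occlusion_max_area) * h * w
    ar = rng.uniform(*cfg.occlusion_aspect)
    oh = int(np.sqrt(area / ar))
    ow = int(np.sqrt(area * ar))
    if oh >= 1 and ow >= 1:
        oy = rng.integers(0, max(h - oh, 1))
        ox = rng.integers(0, max(w - ow, 1))
        img[oy:oy + oh, ox:ox + ow] = rng.uniform(0.05, 0.2)
    img = np.clip(img, 0.0, 1.0)
    # clip box to canvas
    x1 = max(cx - bw / 2, 0.0)
    y1 = max(cy - bh / 2, 0.0)
    x2 = min(cx + bw / 2, float(w))
    y2 = min(cy + bh / 2, float(h))
    box = BBox.from_corners(x1, y1, x2, y2) if x2 > x1 and y2 > y1 \
        else sample.box
    return SyntheticSample(image=img, mask=mask, box=box,
                           lesion_class=sample.lesion_class,
                           patient_id=sample.patient_id, seed=seed,
                           spec=sample.spec)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize(image: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] then channel-wise standardise with the ImageNet
    constants (mean 0.485/0.456/0.406, std 0.229/0.224/0.225)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if img.max() > 1.5:
        img = img / 255.0
    return (img - IMAGENET_MEAN) / IMAGENET_STD


def denormalize(image: np.ndarray) -> np.ndarray:
    return np.asarray(image) * IMAGENET_STD + IMAGENET_MEAN


# ---------------------------------------------------------------------------
# splitting and labels
# ---------------------------------------------------------------------------

def split_by_patient(samples: list, ratio: float = 0.9, seed: int = 0
                     ) -> tuple[list, list]:
    """Partition patients (never images) into train/val, image counts as
    close to the ratio as patient granularity allows."""
    patients: dict[str, list] = {}
    for s in samples:
        patients.setdefault(s.patient_id, []).append(s)
    if len(patients) < 2:
        raise ValueError("patient-level split needs at least 2 patients")
    rng = np.random.default_rng(seed)
    order = list(patients)
    rng.shuffle(order)
    target = round(len(samples) * ratio)
    train, val = [], []
    count = 0
    for pid in order:
        group = patients[pid]
        if count < target and count + len(group) <= max(target,
                                                        len(samples) - 1):
            train.extend(group)
            count += len(group)
        else:
            val.extend(group)
    if not val:                      # granularity forced everything to train
        last = train[-len(patients[order[-1]]):]
        del train[-len(last):]
        val.extend(last)
    return train, val


def write_yolo(samples: list, out_dir: str) -> list[str]:
    """One "class cx cy w h" text label per image, coordinates normalised
    to [0, 1]."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, s in enumerate(samples):
        h, w = s.mask.shape
        b = s.box
        vals = (b.cx / w, b.cy / h, b.w / w, b.h / h)
        x1, y1, x2, y2 = b.corners
        if not (0.0 <= x1 and x2 <= w + 1e-6 and 0.0 <= y1
                and y2 <= h + 1e-6):
            raise ValueError(f"box out of bounds for sample {i}")
        p = os.path.join(out_dir, f"{i:06d}.txt")
        with open(p, "w") as fh:
            fh.write("0 " + " ".join(f"{v:.6f}" for v in vals) + "\n")
        paths.append(p)
    return paths


def read_yolo(path: str, img_w: int, img_h: int) -> list[tuple[int, BBox]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 fields")
            try:
                cls = int(parts[0])
                cx, cy, w, h = (float(v) for v in parts[1:])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: unparseable value") from e
            out.append((cls, BBox(cx * img_w, cy * img_h, w * img_w,
                                  h * img_h)))
    return out


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

def _allocate(n: int, counts: dict) -> list:
    """Largest-remainder allocation of n items to the reference counts."""
    total = sum(counts.values())
    raw = {k: n * v / total for k, v in counts.items()}
    base = {k: int(np.floor(r)) for k, r in raw.items()}
    left = n - sum(base.values())
    order = sorted(counts, key=lambda k: raw[k] - base[k], reverse=True)
    for k in order[:left]:
        base[k] += 1
    out = []
    for k, c in base.items():
        out.extend([k] * c)
    return out


def make_cohort(n_benign: int = FULL_SCALE_BENIGN,
                n_melanoma: int = FULL_SCALE_MELANOMA,
                seed: int = 0) -> pd.DataFrame:
    """Manifest of a benign-only training cohort plus a melanoma-only
    external test cohort, with phototype / hair-grade / site tags drawn to
    the reference proportions (exact counts at the full 2,405 scale)."""
    n = n_benign + n_melanoma
    rng = np.random.default_rng(seed)
    photo = _allocate(n, PHOTOTYPE_COUNTS)
    hair = _allocate(n, HAIR_GRADE_COUNTS)
    site = _allocate(n, SITE_COUNTS)
    rng.shuffle(photo)
    rng.shuffle(hair)
    rng.shuffle(site)
    rows = []
    for i in range(n):
        cls = "benign" if i < n_benign else "malignant"
        cohort = "train" if cls == "benign" else "external_test"
        rows.append({
            "sample_id": f"s{i:06d}",
            "patient_id": f"pt{i:06d}",
            "lesion_class": cls,
            "cohort": cohort,
            "phototype": photo[i],
            "hair_grade": hair[i],
            "site": site[i],
            "seed": int(rng.integers(0, 2 ** 31 - 1)),
        })
    return pd.DataFrame(rows)


def generate_cohort_samples(manifest: pd.DataFrame, canvas: int = 64,
                            limit: int | None = None) -> list[SyntheticSample]:
    """Materialise image samples for (a slice of) a manifest."""
    out = []
    rows = manifest if limit is None else manifest.head(limit)
    for _, row in rows.iterrows():
        rng = np.random.default_rng(int(row["seed"]))
        spec = random_spec(row["lesion_class"], rng, canvas,
                           patient_id=row["patient_id"],
                           hair_grade=int(row["hair_grade"]))
        out.append(make_sample(spec, canvas, seed=int(row["seed"])))
    return out


def generate_dataset(out_dir: str, n_benign: int, n_melanoma: int,
                     canvas: int = 64, seed: int = 0,
                     ratio: float = 0.9) -> dict:
    """Write images/, labels/, masks/ and manifest.csv for a full synthetic
    study: benign train/val split plus melanoma external test set."""
    from PIL import Image
    manifest = make_cohort(n_benign, n_melanoma, seed=seed)
    samples = generate_cohort_samples(manifest, canvas)
    benign = [s for s in samples if s.lesion_class == "benign"]
    melanoma = [s for s in samples if s.lesion_class == "malignant"]
    train, val = split_by_patient(benign, ratio=ratio, seed=seed) \
        if len(benign) >= 2 else (benign, [])
    splits = {"train": train, "val": val, "external_test": melanoma}
    for name, group in splits.items():
        img_dir = os.path.join(out_dir, name, "images")
        msk_dir = os.path.join(out_dir, name, "masks")
        os.makedirs(img_dir, exist_ok=True)
        os.makedirs(msk_dir, exist_ok=True)
        write_yolo(group, os.path.join(out_dir, name, "labels"))
        for i, s in enumerate(group):
            Image.fromarray((s.image * 255).astype(np.uint8)).save(
                os.path.join(img_dir, f"{i:06d}.png"))
            Image.fromarray((s.mask * 255).astype(np.uint8)).save(
                os.path.join(msk_dir, f"{i:06d}.png"))
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return {name: len(group) for name, group in splits.items()}
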
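# Methods

This note records the models, numerical choices and limitations behind the
package, in the order a reader meets them: box losses, attention, detector,
metrics, screening statistics, morphometrics, and the synthetic data
generator that ties them together.

## Shape-IoU box regression

Boxes are axis-aligned and centre-form `(cx, cy, w, h)`, units-agnostic.
The loss combines three terms: `1 − IoU`, a normalised centre-distance
penalty, and an exponentially saturating width/height discrepancy:

* The size weights `w_w, h_h` are formed from the **ground-truth** box
  only, raised to a dataset-level exponent `scale ≥ 0`; their sum is 2 by
  construction.  `scale` is a per-dataset constant describing how strongly
  target size should modulate the penalty; the package defaults to
  `scale = 0` (neutral weights, `w_w = h_h = 1`) because nothing else is
  forced by the definition, and exposes it in `ShapeIoUParams`.
* The distance term divides by `c²`, the squared diagonal of the minimum
  *axis-aligned* enclosing rectangle of the two boxes (all boxes here are
  axis-aligned, so this is the natural reading of a convex-hull diagonal).
  The cross-weighting — the *height* weight on the x-offset and the
  *width* weight on the y-offset, and likewise inside `ω_w`/`ω_h` — is
  part of the loss definition and is implemented exactly as defined, even
  though it reads as transposed.
* `θ = 4` and the 0.5 coefficient on `Ω` are the stated defaults.

Numerics: `max(w, w_gt)` and `c²` are floored at 1e−9; the loss is exactly
0 iff the boxes coincide and is bounded by 4 with the default weight.  The
`|w − w_gt|` term has a kink at equality, so gradient checks and
gradient-descent simulations avoid (respectively: skip, decay the step
through) that point; constant-step descent otherwise enters a small limit
cycle around the optimum.  CIoU is provided as the comparison baseline;
its aspect term uses the conventional detached `α = v / (1 − IoU + v)`
and, on the autodiff path, a first-order expansion of `arctan` around the
current aspect ratio (exact value, exact local gradient).

## The autodiff engine

No deep-learning framework is part of the runtime: the package ships a
small reverse-mode engine (`nevusnet._autograd`) over float64 numpy
arrays — broadcast-aware arithmetic, conv2d (grouped, via one einsum per
kernel offset), batch norm, max-pool, nearest upsampling, and SGD with
momentum, decoupled weight decay and cosine learning-rate decay.  It is
sized for the tiny detector profile; gradient correctness is covered by
finite-difference tests on every op family.

## Multidimensional collaborative attention

Each of the three branches (channel, height, width) squeezes the feature
map with average and standard-deviation pooling fused by a learnable
convex pair — parameterised through a softmax so convexity is structural.
Max pooling is computed as context but joins the fusion only behind
`use_max_pool` (the fusion is defined over avg/std; the third statistic is
optional).  Excitation is a shared 1-D convolution of odd width `k` over
the pooled descriptor followed by a sigmoid; `k` defaults to the nearest
odd integer to `log2(C)/2 + 1/2` with floor 3 — the standard adaptive rule
for 1-D channel excitation — and "grouped" is realised as a single shared
kernel (group count 1), since no group count is prescribed.  Branch
weights are not shared; the height and width kernels start from identical
values (the branches are mirror images) and decouple during training.
The three sigmoid maps are broadcast, averaged and multiplied into the
input, so attention stays in (0, 1) and output shape equals input shape.

## Detector assembly

* **Backbone** (PP-LCNet flavour): 3×3/2 stem; four depthwise-separable
  groups at 1/4 and 1/8 resolution to preserve small-lesion texture; 5×5
  separable blocks with SE at 1/32; SPPF (three serial 5×5 max-pools,
  concatenated) and an SE-style global recalibration in the "PSA" slot.
  A global-average-pool + 1×1 projection head exists for classification
  pre-training but detection trains from random init.  The ablation
  baseline backbone uses dense convolutions with cross-stage split-merge
  (C2f) blocks at the same taps and channel plan.
* **Neck**: top-down upsample + concat with C2f fusion (P5→P4′→P3′),
  bottom-up separable stride-2 reduction (SCDown), MCA before each of the
  three output nodes.  C2f and SCDown follow their common definitions
  (split-merge bottleneck; depthwise 3×3/2 + pointwise 1×1).
* **Head**: decoupled cls/reg branches per scale, duplicated for the
  one-to-many (training) and one-to-one (training + inference) paths.
  Regression decodes a 16-bin discrete distribution per box side in
  stride units.  Head biases start at −4 (objectness) and with a
  monotonically decreasing bin profile so early decoded boxes are compact.
* **Assignment**: task-aligned metric `score^α · IoU^β` with α = 1, β = 6,
  a centre-inside-gt prior, top-k = 10 for one-to-many and top-1 for
  one-to-one; ties break to the lowest anchor index, and anchors claimed
  by several gts go to the highest-IoU gt.  These exponents/k are the
  conventional values; the assigners are named but not parameterised in
  their definitions.
* **Losses**: BCE on objectness (normalised by positive count), Shape-IoU
  (or CIoU under the ablation toggle) on decoded positives, and
  distribution focal loss to the two bins bracketing each target
  distance; gains 7.5 / 0.5 / 1.5.
* **Inference**: one-to-one branch only, confidence threshold 0.5
  (inclusive), scores sorted descending, **no NMS**.

Training defaults mirror the full-scale protocol (640 px, batch 64, 100
epochs, SGD momentum 0.9 / weight decay 5e−4, cosine 0.01 → 1e−5,
validation every 5 epochs, early stop after 15 stagnant epochs, best-mAP
checkpoint kept).  The package's default width profile is *tiny*
(~190 k parameters) and is trained at 64–128 px: all experiments here run
on one CPU core, and the synthetic lesions are fully resolved at that
scale.  The five ablation variants (baseline, each module alone, full)
differ by exactly one toggle each.

## Detection metrics

Greedy score-order matching with single-use ground truths at IoU ≥ 0.5;
precision and recall are reported at the fixed 0.5 confidence threshold,
while AP sweeps all confidences and integrates the all-point-interpolated
precision–recall envelope (the YOLO-ecosystem convention; the alternative
11/101-point interpolations differ only in the third decimal on these
problem sizes).  `mAP@0.5:0.95` averages AP over IoU 0.50–0.95 in 0.05
steps and is also exposed under the legacy alias `mAP@0.95`, which some
reports use for the same mean.

## Screening statistics

`reverse_exclude` is deliberately inclusive at the threshold (a detection
at exactly 0.5 ⇒ low-risk), matching the convention under which a
boundary-confidence miss is counted as a miss.  The confusion vocabulary
is inverted on a melanoma-only cohort: FN = melanoma called nevus, TP =
melanoma correctly excluded.  Some summary tables label the correctly
excluded cases "TN"; the FNR formula requires the TP reading, so the code
uses it and reports both labels.  The reader comparison is the exact
McNemar test — a two-sided binomial test of the discordant pairs at
p = 1/2, via `scipy.stats.binomtest`, with p = 1 when there are no
discordant pairs.

## Morphometrics

All analyses take the largest connected component; holes are filled for
the skeleton and centroid, and the boundary is the outer contour
(sub-pixel marching-squares trace).

* **Zhang–Suen thinning** is implemented directly (vectorised two-subcycle
  iteration to fixpoint) and cross-checked against scikit-image's
  implementation in tests.  Branch nodes are counted as 8-connected
  components of the ≥ 3-neighbour skeleton pixels — a junction several
  pixels wide is one node — and terminals as 1-neighbour pixels.
* **Scale-resolved fractal dimension**: windows of side
  {16, 32, 64, 128, 256} px slide along the boundary (up to 64 windows per
  scale); inside each, boundary pixels are box-counted over dyadic
  sub-box sizes down to 2 px and the regression slope of log N vs
  log(1/ε) is averaged, clipped to [1, 2].  Windows larger than the image
  are skipped.  Pixelisation biases smooth curves slightly above 1
  (a rasterised circle reads ≈ 1.05–1.1); the triadic-Koch check in the
  tests carries a ±0.1 band for the same reason.
* **Elliptic Fourier descriptors** use the Kuhl–Giardina coefficient
  formulas under arc-length parameterisation, magnitudes
  `√(a²+b²+c²+d²)` normalised to harmonic 1 (making the spectrum
  dimensionless and start-point/rotation invariant).  Two mathematical
  facts worth noting: under arc-length parameterisation an *eccentric*
  ellipse is not exactly single-harmonic (a 3:1 ellipse leaks ≈ 10 % into
  harmonic 3), and a k-lobed rose `r = 1 + a·cos(kφ)` concentrates its
  energy in harmonics k−1 and k+1 (the sidebands of the base rotation),
  not k.  The tests assert these true behaviours.
* **Radial profile**: radii are measured from the mask-moment centroid;
  each angular bin keeps the maximum radius (star-shaped reduction —
  multi-crossing rays are rare for these lesions and are logged when
  > 5 % of bins are affected by construction of the generator they are
  not); empty bins are interpolated circularly.  The deviation fraction
  `frac_over(t)` is computed over contour *points* (for near-uniform
  angular sampling this equals the angular measure).

## Synthetic data generator

Boundaries are radial-harmonic curves `r(φ) = R(1 + Σ a_k cos(kφ + φ_k))`
rasterised as polygons; rendering composes a procedural skin background
(low-frequency tone drift + speckle), a pigment field, a Gaussian border
blend of width `border_softness`, and optional dark quadratic-Bézier hair
strokes (grades 0/1/2).  Everything is deterministic given (spec, seed).

Class definitions follow the three benign criteria, with amplitudes
calibrated against the literature anchors for benign nevi (boundary
symmetry, within-lesion RGB variance < 0.10, sharp edge gradients):

* **benign** — two low harmonics with amplitudes ≤ 0.018 (total boundary
  oscillation well under 10 % of the mean radius, `frac_over(0.10) = 0`),
  homogeneous pigment, border blended over ≲ 2 px;
* **malignant** — always at least one *shape* violation (lobulation:
  harmonics 2–4 at 0.14–0.24, or serration: harmonics 8–15 at 0.06–0.11),
  optionally plus colour heterogeneity (3–6 contrasting patches at
  0.15–0.30 contrast, p = 0.5) and/or a blurred border (5–9 px, p = 0.4).
  The guaranteed shape violation makes the generator–analyser closure
  hold: benign fixtures pass and malignant fixtures fail the
  `frac_over(0.10) ≤ 0.15` rule with ≥ 95 % agreement, and the
  reverse-exclusion task is learnable by construction.

The augmentation battery is fixed: horizontal flip p = 0.5, vertical flip
p = 0.3, scaling 0.5–1.2× about the canvas centre, HSV jitter
H ± 20 % / S ± 30 % / V ± 30 %, Gaussian noise σ = 0.1, and one random
rectangle (area ≤ 20 %, aspect 0.5–2).  Geometric operators transform the
mask and box consistently.  Normalisation scales to [0, 1] and
standardises with the ImageNet constants (0.485, 0.456, 0.406) /
(0.229, 0.224, 0.225).  The patient-level splitter partitions patients,
never images, filling the training side to the rounded 9:1 target (2,040
single-image patients → 1,836 / 204).  Cohort manifests allocate
phototype (II/III), hair grade (0/1/2) and site tags by largest-remainder
rounding of the reference counts, so the full 2,405-row manifest
reproduces them exactly (phototype II 46.36 %, total hair occlusion
6.11 %).

## The desk-scale study, and what it shows

`study.run_desk_study` trains the tiny full-model profile on 200 synthetic
benign images (64 px, 30 epochs, batch 8, cosine 0.01 → 1e−5), evaluates
mAP@0.5 on 20 held-out benign images, then screens a 120-image synthetic
malignant cohort through the reverse-exclusion rule.  These sizes were
chosen so a complete run finishes in minutes on one CPU core while
clearing the ≥ 200-benign / ≥ 100-malignant floors of the end-to-end
rehearsal.

What passing shows: the whole chain — generator → training with Shape-IoU
under dual assignment → NMS-free inference → matching/AP → decision rule →
FNR formula — is wired correctly, the detector localises benign lesions it
has never seen (held-out mAP@0.5 ≥ 0.90), and the screening counts are
exactly reproduced by the formula path.

What it does not show: a clinically meaningful false-negative rate.  The
synthetic malignant lesions share the benign pigment model and differ
mainly in geometry, and a ~190 k-parameter model trained on 200 images has
no pressure toward the strict benign-criteria discrimination that drives
the reference study's 0.27 % FNR; the desk-scale synthetic FNR is
accordingly high and is reported as a pipeline statistic, not a clinical
result.  More broadly, the generator emulates controllable criteria —
symmetry, pigment homogeneity, border sharpness, hair occlusion — but not
dermoscopic optics, pigment-network texture, or the hard boundary cases of
real early melanoma, so passing tests certify the algorithms, not
real-data performance.

## Known limitations

* Degenerate inputs: boxes must have positive sides; masks must be
  non-empty; contours need ≥ 3 points; an empty melanoma cohort makes the
  FNR undefined (error, by design).
* The Shape-IoU kink at `w = w_gt` makes the loss non-differentiable on a
  measure-zero set; training is unaffected, but gradient checks sample
  away from it.
* The local fractal dimension is a windowed box-count estimate; its
  absolute level is grid-biased upward for smooth shapes (documented
  above), so spectra should be compared within, not across, pixel grids.
* The CLI trains only the tiny profile at synthetic-image scales; the
  640 px profile exists in the config but full-scale training is outside
  the intended use of the numpy engine.
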
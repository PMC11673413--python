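# Methods

## Problem setting

Breast MRI screening produces axial slices (both breasts) and sagittal
slices (one breast).  Benign masses are typically smooth, round or
lobulated with clear margins; malignant masses show irregular, spiculated
("burr"-edged) enhancement.  A detector that classifies from a loose
candidate box dilutes exactly the boundary evidence that separates the two
classes, so this package implements a two-stage architecture whose second
stage re-extracts features from a *refined* box before the final call, and
combines the two imaging planes for a lesion-level verdict and a 3D
quadrant location.

## Pipeline and parameters

### Preprocessing

* Background level = mean of the top-left N×M pixel block, N = M = 4 by
  default.  The block is taken from the corner unconditionally; callers
  with anatomy in that corner should crop first.
* Subtraction clamps at zero.  Intensities are physical magnitudes; the
  clamp also keeps the Otsu-based mask provider stable.
* Breast masking applies any caller-supplied binary mask; the baseline
  provider is Otsu threshold → morphological closing (disk radius 3,
  which bridges the narrow gap between the two breasts of an axial
  slice) → largest connected component → hole filling.  A raw-threshold
  coherence check (largest component ≥ 5% of the image) returns an empty
  mask, with a warning, on pure-noise input.
* Rescaling multiplies both dimensions by `target / min(h, w)`
  (target 512 by default), rounds half-away-from-zero, and uses bilinear
  interpolation for images, nearest-neighbour for masks.  The order is
  fixed as subtraction → masking → rescaling.

### Detection stage

* Boxes are continuous, 0-based, half-open `[x_min, x_max)`; VOC XML
  stores 1-based inclusive integers (convert: min−1 on read, min+1 on
  write).  Half-open boxes make widths and IoU arithmetic exact, and the
  delta decoder is written in an offset form whose zero-delta output is
  bit-identical to the anchor.
* Class indices are fixed: 0 background, 1 benign, 2 malignant.  Argmax
  ties break toward the lower index (conservative).
* Anchors: ratios 1:2 / 1:1 / 2:1; area scale²; centers at
  `(cell + 0.5) · stride`.  Single-level mode: scales {128, 256, 512}
  (9 shapes/location).  Pyramid mode: base scales {32, 64, 128, 256, 512}
  for P2–P6, each expanded to the two geometric neighbours
  {s/√2, s·√2} (6 shapes/location) so coverage stays continuous across
  levels.
* RPN: shared 3×3 trunk + 1×1 objectness/regression heads.  Proposals:
  decode, clip, drop sides < 2 px, NMS at 0.7, keep the top 300 by
  objectness, pad by repeating the last proposal so the head shapes stay
  fixed at [300, ·].  The pairwise-IoU guarantee applies to the valid
  (pre-padding) prefix.
* ROI align: the box is split into 7×7 bins; each bin averages a regular
  2×2 grid of bilinear samples; feature pixel (r, c) is a point sample at
  (c+0.5, r+0.5); nothing is ever rounded.  Samples are clamped at map
  borders.
* Pyramid level for detection pooling:
  `clamp(floor(4 + log2(sqrt(wh)/160)), 2, 5)` — the standard assignment
  with the canonical ROI size reduced from 224 to 160, matching the
  shorter-side-512 breast field of view.
* Detection head: two parallel fully connected layers on the flattened
  pooled features — one for the `4K` class-conditional deltas, one for
  the `K` softmax scores.

### PDN stage

* Refinement uses the deltas of each candidate's argmax class; background
  candidates keep their proposal box.  Refined boxes below 2 px per side
  are re-centered to a 2 px minimum so re-pooling stays well-posed.
* Size bins for re-pooling: `sqrt(wh)` < 64 → P2, 64–128 (both ends
  inclusive, so the bins partition all sizes) → P3, > 128 → P4.  With the
  pyramid disabled all candidates pool from the single stride-16 map.
* Three extra 3×3 channel-preserving conv layers (ReLU), weights
  independent of the detection head, then a single fully connected
  classifier.  Retention rule: argmax class is a lesion class *and* its
  score strictly exceeds the threshold (0.5 default; "exceeds" is read as
  strict).  Benign detections use the same threshold symmetrically so
  per-class precision/recall are well-defined.  Class-wise NMS (0.3)
  deduplicates retained detections.
* Gradient policy: refined box coordinates are constants (no gradient
  through the argmax/regression path), but gradients do flow through ROI
  align into the pyramid features — the backbone learns from all five
  loss terms.

### Loss and training

* `total = rpn_cls + rpn_loc + roi_cls + roi_loc + pdn_cls`, exactly
  additive by construction.  Classification terms operate in probability
  space (cross-entropy of softmax/sigmoid outputs), so a perfect
  prediction has exactly zero loss; location terms are smooth-L1 (β = 1)
  on encoded deltas of positive samples, normalized by the sampled count.
  The second-stage location term is smooth-L1, the standard choice for
  continuous offsets.
* Matching: positives at IoU ≥ 0.5 (plus each ground truth's best
  anchor), RPN negatives below 0.3.  Per image, 128 anchors and 128 ROIs
  are sampled with a 1:1 positive cap; ground-truth boxes are appended to
  the proposal pool at train time.  PDN targets are re-assigned on the
  *refined* boxes at IoU ≥ 0.5.
* Optimizer: batch-1 SGD, momentum 0.9, weight decay 5e-4, global
  gradient-norm clip 10.  Full-scale defaults: lr 1e-5, 30 epochs
  (appropriate for a pretrained VGG-16 backbone).  Desk-scale preset:
  lr 0.01, 15 epochs for the randomly initialized tiny backbone.  The
  best-on-validation (lowest mean total loss) checkpoint is kept.
* Every random choice (shuffling, sampling, initialization) draws from
  one generator seeded by the run configuration, so a seed fixes the loss
  history bit-for-bit.

### Evaluation and 3D localization

* AP at IoU 0.5 uses greedy score-ordered matching and the all-points
  precision envelope (not 11-point interpolation); mAP averages the two
  lesion classes, excluding (with a warning) a class absent from the
  ground truth.
* AUC is the normalized Mann–Whitney statistic with ties counted ½.
* Lesion-level tally: a malignant ground-truth lesion is TP if any slice
  in either plane has a retained malignant detection at IoU ≥ 0.5; benign
  lesions hit by such a detection count FP, otherwise TN; stray malignant
  detections overlapping nothing count one FP per disjoint overlap
  cluster per image (so touching duplicates are not double-billed).
* Quadrants: up ⇔ anatomical `y_sag > Y_mid`; outside ⇔ `x_ax < x_Rmid`
  or `x_ax > x_Lmid`.  Boundary convention: ties on the horizontal
  midline go *down*, ties on a breast midline go *inside*, making the
  four indicators a partition of the plane.  Anatomical y increases
  superiorly; the geometry record carries the row-sign flip
  (`y_orientation`), since "up" is anatomical rather than image-row
  direction.
* Laterality is the literal printed rule — left iff `x_ax < x_mid`, the
  midline itself counting right — with a `flip` flag for mirrored
  acquisitions, because the rule conflicts with the radiological
  image-left/patient-right convention and real data may need the flip.
* A lesion detected in neither plane is reported *undetected*, never
  benign.

## Synthetic phantom

The generator emulates the data properties the pipeline depends on, per
dual-plane case:

* dark background with a constant additive offset (20) plus Gaussian
  noise (sd 4) — so the 4×4-corner background estimate is exercised;
* a bright breast foreground (intensity 90): two half-ellipses attached
  to a chest-wall baseline in the axial view, one half-ellipse in the
  sagittal view;
* one lesion (configurable range) rendered in both planes with the same
  identity and label, radius resampled ±20% across planes: benign =
  rotated ellipse (axis ratio 0.85–1.15, radius 5–9 px), malignant =
  spiculated star `r(θ) = r₀(1 + a·sin(kθ + φ))` with amplitude 0.5 and
  9 lobes (radius 6–9 px), both at intensity 200 with a light edge blur;
* exact ground truth: tight bounding boxes, per-case breast geometry
  (midlines, baseline, row orientation), quadrant and laterality labels
  consistent with the localization equations by construction (placement
  keeps centers ≥ 4 px from every decision line).

Placement is rejection-sampled (100 attempts, re-drawing the quadrant per
attempt) inside margin-shrunken breast ellipses; an unplaceable lesion
raises a generation error naming the case.  Each case has its own RNG
keyed by `seed XOR case_index`, so generation order and parallelism do
not affect the output.

What the phantom does **not** model: MR physics and coil inhomogeneity,
background parenchymal enhancement, texture inside lesions, multi-slice
3D continuity, inter-plane registration error, and class-dependent
intensity differences — shape (spiculation) is deliberately the *only*
benign/malignant cue, which is what makes passing the end-to-end test
meaningful: the classifier must learn boundary shape.  Conversely,
passing on phantoms says nothing about robustness to real-data nuisances
(BPE, motion, fibroglandular texture).

The `boundary_roughness` statistic (isoperimetric ratio
perimeter²/(4π·area), measured on a 5-point-smoothed marching-squares
contour; the smoothing suppresses the ~15% pixelation bias on smooth
shapes) quantifies the shape contrast: generated malignant lesions score
several times higher than benign ones with no overlap between the
distributions.

## The desk-scale study

The built-in study (`bcrcnn.experiments.run_study`) uses 145 cases at
128×128 (100 train / 15 val / 30 test — 200 training slices), the tiny
backbone with a 24-channel FPN, per-level anchor base scales
{16, 32, 64, 128, 256} (the defaults scaled to the 128-px field of view),
lr 0.01, 15 epochs.  These sizes keep a full run in the ten-to-fifteen
minute range on one CPU while leaving every architectural constant (300
candidates, 7×7 pooling, canonical size 160, size-bin edges 64/128, three
extra convs, threshold 0.5) at its full-scale value.

## Numerical and engineering choices

* No GPU framework is used: `bcrcnn.nn` is a ~400-line reverse-mode
  autodiff over float32 numpy arrays (im2col convolutions, differentiable
  weighted gathers for ROI align, probability-space losses).  Gradient
  correctness is property-tested against central differences.
* The VGG-16 preset reproduces the 13-conv feature extractor (stage taps
  at strides 4/8/16/32); `load_npz` accepts pretrained weights and
  averages a 3-channel first conv down to grayscale.  Tests never load
  external weights.
* Checkpoints are flat named-array `.npz` files with the configuration
  echoed as JSON inside.
* Degenerate inputs: empty proposal sets fall back to one whole-image
  proposal; images are zero-padded bottom/right to a multiple of 32;
  rates with zero denominators are NaN with a warning.

## Known limitations

* Batch size is fixed at 1; there is no GPU path, mixed precision, or
  multi-scale test-time augmentation.
* The phantom's single-lesion-per-case default reflects the geometric
  reality that two full-size lesions rarely fit one 128-px breast with
  the required margins; multi-lesion cases are supported but may raise
  a generation error when crowded.
* VOC "difficult/truncated" flags are parsed and ignored; DICOM and
  time-series (kinetic) features are out of scope.
* Real-data use requires caller-provided breast geometry (the axial
  baseline and midlines are not estimated from images outside the
  phantom).
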
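# Methods

## The problem and the two detection routes

The task is to find every large cancer-line cell (MCF-7-like, mean diameter
≈ 20 µm) in an 8-bit bright-field micrograph containing a background
population of small leukocyte-like cells (≈ 10 µm) and debris, without any
fluorescent label at inference time. Fluorescence (FITC cell-body dye on
the cancer cells, DAPI nuclear stain on all nucleated cells) is used only
to build ground truth.

Two routes are implemented. The *decoupled* route separates localization
(MSER) from identification (a shallow tile CNN) so that errors can be
attributed per stage. The *integrated* route trains a single anchor-box
detector under the training contract of a two-stage region-proposal
detector. Both are evaluated with the same box/centroid matching semantics.

## Synthetic scene generator

No image data ship with the package, so `brightcell.scenes` renders the
study conditions directly:

- **Geometry.** 512×512 frames at 0.8 µm/pixel by default. Cell diameters
  are drawn per class from truncated normals (±3 sd): MCF-7
  N(20 µm, 3 µm), WBC N(10 µm, 1.5 µm) — preserving the ~2× mean-diameter
  ratio that makes size a usable classification cue. Debris is rendered as
  small irregular dark specks (unions of offset disks, ~4 µm).
- **Photometry.** Bright background (default level 180) with cells darker
  than background: interior offsets −55 (MCF-7) and −45 (WBC), a darker rim
  (−35) over the outer 18% of the radius, class-specific interior texture
  (Gaussian random fields; MCF-7 amplitude 14 at 2.5 px correlation, WBC 7
  at 1.2 px), a global blur of σ = 0.8 px and additive noise σ = 3. The
  texture/contrast asymmetry is deliberate: it keeps the two classes
  separable *after* size equalization, which the size-feature study
  requires.
- **Fluorescence.** Each MCF-7 contributes one FITC blob (0.9 r) and one
  DAPI blob (0.45 r); WBCs contribute DAPI only; debris neither. Blob
  counts per mask therefore equal class counts exactly and are asserted in
  tests.
- **Placement.** Rejection sampling with a minimum inter-cell gap (4 px
  between circle edges). An optional interior margin keeps every circle at
  least that far from the frame border; the pipeline defaults use margin =
  18 px (half the tile size) so that every cell is tile-croppable. With no
  margin, boundary-crossing cells occur naturally and carry a
  `touches_boundary` flag. Overcrowded specifications fail with an explicit
  error after bounded retries.

What the generator does **not** emulate: optical point-spread physics,
focus gradients, overlapping/touching cells, red blood cells, staining
variability, or the long-tailed morphology of real cells. Passing the
scaled studies therefore demonstrates that the pipeline machinery is
correct and that the claimed properties (size reliance, polarity
sensitivity, FN attribution) hold on data with the stated statistics — not
that the specific accuracy numbers transfer to real microscope images.

## MSER localization

The localizer binarizes the image at thresholds δ, 2δ, … (δ = 5 gray
levels), labels connected regions at each level, and links regions across
levels by containment (the level sets are nested). For a region R at level
k with area A(k), the variation is (A(k+1) − A(k−1)) / A(k), where A(k+1)
is its containing region one level up and A(k−1) its largest child one
level down. A region is a candidate when its area lies inside the
configured band and its variation is at most `max_variation` (default
0.25); a candidate location must be supported by at least `stability_range`
(default 2) consecutive levels. Candidates are ranked by variation (ties:
larger area) and greedily accepted with a minimum centroid separation of
d_lo/2, which collapses the nested duplicates of one cell.

The size band is specified as diameter bounds with a ±5% margin applied on
the *diameter* and converted to an equivalent-circle area band
π·(d/2)². Polarity defaults to dark-on-bright (the image is inverted for
bright-on-dark). The pipeline derives the band from both class
distributions (WBC mean − 3 sd to MCF-7 mean + 3 sd) so that non-target
cells are also localized and become classifier negatives.

Tiles of 36×36 (chosen so the largest cells fit at 0.8 µm/px) are cropped
centered on each localization; a tile that would cross the border is
skipped and the cell counted as a localization miss.

## Tile labeling and the shallow CNN

A tile is labeled MCF7 iff both a FITC and a DAPI signature (≥ 1 positive
pixel) fall in the central third of the tile; otherwise NON_MCF7. The rule
is a pure function of the masks.

The classifier is a self-contained numpy CNN: 2 or 3 valid-mode 5×5
convolutions with 16/32/64 filters, each followed by ReLU and 2×2 max
pooling (pooling is skipped when the spatial side has shrunk below 2, which
is what admits the 15×15 input variant with two conv layers), then one
fully connected layer producing a 2-dimensional class-score vector.
Training: softmax cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999), batch size
64, learning rate 10⁻³, 35 epochs by default, inputs scaled to [0, 1], no
augmentation (augmentation would confound the size-feature experiments).
Backpropagation is verified against finite differences in the test suite,
and training is bit-deterministic given the seed.

The size-feature study resizes tiles bilinearly and center-crops: doubling
the small-class tiles at test time (accuracy must drop if the model leans
on size), then retraining on size-equalized data at 36×36 (doubled WBC) and
at 15×15 (halved MCF-7, two-layer network).

## Automatic box annotation

FITC blobs are localized with the circular Hough transform
(`skimage.transform.hough_circle` on the mask's edge image), searching radii
[0.4·d_lo, 0.6·d_hi] of the MCF-7 diameter bounds, with near-duplicate
peaks suppressed at a minimum separation of r_lo. A hit is kept iff its
circle lies strictly inside the frame ("touching the boundary" = the circle
crosses the border, not the 36-px box) and at least one DAPI-positive pixel
lies inside the circle. Each surviving blob yields a 36×36 box centered on
its rounded centroid; a box that would extend past the frame after rounding
is dropped. On margin-18 synthetic scenes the procedure is exact: one box
per target cell, every center within 2 px of truth.

## Anchor-box detector

The reference design for this component is a deep two-stage detector; at
desk scale the *training contract* is kept and the backbone shrunk. Anchors
are a dense grid of 36-px squares at stride 4. An anchor is positive when
its best IoU with ground truth is in [0.6, 1], negative in [0, 0.5], and
ignored in the (0.5, 0.6) gap. Training pools all positive windows with
sampled negatives per image: half *hard* negatives — the windows whose
central 12×12 region carries the most absolute deviation from the image
median, i.e. the non-target cells and debris the detector must reject — and
half uniform negatives, at 2:1 negatives:positives. The scoring network is
the same conv stack with 8/16/32 filters, trained 30 epochs. Inference
scores every anchor window, keeps scores ≥ 0.5, and applies greedy NMS at
IoU 0.3; NMS can be disabled to expose redundant boxes for the FP-type
analysis.

Images are standardized globally (zero mean, unit variance over the whole
frame) before windows are cropped. This is the detector's photometric
inductive bias: a uniform brightness shift or a centered contrast stretch
cancels under global standardization (up to clipping effects), while the
*within-image* contrast differences between cell classes are preserved —
so the detector is robust to the shift/stretch stress tests but collapses
under contrast-polarity reversal, and recovers once retrained on originals
plus negatives. Per-window standardization was rejected: it erases the
between-class amplitude cue and measurably degrades precision.

The train report's mean IoU and mean score are computed by running
detection on the training images and averaging over detections that match
a ground-truth box at IoU > 0.5.

## Photometric transforms

All three operators compute in floating point, record their draws, clip to
[0, 255] and quantize last (the clipped fraction is logged rather than
raised, so arbitrary inputs are handled):

- **Shift**: I′ = I + B₁, B₁ ~ U[mean/4, mean/2] → the mean rises by
  25–50% pre-clip. A zero-mean input degenerates to the identity with a
  warning.
- **Stretch**: I′ = A₂·(I + B₂), A₂ ~ U[1.5, 2.5],
  B₂ = 127.5/A₂ − mean(I). This centers the stretched histogram at the
  midpoint of [0, 255] and scales the variance by exactly A₂² ∈
  [2.25, 6.25] (+125% to +525%). The operator order is ambiguous in the
  prose it reproduces (center first, then scale, would brighten and
  saturate bright-background images); the chosen resolution preserves the
  literal algebraic form, the stated variance bounds, and the stated
  "darker, higher-contrast" behavior simultaneously.
- **Negate**: I′ = 255 − I, an exact involution; the aggregate histogram of
  a negated set is the bin-reversed aggregate of the original set.

Aggregate histograms are normalized means of per-image normalized 256-bin
histograms. The "new experiment" analogue re-generates scenes with altered
background (−20), reduced cell contrast (×0.85), extra blur (+0.5 px) and
noise (+1), emulating re-acquisition with different focus/exposure.

## Evaluation semantics

Box matching is greedy by descending detection score at strict IoU > 0.5
over half-open pixel boxes; each truth box matches at most once. A
detection overlapping only already-matched truth is a *redundant* FP; one
overlapping no truth is a *non-target* FP. Greedy matching is checked
against an optimal-assignment oracle on small instances in the tests. In
decoupled mode, truth cells are matched to centroids within 18 px (half the
tile); unmatched targets are localization FNs, matched-but-misclassified
targets are classification FNs, and a matched centroid whose tile was
dropped at the border counts as a localization FN. Sensitivity
(100·TP/(TP+FN)), precision (100·TP/(TP+FP)) and F1 (harmonic mean) are
kept at full precision internally and rounded only for presentation;
undefined denominators yield NaN, never silent zeros.

## Study scales and defaults

Every scenario is sized to finish in minutes on one CPU and is fully
configurable back toward larger scales: decoupled study — 20 scenes of
512×512 (6 MCF-7, 18 WBC, 4 debris each), 60/40 split by image, classifier
20 epochs; detector studies — 18 scenes of 256×256 (4 MCF-7, 7 WBC, 2
debris), stride-4 anchors, 30 epochs; size-feature study — 20 scenes, 8
MCF-7 + 12 WBC each, truth-centered tiles. Scene generation, splitting, and
training use separately derived seeds; identical configuration and seed
reproduce every report bit-for-bit.

## Known limitations

- The MSER stability parameters (δ, stability range, max variation) and the
  Hough radius band / DAPI-signature criterion are not fixed by the
  reproduced design; the defaults above are this package's choices and are
  exposed in the configs.
- The anchor detector is single-stage over a fixed anchor size with no box
  regression; it relies on the ground-truth boxes being fixed-size. Cells
  larger than the anchor or overlapping cells are out of scope.
- Synthetic cells are non-overlapping disks; touching-cell splitting and
  watershed-style segmentation are explicitly out of scope.
- Accuracy figures obtained on synthetic scenes characterize the machinery,
  not performance on real microscope images.
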
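# Methods

`crownscope` implements an individual tree-crown extraction pipeline for
low-stature orchard/plantation stands (the motivating case is *Camellia
oleifera*, a shrub-like oil tree under 3 m tall) surveyed with
centimeter-resolution visible aerial imagery plus a photogrammetric surface
model. This note describes the models and procedures, the choices made
where the design was genuinely open, and what the synthetic test scenes do
and do not demonstrate.

## Input construction

The pipeline consumes a pixel-aligned RGB orthomosaic and a digital surface
model (DSM). From these it derives:

- **EXG** (excess green index), `EXG = 2G − R − B`, computed on raw band
  values with no rescaling and no clamp; negative values are meaningful
  (non-vegetation) and are kept.
- **DEM** (bare-ground elevation): the DSM is passed through a moving
  *minimum* filter (default window 20 × 20 px) that suppresses above-ground
  objects whose footprint fits inside the window, then a moving *mean*
  filter (default 5 × 5 px) that smooths the blocky minimum surface. Both
  filters use edge replication at raster margins, which avoids artificial
  height spikes there. Even-sized windows follow the scipy convention
  (center-heavy on the leading side); the test suite pins this down against
  a literal double-loop oracle.
- **CHM** (canopy height model): `DSM − DEM`, negatives preserved (their
  count is logged).

The minimum filter only recovers ground under a crown when its window
extends past the crown footprint. At the emulated survey's scale (ground
sampling distance 0.0153 m, crown diameters 1.2–3.5 m ≈ 76–226 px) the
20 px default window cannot see past a crown; on synthetic scenes
`recommended_min_window` sizes the window to the largest planted crown
(largest major axis + 8 px), and any residual terrain-slope bias appears as
a small height overestimate (≈ 2–5 % on the default scenes).

Six input recipes are supported, with layers stacked in the order blue,
green, red, then the elevation layer: RGB (3), RGB-DSM (4), RGB-CHM (4),
EXG (1), EXG-DSM (2), EXG-CHM (2). Because digital numbers and meters are
not commensurate, layers are normalized before training: reflectance-like
bands min-max to [0, 1] over the mosaic, elevation bands divided by a
configurable height ceiling (default 5 m, comfortably above the < 3 m
stand). Rasters are cut into non-overlapping 256 × 256 px tiles from the
top-left corner (trailing partial windows dropped rather than padded), and
the tile set is optionally quadrupled by 90°/180°/270° rotations applied
identically to input and label chips.

## Segmentation model

The segmenter is a residual-encoder U-Net. The stem is a 7 × 7 stride-2
convolution + BN + ReLU followed by 2 × 2 max pooling, bringing a chip to a
quarter of its size at `base_width` channels. Each of `encoder_depth`
residual stages then halves the spatial size (stage 1 keeps it) and sets
the width to `base_width · 4 · 2^(i−1)`; at the defaults (`base_width` 64,
four stages) a 256 × 256 chip reaches an 8 × 8 bottleneck with 2048
channels, and the post-stem feature is 64 × 64 × 64 — both asserted by the
test suite through a shape-introspection hook. A stage is
`blocks_per_stage` two-convolution residual blocks (3 × 3 conv/BN/ReLU,
3 × 3 conv/BN, projection shortcut where shape changes, post-add ReLU);
the default is one block per stage, which preserves the shape contract
while keeping CPU training tractable. The decoder mirrors the encoder:
2 × 2 stride-2 transposed convolution, concatenation of the equal-size
encoder feature (the pre-pool stem feature at half resolution; nothing at
full resolution, where no encoder feature exists), and a 3 × 3
conv/BN/ReLU fusion; a final 1 × 1 convolution emits a one-channel crown
score.

The network, its backward passes, and the Adam optimizer are implemented
directly on numpy (im2col convolutions over BLAS); gradient correctness is
verified against central differences per layer and per block.

**Training.** Per-pixel binary cross-entropy on logits (the natural loss
for a one-channel binary mask head), Adam at learning rate 0.001, batch
size 4, up to 100 epochs. A seeded hold-out split (default 20 % — the
protocol names hold-out validation without a ratio) is monitored by mean
IoU over the background/crown classes; only improving checkpoints are
kept, and training stops once validation mIoU has not improved for
`patience` (default 10) consecutive epochs. All randomness (initialization,
split, shuffling) flows from one integer seed; identical seeds give
identical training logs. Pretrained encoder weights are not supported —
initialization is seeded He-normal only.

**Inference.** Scores are sigmoid probabilities thresholded at 0.5 into a
{0, 255} mask. Rasters larger than one tile are scored in
half-tile-overlapping windows whose probabilities are averaged before
thresholding, suppressing tile-seam artifacts; rasters smaller than a tile
are reflection-padded and cropped back.

`ResUNetSegmenter` wraps all of this behind the scikit-learn estimator
protocol (`fit`/`predict`/`predict_proba`/`score`, `get_params`,
fitted attributes with trailing underscores), so it composes with sklearn
model selection; `build_resunet`/`train`/`predict_mask` are thin module
functions over the same machinery.

## Crown measurement

Binary masks decompose into connected components under 8-connectivity (a
compact crown that touches diagonally is one object). Components smaller
than `min_crown_pixels` (default 50 px ≈ 0.012 m² at the survey
resolution) are dropped as speckle. Per instance:

- **CPA** (crown projection area) = pixel count × resolution².
- **CW** (crown width): Canny edges are extracted from the component patch
  (σ = 1, no hand-tuned thresholds) and an ellipse is fitted to the edge
  points by direct least squares. The full major and minor axes times the
  resolution give the maximum and minimum crown width; CW is their mean.
  The fitted ellipse — not a minimum-area enclosing ellipse — is the
  interpretation adopted for the crown's "external ellipse". Degenerate
  components ((near-)collinear pixels, too few edge points, or a fitted
  ellipse whose area is grossly inconsistent with the pixel count) are
  flagged unfittable and excluded from CW reporting rather than
  contributing a garbage number.
- **Tree height** = maximum CHM value over the component's pixels.

Crowns touching the raster border have incomplete shapes; they carry a
flag and are excluded from evaluation.

## Evaluation protocol

Predicted and reference crowns are matched one-to-one greedily in
descending IoU order (IoU in percent, pairs admitted only *strictly above*
the 50 % threshold; ties break toward smaller label ids). Above a 50 %
threshold the candidate graph is already a matching — two disjoint regions
cannot each overlap the same region at IoU > 50 % — so greedy equals the
optimal assignment there; the suite verifies agreement with exhaustive
enumeration. Accepted pairs are TP, leftover predictions FP, leftover
references FN, and

    P = TP/(TP+FP) × 100,  R = TP/(TP+FN) × 100,  F1 = 2PR/(P+R).

Zero denominators leave a metric undefined (NaN with a warning), never 0.
Report percentages are rounded half-up to two decimals (so an exact
84.375 prints as 84.38, matching how such tables are conventionally
rounded).

Agreement of matched-pair crown width, area and height is summarized by
R², RMSE = √(Σ(yᵢ−xᵢ)²/N) and rRMSE = RMSE/x̄ × 100 (x reference,
y predicted). The default R² normalizes the residual sum by the spread of
the *predictions* around their own mean, Σ(yᵢ−ȳ)², reproducing the
formula as printed in the protocol this package implements;
`conventional=True` selects the textbook reference-centered denominator.
Both the mean matched-pair IoU and the pooled crown-pixel IoU are
reported, since a table "IoU" column can mean either.

## Synthetic scenes

`gen_scene` emulates the surveyed stand: earth-toned background
(mean RGB ≈ (120, 100, 80), Gaussian noise σ = 8 DN), green elliptical
crowns with a radial color falloff (apex ≈ (55, 135, 60) to rim
≈ (78, 116, 72), per-pixel jitter σ = 4) so that EXG-only segmentation is
solvable but not trivial; crown mean widths uniform on [1.16, 3.47] m with
aspect ratios 0.75–0.95 (the published survey's CW range), peak heights
uniform on [0.4, 0.95] × 3 m (heights below 3 m); a DSM that is a smooth
low-relief terrain (≈ 0.3 m range across a 1024 px scene, "little
elevation change") plus an elliptic-paraboloid dome per crown (zero at the
rim, peak at the center — a smooth field with a well-defined maximum for
height estimation); and a {0, 255} truth mask, per-crown label image, and
truth table. Non-overlapping placement uses rejection sampling with
center-distance constraints and whole-layout restarts; identical seeds
give bit-identical scenes.

What the scenes deliberately lack: shadows, weeds and other-species
confusers, crown overlap/occlusion, photogrammetric DSM noise, and
co-registration error. Passing tests therefore demonstrate that the
pipeline's machinery is correct and self-consistent — that the model can
learn and the measurement stack recovers planted geometry — not that
real-imagery accuracy figures transfer.

## Problem sizes and defaults in tests

Desk-scale runs use a miniature model (base width 8, two stages, one
residual block each — the architecture unchanged, only narrower and
shallower), 20 crowns in a 1024 px scene (64 augmented tiles), 10 training
epochs, one CPU. These sizes were chosen as the smallest configuration on
which the end-to-end contracts (crown-pixel IoU > 0.7, recall > 70 %
against scene truth) are demonstrated with a wide margin; the measured run
reaches ≈ 99 % crown-pixel IoU and 100 % recall. The measurement-recovery
check uses 50 crowns in an 1800 px scene (median CW error ≈ 0.1 %, CPA
exact to rasterization, height ≈ 1 %).

## Known limitations

- The DEM ground filter needs bare ground within its window; under closed
  canopy it rides up the vegetation and biases CHM low (in dense real
  stands) or along terrain slope (wide windows on sloped synthetic
  terrain). This mirrors the known behavior of minimum-filter ground
  extraction.
- Touching crowns merge into one instance; the semantic (not instance)
  segmentation model does not separate them, and no splitting is
  attempted.
- GeoTIFF georeferencing is not parsed; resolution rides in a JSON sidecar
  or a CLI flag, and rasters are assumed pixel-aligned.
- The numpy training loop is single-threaded BLAS-bound; it is meant for
  desk-scale models, not for reproducing full-scale training runs.
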
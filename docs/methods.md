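# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the numerical conventions, and what the synthetic phantom does
and does not establish about real OCT data.

## The classification problem

An SD-OCT C-scan is a 3-D volume of backscattered-intensity values in dB,
indexed (B-scan, depth row, lateral column); one column of one B-scan is an
A-scan. The clinical acquisition this package is built around images a
3.0 × 3.0 × 2.5 mm field at 1024 × 1024 × 512 px (lateral pixel
3000/1024 ≈ 2.93 µm; the axial pixel size is stored independently of the
naive depth/rows ratio because the optical path through tissue rescales it
— the container records both). Each C-scan is labelled *healthy* (liver
parenchyma) or *tumor* (colorectal liver metastasis) from histology of the
scanned area; whole scans carry one pure tissue type. The classifier works
on 2-D tiles cut from individual B-scans, and all reporting is at tile
level; an optional majority vote over a scan's tiles is easy to add on top
of the prediction tables but is not part of the evaluated pipeline.

## Phantom model

The generator emulates the image statistics the preprocessing chain relies
on. For each B-scan:

* **Surface**: a tilted line (`surface_tilt` px height per px width,
  default 0.03 — specimens are scanned at a slight angle to reduce specular
  reflection) plus Gaussian-smoothed roughness (`surface_roughness_px`,
  default 3 px SD), varying slowly across B-scans.
* **Depth attenuation**: below the surface the expected natural
  log-intensity falls linearly with depth at `attenuation_per_px`
  nepers/px, jittered per A-scan (`attenuation_jitter`, 5% SD) and
  modulated by a smooth unit-variance heterogeneity field of correlation
  length `heterogeneity_scale_px` (12 px) scaled by `heterogeneity_amp`.
  The volume stores dB = 10/ln 10 × log-intensity, anchored at
  `surface_peak_db` = 60 at the surface over a `noise_floor_db` = 0 floor;
  the 8-bit scaling stage is invariant to affine shifts of these anchors.
* **Speckle**: multiplicative gamma noise with mean one and shape
  `speckle_shape` (default 4, i.e. 50% intensity SD) applied to the linear
  intensity — the standard first-order approximation of fully developed
  coherent speckle. `None` disables it for analytic tests.
* **Artifacts**: per B-scan, Poisson(`artifact_col_rate`) columns are set
  to just above the surface peak over their full height, emulating detector
  saturation by specular reflections.
* **Ground truth**: the per-column surface row; a tissue mask marking
  voxels whose noiseless expected signal sits at least `snr_floor_db`
  (5 dB) above the noise floor; the planted artifact positions.

Class defaults: healthy `attenuation_per_px` 0.030 (≈ 0.13 dB/px, a usable
band of ~420 px) with `heterogeneity_amp` 0.10; tumor 0.048 (1.6×) and
0.25 (2.5×). These separations make a plain depth-decay-slope statistic an
almost perfect classifier (AUC ≈ 1 over 20 scans), so the CNN's task is to
rediscover learnable structure, not to squeeze out marginal signal. The
default phantom geometry is a desk-scale stand-in for the clinical one:
32 B-scans of 400 × 340 px, tall and wide enough that 299-px tiles fit with
overlap while a full cohort generates in seconds. One pseudo-patient
contributes one healthy and one tumor scan, mirroring how both tissue types
are imaged on the same resection specimen.

**What the phantom does not model**: anatomical texture (vessels, bile
ducts, lymphoid aggregates), mixed or transitional tissue, surface fluid
films, motion, or any instrument-specific artifact beyond saturated
columns. Passing the synthetic-recovery tests therefore demonstrates that
the pipeline's mechanics (scaling, correction, masking, tiling, QC,
splitting, training, metric arithmetic) are correct — not that the
classifier would reach any particular accuracy on clinical scans.

## Preprocessing

8-bit conversion scans the first, middle (`floor((n−1)/2)`) and last B-scan
for the global min/max and maps the whole volume linearly onto [0, 255]
(half-away-from-zero rounding, clamping outside the anchor range). This
anchors contrast at the tissue-surface peak and deep noise floor rather
than per-image histograms, and keeps one consistent scale per C-scan.

**Column removal.** A column is a saturation artifact when its mean
exceeds the image mean by `artifact_k` image standard deviations; one pass
is applied and surviving columns are concatenated, narrowing the image.
The factor is the rule's only free parameter and was set by margin
analysis: a full-contrast B-scan (air ≈ 0, surface ≈ 255) has pixel SD
≈ 70–110 and mean ≈ 100–130, so a saturated column (mean 255) sits only
1.2–2 SDs above the mean — the classical 3 SD factor can never fire. At the
other extreme, when nearly half the columns are saturated the image mean
rises toward 180 and detection collapses once `mean + k·std` crosses 255.
`artifact_k = 0.6` keeps the detection cliff above ~60% column saturation
while leaving a ~30-gray-value margin over the brightest genuine columns
(measured ≤ ~137 across phantom classes and seeds).

**Tissue mask.** 5×5 median filter; binarization (gray value ≤ 20 →
background); background/hole handling in which 0-regions connected to the
image border (air above, low-SNR depth below) stay background and enclosed
0-regions are filled; erosion then dilation with square structuring
elements of radius 3 px (small enough to preserve the tissue band at this
scale); and a final fill of every closed contour of the 8-connected
foreground. The result is white superficial tissue on black.

**Tiling.** Tile origins lie on a `tile_stride_px` grid (default 150 px,
≈ 50% overlap) over the mask's bounding box, clipped so tiles stay inside
the image; a tile is kept when ≥ `min_tissue_fraction` (default 0.8) of it
is mask-positive, and masked-out pixels inside kept tiles are zeroed.
299 px is the classifier's input size; 0.8 keeps tiles mostly tissue while
tolerating surface tilt and curvature.

**Quality control.** A B-scan is flagged when column removal cropped
≥ 1/3 of its width (inclusive bound) or it produced no tiles. A C-scan is
excluded outright when ≥ 1/3 of its B-scans are flagged; otherwise only the
flagged B-scans are dropped — isolated problems cost single B-scans, not
the scan. The QC report accounts for every input B-scan either way. Manual,
judgment-based review criteria are out of scope; only these two codified
rules are implemented.

## Cross-validation plan

15% of C-scans per class (half-away-from-zero rounding, minimum one per
class; the test draw is stratified) form a fixed test set shared by all
runs. The remaining ~85% are, within each of 5 sets A–E, shuffled with a
set-specific seed and dealt round-robin into 5 class-stratified folds;
iteration *i* trains on four folds and validates on the fifth, so each
set's validation folds are disjoint and cover the non-test scans exactly
once. The validation share is thus a fifth of the retained 85% (17% of the
total) — the nominal 70:15 is honoured approximately, in exchange for
exactly non-overlapping iterations. C-scans are atomic throughout, which is
what prevents neighbouring, nearly identical B-scans from straddling
training and validation; patient identity is recorded but deliberately not
constrained (the splitting unit is the scan). `verify_no_leakage` checks
any tile-to-partition assignment against a plan and fails loudly, naming
the scan and run, on the first violation.

## Classifier

Both trunks share the head: global average pooling over the final feature
maps, one fully connected output, sigmoid. Inputs are grayscale tiles
scaled to [0, 1] and replicated onto three channels (so the same tile feeds
all channels of an RGB-native architecture). The positive class is tumor
and the decision threshold is 0.5.

* `xception`: the 36-layer depthwise-separable-convolution trunk with
  residual connections, for GPU-scale fine-tuning. It is an optional torch
  extra; no weights are downloaded, and the NumPy training loop refuses it.
* `small_cnn`: a fixed trunk implemented directly on NumPy — 4×4 average
  pooling, then three 3×3 stride-2 convolutions (8, 16, 32 filters) with
  ReLU; ~6k parameters. Convolutions run as im2col matrix products with
  exact backpropagation; there is no batch normalization or dropout, so
  inference is deterministic and exactly independent of batching.

Training is mini-batch Adam on per-tile binary cross-entropy with seeded
shuffling; loss and F1 are recorded per epoch on both partitions (training
metrics are the running per-batch values, validation is recomputed after
each epoch). The default configuration (batch 20, 10 epochs, learning rate
1e-5) is the fine-tuning protocol for a large pretrained trunk, where tiny
steps suffice. Training the small trunk from random initialization at 1e-5
would move its weights by ~1e-3 over a whole run and learn nothing;
`small_cnn_config()` therefore uses the conventional Adam step 1e-3 and
5 epochs, the scaled-down protocol used by the end-to-end tests. Rising
validation loss late in training (overfitting) is permitted and simply
shows in the learning curves. All 25 runs of a plan share one architecture
and configuration, differing only in their data split.

## Metrics and aggregation

All six metrics derive from the test-set confusion matrix; a metric whose
denominator is zero is reported as NaN with an explicit reason and excluded
metric-wise from aggregation, never silently zeroed. Aggregation uses
unrounded per-run values, the sample (n−1) standard deviation (the
population version is available via `ddof=0`), and exact min/max; the mean
is clamped into [min, max] to guard against last-ulp drift on identical
inputs. Display rounding is half away from zero at two decimals. The
rendered table has one row per run A1–E5 plus Mean and SD, columns
Sensitivity/Recall, Specificity, PPV/Precision, NPV, Accuracy, F1-score;
rendering is a pure function of its inputs and a missing run is a
completeness error, not a blank row.

The bundled 25-run benchmark table reproduces its published summary under
this arithmetic: means 0.94/0.93/0.92/0.94/0.93/0.93, sensitivity range
0.86–0.99, specificity range 0.78–0.96. Two caveats surface when
recomputing from the printed per-run values: the printed F1 range 0.88–0.97
excludes run C1, whose own row implies F1 0.83 (the package reports the
table-derived extrema 0.83–0.97); and the PPV SD recomputed from the
2-decimal rows rounds to 0.03 where the published summary prints 0.04 — an
artifact of aggregating rounded rather than unrounded values.

## Numerical conventions and degenerate inputs

* Rounding is half away from zero everywhere a convention is needed.
* Coordinates are (row, column), 0-based, row 0 shallowest; A-scans run top
  to bottom.
* A constant C-scan scales to all-zero images with a warning rather than an
  error; an all-background mask or an image smaller than the tile size
  yields zero tiles and a B-scan flag, not a crash.
* The container encodes dB affinely into 16-bit PNGs (quantization error
  < 0.001 dB for a 60 dB range, bounded well under 0.01 dB); metadata
  round-trips exactly.
* Seeds: every stochastic component takes an explicit integer seed;
  per-scan and per-set seeds are derived through `numpy` seed sequences and
  kept below 2³¹.

## Problem sizes used by the test suite and acceptance script

Phantom-recovery checks use 30 C-scans of 6 B-scans (26 clean + 4
constructed violators with ~160 saturated columns per 340-px B-scan);
the end-to-end run uses 20 C-scans of 32 B-scans (≈ 1900 tiles), the small
trunk and the 5-epoch from-scratch configuration. These sizes were chosen
so a full validation cycle completes in minutes on a single CPU core while
still exercising every stage at realistic per-B-scan dimensions.

## Known limitations

* The phantom's two classes are separable by simple statistics; end-to-end
  F1 near 1.0 on phantoms says nothing quantitative about clinical
  performance, where the published tile-level F1 is ~0.93.
* Tile-level metrics treat tiles as independent although tiles from one
  scan are highly correlated; the fixed test set makes runs comparable but
  inflates the effective n of the confusion matrices.
* The `xception` path defines the architecture and inference only; its
  training loop must come from a torch workflow, and pretrained weights
  must be supplied by the caller.
* Proprietary instrument files are out of scope; data enters through the
  open container only.
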
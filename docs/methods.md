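# Methods

This note records the models and procedures the package implements, the
defaults that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Frame selection

A frame passes when `max_pixel > 80` and `mean_pixel > 10` (strict
inequalities, 8-bit scale) and its timestamp lies in the inclusive
10:00–14:00 window. `max_pixel` is the maximum over per-pixel channel
maxima and `mean_pixel` the grand mean over all channel values; the
channel convention is ours, since only "maximum and average pixel values"
are specified by the procedure. Among a day's survivors, at most four are
kept, ranked by |t − 12:00| with ties to the earlier frame. Selection is a
pure function of the immutable frame statistics, hence idempotent.

## Registration and plant localization

**Marble detection.** The detector is classical and deterministic: the
per-pixel minimum over R, G, B ("whiteness" — large only for near-white
pixels) is thresholded at the larger of its 99.5th percentile and 75% of
its maximum (the percentile alone dips far below the marbles on large
frames and merges them with bright soil); connected components must have
area ≥ 30 px and circularity 4πA/P² ≥ 0.7, and the best blob
(circularity × brightness) is kept per frame quadrant. A learned detector
could be substituted behind the same function signature.

**Homography.** The reference marker set is the per-quadrant mean over
frames. Each frame's four marbles determine the exact 4-point projective
transform (skimage `ProjectiveTransform`), normalized to H₃₃ = 1;
registration is bilinear inverse warping with zero fill. Mean residual on
noiseless synthetic marbles is below 0.5 px.

**Tiling.** Full-resolution 4608×3456 captures are downsized 4× to
1152×864 and tiled into 384×384 patches by ceiling division per axis with
the last patch flush to the border — 3×3 = 9 patches at the working
resolution. Overlap regions are merged by logical AND (configurable to
OR): the AND reading of "adopt both areas" makes the merged mask a subset
of every contributing patch. Synthetic desk-scale scenes are rendered at
1152×864 directly, so their tiling uses `downscale=1`.

**Accumulation and peaks.** Binary per-frame masks are summed; stable
plant cores accumulate the full frame count while leaves, jittered by the
camera, do not. The map is Gaussian-smoothed (σ = min_distance/6) before
`peak_local_max` (min distance 0.6 × nominal spacing, relative threshold
0.3), and each peak is refined to the intensity-weighted centroid of its
≥95%-of-local-max plateau — the stable rosette core — rather than left on
an arbitrary plateau pixel. Block/genotype labels come from the nearest
expected grid cell inside the marble rectangle. Manual add/remove edits
are flags, never deletions, and re-check the minimum-separation invariant.

## Segmentation

Two interchangeable backends satisfy one contract (`fit`, `predict` →
per-pixel plant probability):

* **Classical hue gate.** In CIELAB, soil/sand/humus hues cluster near
  40–85° while leaves run from green (≈140°) through red/purple (≈10°);
  plant probability is a product of sigmoid gates on hue distance from
  the background band, chroma (floor 9), and lightness. Zero training,
  fully deterministic — used for the coarse tiling pass and fast tests.
  Its blind spot is inherent: a leaf whose color crosses the soil-hue
  corridor during the green→red transition is indistinguishable from
  background by hue alone, and such crops yield empty masks (missing
  color summaries) for a few days per season. This is the same limitation
  that motivates learned segmenters for field imagery.
* **Trainable per-pixel classifier.** A small scikit-learn MLP on 9
  per-pixel features (RGB, Lab, σ=2-smoothed Lab) trained on a pixel
  subsample of the training split; deterministic given its seed. It is a
  deliberately compact learned baseline that the test suite can train on
  CPU in seconds and overfit on demand (training-set Dice > 0.9 on 30
  examples); heavyweight encoder–decoder architectures are out of scope.

Training data grow from polygon annotations (labelme-dialect JSON) by two
branches whose counts are exact: geometric/photometric augmentation
(rotation, shift, scale applied jointly to image and mask; brightness and
contrast to the image only) and compositing (the masked plant pasted onto
a new background with the plant area cut out). The canonical recipe
expands 225 labels into 4100 + 3400 = 7500 examples. Splits are a seeded
shuffle into 68/12/20% train/validation/test.

Post-processing: Gaussian smoothing (σ = 1 px) → binarization (threshold
0.5) → removal of connected components below 25 px². The two thresholds
are configurable defaults; the source procedure names the steps but not
the values. Mask scoring uses Dice = 2|A∩B|/(|A|+|B|), precision,
sensitivity, specificity; 0/0 ratios (e.g. two empty masks) report 1,
since no disagreeing pixel exists.

Per-plant crops are squares of 384 px (zero-padded at borders) with the
inscribed circle masked in, which excludes neighbors at field-realistic
spacing. Desk-scale synthetic scenes pack 12 genotype columns into 1152
px, so the pipeline config uses a proportionally smaller crop (96 px at
1152×864; smaller still in the miniature test scenes) — the geometry
constraint is crop radius < spacing − plant radius.

## Colorimetry

sRGB → XYZ (IEC 61966-2-1 matrix, D65, 2° observer) → CIELAB, with the
Lab reference white taken as the matrix's own white point so that
(255,255,255) maps to exactly (100, 0, 0); round-trip error is below
1/255 per channel. HSV (hue in degrees) and BT.601 YUV conversions and
the vegetation indices ExR = (1.4R−G)/(R+G+B), GRVI = (R−G)/(R+G),
RGR = R/G serve as alternative feature sets; zero denominators propagate
as missing. Color summaries (mean and median per channel, RGB and Lab)
are computed strictly over mask pixels; an empty mask yields a missing
summary. Downstream analyses use the mean.

## Pigment estimation

Relative anthocyanin is (A_main − A650)/denominator with denominator leaf
weight (mg) or area (mm²); relative chlorophyll is (chl a + chl b)/weight
with chl a = 11.65·A664 − 2.69·A647 and chl b = 20.81·A647 − 4.53·A664.
Negative values are retained and logged.

The estimation models map one color space or index (Lab, YUV, HSV, RGB,
ExR, GRVI, RGR) to a pigment response; genotype and date are never design
columns, so estimation transfers across genotypes and seasons. "Default
parameter settings" for the random forest are read as the classical
regression-forest defaults: 500 trees, mtry = max(1, ⌊p/3⌋), unlimited
depth, with an explicit seed. LOOCV runs n single-holdout fits; the
default aggregation is the RMSE of the pooled holdout errors, with a
per-trial mode (mean absolute error — for single holdouts the only other
reading of "average of the RMSEs over trials") available. An optional
monotone recalibration of predictions (isotonic regression) is provided
for the per-area response, whose relation to the raw prediction is
nonlinear; it is off by default.

## Trait-series QC

Per-plant values are averaged within (plant, day), then across plants of
a genotype; plots use 5-day centered moving averages over available days.
Three removal criteria, every exclusion written to a ledger:

1. **Manual records** — date(-range) rows from the incident file (snow,
   storms); matching days are set missing.
2. **Deviating-plant report** — plants whose a\* deviates from the
   genotype median by > 5 robust sd (MAD × 1.4826) on ≥ 3 days are
   reported for human review, mirroring the visual-inspection step;
   nothing is removed automatically.
3. **Block z-score screen** — the season is cut into 10 equal blocks;
   each block in turn is masked and nearest-neighbor imputed from the
   remainder; days whose |imputed − original| difference has z > 5 are
   excluded. Two numerical choices make the z meaningful. First,
   differences are compared only among days with the same donor distance:
   a day adjacent to its donor carries full day-to-day noise while an
   interior day carries trend error over several days, so pooling them is
   heteroscedastic in both tails (distance groups under 8 days merge with
   the next group). Second, the score is robust (median/MAD) by default:
   with a classical mean/sd the anomalous block's own extreme values
   inflate the scale, bounding its z near √((1−f)/f) ≈ 3 for one block in
   ten — a threshold of 5 could then never fire on a block-sized anomaly,
   however extreme. `robust=False` restores mean/sd scoring.

Exclusion removes values and never alters survivors; every missing output
day traces to the ledger or to missing input.

## Environmental model

Daily coldness is the degree-day deficit max(0, T_thr − T_mean) — chosen
because the features are described as accumulated ("moving total",
"cumulative") quantities; a days-below-threshold count would discard the
severity information. The feature for day d with window w and lag l is
the sum of the daily series over [d−l−w+1, d−l]; days whose window
reaches before the series start are missing, and the grid-wide burn-in
(max window + max lag = 28 days for the full grid) is dropped from every
fit so AIC values share the same rows.

The full grid — thresholds {1, 4, 7, 10, 13} °C, windows 1–14 d, lags
0–14 d per factor, 46,305,000 specifications — is searched exhaustively:
features are precomputed per (factor, window, lag[, threshold]) on the
fitting rows, all pairwise Gram tables are formed once, and each chunk of
specifications is solved as batched 3×3 standardized normal equations
(ties go to the first specification in canonical threshold-major order).
Restricted grids of ~2×10⁵ specs fit in well under a second; the full
grid streams in chunks without materializing any design matrix. The
winning specification is refitted conventionally; the engine's
Gram-assembled RSS agrees with the refit except for benign cancellation
when the fit is essentially exact. Features are z-standardized on the
fitting rows of each specification (the standardization scope is a
declared choice), AIC = n·ln(RSS/n) + 2(k+1) with k = 4.

Significance comes from a case-resampling bootstrap (default 2000
replicates, seeded) of the full estimator — standardization is re-applied
within each resample — with BCa intervals: bias correction ẑ₀ from the
bootstrap CDF at the point estimate, acceleration â from jackknife
skewness; a coefficient is significant iff its 95% interval excludes 0.
Coverage of a null coefficient is 94% over 200 simulation replicates, and
the implementation agrees with an independent BCa (scipy) on the same
statistic. Relative importance is the LMG decomposition: the sequential
R² increment of each predictor averaged over all 3! orderings, computed
by exact enumeration; shares sum to the total R² to 10⁻¹⁰.

## PCA of genotype trajectories

Genotype-mean series from all site-years form a genotype × time-point
matrix; time points missing for any genotype are dropped (a mean-imputation
fallback exists for exploration and is clearly second-class). PCA is
column-centered SVD (no scaling by default, matching the common default
of the cited tools; `scale=True` available), with a deterministic sign
convention (largest-|loading| entry positive). Score variances equal the
eigenvalues; per-time-point contributions loading × centered value sum
exactly to each genotype's score, supporting "which site-year drives the
separation" reports. A trajectory constructed as a time-varying convex
combination of two progenitors scores near the progenitors' segment in
the PC1–PC2 plane — the testable analogue of intermediate-phenotype
geometry.

## Synthetic scenes: what they emulate, and what not

The generator renders plots of 48 rosettes (4 blocks × 12 genotypes),
four white marbles (2.5 cm-scale fiducials), per-frame jitter
homographies (defaults ±8 px translation, ±1.5° rotation at the 1152×864
working scale — field rigs drift by storms and maintenance, but no drift
magnitude is documented, so these are declared guesses), a diurnal
brightness curve with multiplicative noise, three background kinds with
static luminance texture plus a fresh per-day chromatic blotch layer
(real soil appearance varies day to day; a perfectly static background
would let any deterministic misclassification accumulate into spurious
localization peaks), snow-speckle days recorded in a manual-record file,
and rosettes of 5–12 ellipse "leaves" in near-regular phyllotactic
arrangement around a dense core, growing through the season. Plants are
drawn in Lab and converted to sRGB, so color truth is exact by
construction up to 8-bit quantization (mean reconstruction error ≲ 0.5
Lab units).

Genotype color trajectories follow anthocyanin(d) = β₀ + β_p·f_p +
β_c·f_c + β_r·f_r + ε with the features standardized over valid days, and
an affine invertible anthocyanin→Lab map (green, light, yellow-leaning at
low anthocyanin → red/purple, darker at high). The leaf spectrophotometry
table inverts the anthocyanin formula exactly: absorbances are
constructed so (A_main − A650)/weight reproduces the mapped value.

Not emulated: perspective distortion (jitter is Euclidean, though the
estimator is a full homography), lens distortion, shadows and specular
highlights, herbivory and disease, plant death, inter-plant occlusion,
and photorealistic leaf texture. Passing tests therefore demonstrate the
correctness of the algorithms under controlled geometry/color truth, not
segmentation accuracy on real field imagery.

## Problem sizes in the test suite

Tests run on miniature study conditions chosen once: scenes of 288–1152
px width and 2–40 days; leaf tables of 40–451 rows; environmental series
of 150–300 days with restricted grids (≈2.2×10⁵ specs) for recovery
tests; random forests of 25–100 trees in LOOCV loops (500 trees for
single fits); 200 replicates × 600 bootstrap draws for BCa coverage. The
acceptance script renders one 1152×864 scene with 20 jittered daily
frames and runs the full localization chain.

## Known limitations

* The classical segmenter loses leaves during the green→red hue
  transition (empty masks → missing color for those plant-days); daily
  aggregation and QC tolerate this, and the trainable backend does not
  share the blind spot.
* The full 46M-spec grid search is exact but takes minutes per response
  series on one CPU; restricted grids are the interactive default.
* The block z-score screen assumes a roughly smooth seasonal trend;
  extremely rough series inflate the imputation-difference baseline and
  reduce its sensitivity.
* GLM fits use a Gaussian family with log link (positive, right-skewed
  pigment scale); responses spanning zero are shifted by an offset before
  fitting, and configurations that fail to converge are recorded as
  missing in the comparison, not raised.
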
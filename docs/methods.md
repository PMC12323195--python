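# Methods

## The measurement problem

The niacin (methyl nicotinate) skin test applies four dilutions of AMN
(0.1, 0.01, 0.001, 0.0001 M) to the forearm through 1 cm patch holes and
photographs the resulting erythema at 1, 5, 10, 15 and 20 minutes.  The
flushing response is attenuated and delayed in several psychiatric
disorders, which makes its *size over time* a candidate screening signal —
provided the size can be measured consistently across cameras, lighting and
shooting distances.  Every photograph therefore includes an arm label with
a white patch, which provides both a colour reference and a length
reference.

The pipeline in this package is:

1. **Calibration** (`preprocess`).  Perfect-reflector white balance: per
   channel, gain `g_c = 255 / mean_c(white patch)`, clipped at 255.  We use
   the mean (not the max) of the patch as the estimator because it is
   robust to specular noise; the patch itself is located as the brightest
   connected subregion of the label mask (90th luminance percentile within
   the label, largest connected component).  Scale normalisation rescales
   the image so that the label's major axis — the longer side of its
   mask's bounding box — spans `target_label_px` (default 96 px).  Only
   *relative* calibration is possible: the label's physical size in mm is a
   property of the printed labels, not of the algorithm, so all areas are
   expressed relative to the label area rather than in cm².  Finally the
   image is resized to the fixed network input of 128 x 512 (bilinear for
   images, nearest for masks).

2. **Segmentation** (`segmentation`, `_nn`).  A U-Net — encoder stages of
   two 3 x 3 conv + ReLU blocks with 2 x 2 max-pooling, a two-conv
   bottleneck, nearest-neighbour upsampling decoder stages with skip
   concatenation, and a 1 x 1 sigmoid output head — predicts a per-pixel
   flushing probability.  The network core is implemented directly on
   numpy arrays with hand-derived gradients (im2col-free offset
   convolutions, Adam), so the package has no deep-learning framework
   dependency and runs on a single CPU.  Loss is soft Dice + binary
   cross-entropy (BCE evaluated from logits for stability; Dice per sample
   with additive smoothing 1.0, then averaged).  The output bias is
   initialised to −3 — roughly the logit of the foreground prior, since
   flushing covers a few percent of the frame — which removes the long
   all-background plateau that a 0.5 initial guess produces under class
   imbalance.  Probability maps are thresholded at 0.5 (`>=` counts as
   foreground) with **no** morphological post-processing, so evaluation
   reflects raw model output.  Dice/IoU are macro-averaged (per image,
   then averaged); both-empty masks score 1.0, empty-vs-nonempty 0.0.

3. **Quantification** (`quantify`).  `A_norm = A_detected / A_label`, both
   areas counted in the same calibrated frame, making the ratio invariant
   to resolution and camera distance.  Detected pixels are attributed to
   the four concentration sites by column bands along the 512-px axis
   (configurable; the default partitions the application zone into four
   equal bands ordered by descending concentration).  Pixels outside every
   band are dropped and counted, so band areas + dropped = total flushing
   area by construction.

4. **Objective 3-scale** (`quantify`).  `A_norm` is quantised at cut-points
   t0 = 0.1091 and t1 = 0.1598: score 0 below t0, 1 in [t0, t1), 2 at or
   above t1.  These constants were calibrated on the open dataset as
   midpoints between the mean `A_norm` of adjacent manual-score strata
   (means 0.0648 / 0.1535 / 0.1661 / 0.1665 for manual scores 0–3), with
   manual scores 2 and 3 merged because their mean areas differ by only
   0.0004.  `derive_thresholds` reproduces t1 = 0.1598 exactly; the lower
   midpoint is 0.10915, and the published constant 0.1091 is that value
   truncated to four decimals — the default `ScoreScale` uses the published
   constant for bit-compatibility, and the derivation documents the
   difference.  The published per-stratum SDs are stored verbatim rather
   than recomputed from the variances (they differ in the third decimal,
   an artefact of the original estimator).

5. **Feature vectors** (`quantify`).  20 dimensions = 4 concentrations x 5
   time points, concentration-major (0.1 M first), time ascending.  Two
   schemes: `three_scale` (the quantised scores) and `direct_area` (raw
   `A_norm`).  The ordering is a package convention (recorded in output
   metadata); nothing downstream depends on it beyond consistency.

6. **Screening** (`classify`).  Binary HC-vs-disorder classification with a
   kernel SVM under stratified 5-fold cross-validation.  Per outer fold,
   using the training 80% only: features are standardised (fit on the
   training portion; toggleable), SMOTE oversamples the minority class to
   parity, and a grid search over
   kernel ∈ {rbf, poly}, C ∈ {0.1, 1, 10}, gamma ∈ {0.01, 0.1, 1} (rbf),
   degree ∈ {2, 3, 4} (poly), SMOTE k ∈ {3, 5, 7}
   selects by balanced accuracy on a nested stratified 3-fold split
   (SMOTE re-run inside each inner training fold; first-listed combination
   wins ties, making selection deterministic given the seed).  All
   out-of-fold predictions are pooled into a single 2 x 2 confusion matrix
   — the only construction consistent with reference matrices whose row
   sums equal the cohort sizes (60 HC / 20 patients) — and every metric is
   computed from that matrix: sensitivity = patient recall, specificity =
   HC recall, balanced accuracy = their mean, overall accuracy = trace /
   total, per-class precision/recall/F1 column- and row-wise.

   SMOTE is implemented to its canonical definition (synthetic sample
   `x_i + u (x_nn − x_i)`, `u ~ U(0,1)`, `x_nn` among the k nearest
   minority neighbours; originals preserved) so its convexity property is
   directly testable; only the neighbour search is delegated to
   scikit-learn.

   Score-threshold baselines are provided for comparison: predict patient
   iff the score at a chosen (concentration, time) cell is below a cutoff
   (an attenuated response), and the analogous rule on the total of all 20
   scores.

## Reporting and rounding

Reported metrics are rounded from exact integer ratios (via
`fractions.Fraction` / `decimal.Decimal`) with **round-half-even** at 2
decimals (4 for sensitivity/specificity).  Half-even on exact ratios is the
only rule that reproduces the full set of reference report values —
e.g. 50/80 = 0.625 → 0.62 and 54/80 = 0.675 → 0.68 — where half-up or
floating-point rounding each fail on at least one entry.

## Synthetic data: what it emulates, and what it does not

`synthetic` generates cohorts (default 60 HC + 20 each of DP/BP/SZ, five
photographs per participant = 600 images) whose true normalised areas
follow a saturating-exponential kinetic
`a(t) = a_max · amp(conc) · (1 − exp(−r (t − delay)+))` with additive
Gaussian noise (sd 0.03, clipped at 0) and per-participant lognormal
heterogeneity (sd 0.25).  Group defaults encode the qualitative clinical
picture — controls flush faster (r = 0.30/min, delay 1 min, plateau
`A_norm` 0.26 at 0.1 M) than patients (r ≈ 0.13–0.14/min, delay 3 min,
plateau 0.19–0.20) — and amplitude decreases with dilution (1.0 / 0.75 /
0.45 / 0.04), with the 0.0001 M site essentially unresponsive.  The
kinetic form and the parameter values are this package's choices: they
are set so that the three score bands all occur at realistic rates and
group separation is moderate (cross-validated balanced accuracy well
above chance but far from perfect), not fitted to any dataset.

The renderer draws a skin-coloured strip, a grey label with a white patch,
and per-site flushing ellipses whose pixel area equals `A_norm` x label
area (rasterisation error under 5%).  Device effects exercised: a
per-photograph camera-distance scale (0.8–1.25x), a per-participant
diagonal RGB cast sampled in [0.7, 1.3] and then normalised below 1 so the
white patch never saturates (mimicking sensor exposure control — a clipped
white reference would carry no calibration information), Gaussian blur and
pixel noise.  Ground-truth masks are the sharp pre-blur ellipses,
mirroring human annotation of visible erythema.

Passing on this generator therefore demonstrates that the pipeline's
plumbing, calibration and statistics are correct — it does **not**
demonstrate performance on real skin: real flushing has diffuse
boundaries, texture, hair, specularities and anatomical curvature that the
renderer deliberately omits.  Segmentation scores on the synthetic
benchmark (Dice ≈ 0.94) are accordingly not comparable to scores on real
photographs.

## Numerical choices and degenerate inputs

* Consensus voting: pixel true iff ≥ `min_votes` (default 2 of 5)
  annotators marked it; `min_votes = 1` is union, `= n` intersection.
* Masks on disk: 8-bit single-channel PNG, 0/255; any nonzero reads as
  true (tolerant of annotation-tool exports).
* Splits: participant-level, largest-remainder proportional allocation of
  the 90/10/20 reference fractions, each part guaranteed non-empty;
  a single run seed controls split, weight init and augmentation draws.
* Augmentation: flips are exact array ops (so zero-magnitude parameters
  give a bit-exact identity and certain flips are involutions); rotation /
  shift / scale share one affine warp (bilinear image, nearest mask);
  photometric jitter (brightness / contrast / saturation, default ±20%)
  touches the image only.  Default geometric ranges are mild: ±15°, ±5%
  shift, scale 0.9–1.1.
* Degenerate inputs are errors, not silent defaults: empty white region,
  zero-mean channel, label area < 9 px, non-positive label area, missing
  feature cell, minority class ≤ SMOTE k, confusion matrix with an empty
  actual class.
* Training aborts on non-finite loss; the checkpoint kept is the best by
  validation Dice.

## Benchmark problem sizes

The packaged benchmarks are sized for a single CPU: the single-image
memorisation check trains 25 epochs on one 128 x 512 photograph
(Dice ≥ 0.95); the cohort benchmark renders the default 600-image cohort,
trains a depth-2, 8-channel U-Net (≈30k parameters, lr 2e-3) for 5 epochs
on a 160-image subsample of the 450 training images, and evaluates on all
100 test-participant images (the synthetic scenes are homogeneous enough
that a subsample saturates performance).  The screening harness runs the
full default grid; null-calibration checks use a reduced rbf grid, which
does not change the null distribution being verified.

## Known limitations

* No absolute areas: everything is relative to the label; if the deposited
  labels' physical size were known, `label_real_size_mm` would convert.
* The site-to-concentration band assignment assumes the photograph layout
  places sites left-to-right by descending concentration right of the
  label; other layouts need a custom `SiteGeometry`.
* The manual 4-point score's "erythema beyond the patch area" criterion
  (score 3) is spatial and is not modelled; manual scores 2/3 are merged
  in the objective scale.
* No multiclass screening (the reference evaluation is binary
  HC-vs-disorder only), no probability calibration, no EC50 fitting.
* Pretrained encoder backbones are out of scope; the pluggable
  `SegModelConfig` controls depth/width of the plain U-Net only.
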
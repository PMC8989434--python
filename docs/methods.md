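# Methods

This note documents the models, the synthetic phantom population, the
numerical choices and the limitations of `ctatrophy`.

## Problem and pipeline

Brain atrophy on non-contrast CT shows as two patterns: *central* atrophy
(ventricular enlargement) and *cortical* atrophy (widened Sylvian fissures
and sulci). Both are captured by classical one-dimensional measurements
taken at defined axial levels, which tolerate CT's low soft-tissue contrast
far better than volumetric segmentation. The pipeline automates that
protocol in four sequential modules — key-slice detection, linear
measurement, parietal-sulci assessment, logistic classification — each
consuming the previous module's output, exactly as a human reader would
proceed. The modular design is deliberately not end-to-end: every
intermediate quantity (slice indices, millimetre measurements, indices) is
inspectable and clinically meaningful.

## Pre-processing

* **Windowing.** HU are mapped linearly from the brain window
  [WL − WW/2, WL + WW/2] = [0, 80] HU (WW = 80, WL = 40) onto integers
  0–255, clamped outside. Rounding is half-up, so the window centre
  (40 HU) maps to 128; the choice is symmetric and makes the anchor values
  {0, 40, 80} → {0, 128, 255} exact.
* **Tilt correction.** In-plane head tilt is estimated from the principal
  axis of the bone mask (≥ 300 HU) on the mid-stack slice — exact for an
  elliptical skull up to discretization — then refined within ±0.5° (step
  0.05°) by maximizing the left–right overlap of the mirrored ventricular
  CSF mask on the CSF-richest slice. The thin midline-symmetric ventricles
  give a much sharper angular optimum than the almost-elliptical head
  outline; with no CSF voxels the refinement is skipped. Correction is
  always estimated and applied (no "when necessary" judgement call). On
  phantoms the recovery error is well under 0.5° across ±8° tilts.
* **Model input.** Slices are resampled to 224 × 224 (bilinear,
  anti-aliased); the effective mm-per-pixel is recorded for converting
  pixel-unit regression outputs back to millimetres. In the batch
  preparation path the tilt rotation is applied at the 224 × 224 stage,
  which is equivalent to rotating the 512 × 512 volume up to interpolation
  error and roughly an order of magnitude cheaper.
* **Augmentation.** Training-time augmentation offers random rotation
  (±5°), shift (±5% of the image), zoom (0.95–1.05), left–right flip
  (p = 0.5) and additive Gaussian noise (σ = 5 on the 0–255 scale); a
  zero-magnitude configuration is the exact identity. The shift/zoom/noise
  magnitudes are conventional defaults for this family of augmentations.

## Trainable modules

All three image modules are small multi-layer perceptrons (`nn.MLP`,
float32 numpy) on downsampled standardized slices. Downsampling is
anti-aliased on purpose: the sub-pixel CSF structures (a 2–14 mm third
ventricle is 0.5–3.4 px at the 56-pixel working resolution) survive as a
graded intensity signal rather than aliasing away, and a
moderate-capacity network reads widths from edge intensities.

* **Key-slice detection** — four independent binary scorers (one per key
  slice) on 32 × 32 slices, hidden layer of 64 ReLU units, softmax +
  cross-entropy, SGD with momentum 0.9, batch size 8, one warm-up epoch
  then learning-rate decay ×0.1 at 50% and 75% of the epoch budget
  (initial rate 0.01, 20–25 epochs). Inputs are z-scored per feature with
  training-set statistics stored in the model; without centering the
  scorers collapse to the majority class. Per subject the annotated key
  slice is the positive (duplicated ×4 for batch balance) and 8 randomly
  sampled slices at distance ≥ 2 are negatives; the immediately adjacent
  slices are excluded as near-duplicates. Model selection keeps the best
  of 5 subject-level folds by validation (within-one-slice) accuracy.
  Detection is the per-type argmax with ties to the inferior slice; the
  ordering key1 ≤ key2 < key4 is enforced by constrained argmax when
  violated.
* **Linear measurement** — three multi-output regression heads (key slice
  1 → A,B,C,D; 2 → E,F,G; 3 → HL,HR) on three-channel fused images
  (slices z−1, z, z+1, duplicated at volume edges) at 56 × 56 per channel,
  hidden layer of 96 units, MSE loss, Adam at learning rate 1e-4 with
  multiplicative decay 0.8 every 10 000 steps, batch size 16, ~150 epochs.
  Targets are lengths normalized by the in-plane field of view, so
  millimetre outputs scale exactly linearly with pixel spacing. Inputs are
  *not* z-scored here: per-pixel standardization amplifies the noise floor
  and makes the heads memorize; raw [0, 1] intensities with small initial
  weights act as an implicit ridge and generalize. The output layer is
  initialized at the target mean so the small Adam steps refine residuals
  rather than hunt the overall scale. Training uses the fused images at
  the annotated key slice and its two neighbours (same targets), tripling
  the sample count — consistent with the anatomical-similarity rationale
  for fusion. One multi-output head per key slice (rather than nine
  separate models) shares features among same-slice landmarks.
  Non-positive predictions are clamped to 0.5 mm and flagged.

  *Recalibration.* High-capacity heads interpolate their training set and
  generalize with small but systematic millimetre offsets; the paired-t
  agreement protocol is sensitive to precisely that kind of bias because
  the residual variance is tiny. Two mechanisms matter: shrinkage of
  predictions toward the training mean, and shrinkage *mixing* between
  collinear same-slice landmarks (the intercaudate gap B co-varies
  strongly with the frontal horn width A, so an under-trained head
  predicts B partly through A — this is why the basal-ganglia head gets
  the longest epoch budget, 400 versus 150 for the other heads).
  Training additionally holds out 30% of the subjects — at desk scale the
  calibration cohort should be no smaller than the evaluation cohort, or
  its own noise dominates the paired-t standard error — and subtracts
  the mean out-of-sample residual per measurement. Intercept-only
  calibration is deliberate: at the accuracy these heads reach (r > 0.99)
  slope corrections are negligible, and a fitted slope (let alone a
  multivariate map) costs more calibration variance than the bias it
  removes. The offsets are stored with the model and applied at
  inference; with fewer than 8 held-out subjects (or zero epochs)
  recalibration is skipped.
* **Sulci enlargement** — a binary classifier with the same architecture
  and optimizer recipe as the detectors, on the fused image at key slice
  4; labels come from the >5 mm rule applied to the phantom's sulcus
  widths (strictly greater than 5 mm, at least two sulci). 5-fold
  best-validation-accuracy selection. The 0.5 probability threshold is
  inclusive ("enlarged" at exactly 0.5).

The backbone choice (MLP on downsampled slices, rather than a deep
convolutional network) keeps training deterministic, dependency-free and
inside a desktop-CPU budget; capacity is adequate because the phantom
population is geometrically simple. Layer sizes and the working
resolutions (32/56 px) are configurable.

## Atrophy classifier

Features: the seven indices (Huckman number A+B, ventricle index D/A,
lateral body index F/E, width-of-body index G/E, forefoot index G/A, C,
Sylvian average) + the sulci flag; integrated mode appends age (years) and
gender (female = 0, male = 1). Continuous features are z-scored with
training-set statistics stored in the model; the binary flags are left
0/1 (documented since the convention affects coefficients, not
predictions). The estimator is logistic regression with L2 penalty,
strength chosen from 10 grid points by stratified 5-fold CV on the
training split (log-loss scoring); the three-class form is multinomial
softmax — the conventional reading of "logistic regression" for a
three-way outcome; an ordinal link would be a natural extension. Binary
decisions threshold P(atrophy) at 0.5; three-class prediction is the
argmax with exact ties resolved toward the more severe grade (the safer
clinical default).

## Synthetic phantom population

Geometry: 40 slices of 512 × 512 at 0.45 mm in-plane and 5 mm slice
thickness. The head is two nested ellipses (outer width G, inner F,
anteroposterior elongation 1.25); parenchyma 35 HU, CSF 8 HU, skull
1000 HU, choroid-plexus calcifications 150 HU, air −1000 HU, plus
additive Gaussian noise (σ = 2 HU). Structures are drawn in head
coordinates rotated by the specified tilt (sampled uniformly in ±8°), so
widths along the tilted measurement lines stay exact; the pixel-count
oracle verifies every rendered width to within one pixel spacing.

Axial layout (jittered per subject from its seed): key slice 1 at z
12–15 with frontal horns (outer extent A, inner gap B), third-ventricle
band (width C) and two choroid markers (centre distance D); key slice 3
two-to-three slices below it with lateral CSF slots of widths HL/HR; key
slice 2 three-to-five slices above key slice 1 with ventricular-body bands
(outer extent E, maximal at key slice 2, tapering to the ventricle top);
key slice 4 exactly three slices above the ventricle top, with four
parietal sulcus slots of specified widths. Each structure is most
prominent at its key slice so detection is well posed. *D* is defined as
the centre-to-centre distance of the two choroid-plexus markers (the
precise geometric construction of this landmark varies between readers;
the phantom fixes this convention).

Class-conditional sampling follows the label rules with the >5 mm sulcus
criterion anchored and the remaining ranges chosen to be separable but
adjacent: no atrophy C ∈ [2, 6] mm, Sylvian ∈ [2, 5] mm, sulci ∈ [1, 4] mm;
severe C ∈ [9, 14] mm, Sylvian ∈ [7, 12] mm, 2–4 sulci ∈ (5.5, 9] mm and
ventricular widths (A, B, E) scaled ×1.3–1.6 (D ×1.1–1.25); mild sits
between (C ∈ [6.5, 8.5], Sylvian ∈ [5.3, 6.7], ventricular ×1.1–1.3, at
most one sulcus > 5 mm) and by construction satisfies neither extreme
predicate. The classifying predicate (`classify_spec`) uses the midpoints
between adjacent ranges, so the stored label is always recoverable from
the geometry — the label-rule consistency property the tests check
exhaustively. Skull widths F ∈ [118, 132] mm and G = F + 2×(7–10) mm are
class-independent; anatomical containment G > F is enforced even though
the strict reading of some published cohort tables would order the two
means the other way. Age is sampled with class-dependent means (53, 72,
80 years, clipped to plausible per-class ranges) and gender with per-class
male fractions near one half, so the integrated classifier has a real but
modest demographic signal.

Datasets are written as NIfTI (`.nii.gz`, int16, spacing in the header),
one JSON annotation per subject, and a CSV manifest; identical seeds give
identical manifests and annotations.

## Evaluation statistics

AUC is the Mann–Whitney statistic computed from midranks (ties count ½);
its 95% CI uses the DeLong structural-component variance with a normal
approximation, clipped to [0, 1] (a bootstrap CI would be the obvious
alternative; DeLong is the default because the same components drive the
paired test). The paired DeLong test compares two markers scored on the
same subjects; degenerate zero-variance cases return p = 1 for a zero
difference. Weighted kappa uses linear disagreement weights |i−j|/(k−1)
by default with the quadratic variant also reported, since the weighting
convention is often left unstated in clinical papers; for two categories
the linear-weighted and unweighted forms coincide (tested). "Average F1"
is macro-F1 over the three grades (absent classes contribute 0 and are
flagged); micro-F1 is also emitted. Measurement agreement uses Pearson r
(two-sided t-based p) plus a paired t-test; identical pairs return t = 0,
p = 1 by convention, and zero-variance inputs report the correlation as
undefined rather than a number.

## Experiment scales and expectations

The validation experiments (in `ctatrophy.experiments`, also run by
`scripts/acceptance.py`) use phantom populations sized for a single CPU
core: 20 phantoms for tilt recovery; 300 training / 100 test phantoms for
classification from ground-truth features (two-class AUC ≥ 0.95,
three-class weighted kappa ≥ 0.7, integrated ≥ base); and 200 training /
50 test phantoms for learned-module recovery (within-one-slice detection
accuracy ≥ 0.9 per key slice; Pearson r ≥ 0.8 versus the oracle for B, F
and G with non-significant paired differences; third-ventricle MAE ≤
1.5 mm; sulci accuracy ≥ 0.8). On the phantom population these thresholds
are met with margin; the per-measurement difficulty ordering nevertheless
mirrors clinical experience — the skull widths F/G are easiest, the
small choroid-plexus markers (D) are hardest.

## Limitations

* The phantom is geometric, not anatomical: no cortical folding, no
  partial-volume or beam-hardening effects, no scanner artifacts beyond
  additive Gaussian noise, no posterior-fossa structures. Passing the
  recovery experiments demonstrates that the pipeline machinery is
  correct and trainable, not that the shipped weights transfer to
  clinical NCCT — on real data the modules must be retrained on
  annotated scans.
* Key-slice appearance in the phantom is sharply localized, so detection
  is easier than on real anatomy, where adjacent slices are nearly
  identical; only the within-one-slice accuracy target is meaningful
  here, and no exact-slice target is set.
* Measurement uncertainty is not quantified; line endpoints are not
  regressed (lengths only), so overlays are reconstructed for display
  rather than predicted.
* The three-class model is multinomial, not ordinal; with heavier class
  imbalance an ordinal link may be preferable.
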
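# Methods

This note records the models implemented in `atrophy2d`, their assumptions,
the defaults that matter, and the design choices made where the design was
genuinely open. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## The phantom generative model

A subject's head is a set of nested ellipsoids on a voxel grid (desk preset
96×96×60 at 2.5 mm isotropic; a full-resolution preset 360×480×480 at
0.5 mm exists for in-plane-shape checks). From outside in: air (intensity
exactly 0), a bright scalp/skull shell (6 mm), a skull/dura gap (4 mm), the
extracerebral CSF (eCSF) band, the cortical gray-matter ribbon, and a white
matter core carrying three dark CSF structures — anterior and posterior
lateral-ventricle (LV) ellipsoids and a pair of inferior-lateral
"temporal horn" ellipsoids forming the perihippocampal LV region. GM and
eCSF are split into four lobes by axial angular sectors (anterior =
frontal, posterior = occipital) with the lateral sectors divided by height
into parietal (superior) and temporal (inferior).

Atrophy is a single score per subject,

    alpha = clip(c_age · (age − 55) + c_dx · dx + eps, 0, 1),

with defaults `c_age = 0.015 /yr`, `c_dx = 0.35`, `eps ~ N(0, 0.05)`. It
widens the eCSF band by `(1 + 1.5·alpha)`, dilates LV semi-axes by
`(1 + 0.8·alpha)` (temporal horns get an extra ×(1 + 0.25) in DAT), and
thins cortex by `(1 − 0.4·alpha)`. True brain age is
`age + 20·(alpha − c_age·(age − 55))` years, so a CU subject with `eps = 0`
has brain age exactly equal to chronological age. Ages are uniform on
[55, 90]; sex is a 0/1 code (1 = female).

Deliberate fidelity choices:

* **Contrast structure.** Tissue means are CSF 20, GM 110, WM 150, scalp
  200 (arbitrary units) with Gaussian noise (SD 8) and a per-subject
  brightness offset U[−25, 25] added only inside the head. GM sits close to
  WM while CSF is far from both — so CSF boundaries are intrinsically
  easier than the GM/WM boundary, which is the mechanism behind the
  qualitative finding that 2D CSF volumes track 3D truth better than 2D
  cortical thickness does.
* **Sub-voxel thickness variation.** Each lobe's cortical thickness carries
  an independent per-subject multiplier `1 + N(0, 0.08)` (clipped at
  ±25%). At 2.5 mm voxels much of this variation is below the sampling
  resolution of a 20-slice stack, again mirroring why thickness is the
  harder 2D target. Base thickness is 7.5 mm — anatomically thick, chosen
  so the ribbon spans ≈3 voxels on the coarse desk grid and remains
  segmentable; the atrophy *ratios*, not absolute sizes, carry the signal.
* **Exact ground truth.** CSF ROI truth volumes are label-voxel counts ×
  voxel volume, exact by construction; GM truth is the generative lobar
  thickness in mm. Labels: 0 background (air, scalp, WM), 1–4 lobar GM,
  5–8 lobar eCSF, 9/10 anterior/posterior LV, 11 perihippocampal LV. LVs
  are painted last and override tissue labels, so classes are mutually
  exclusive; atrophy moves each shell's inner surface strictly inward,
  making every CSF truth volume non-decreasing and every thickness
  non-increasing in alpha with other randomness fixed.
* Geometry that cannot fit the grid at maximal atrophy (alpha = 1) raises a
  sizing error up front rather than silently clipping structures.

What the phantom does **not** emulate: MRI physics (no k-space, bias
fields, or Rician noise), gyral folding, registration error, or pathology
beyond global/lobar atrophy. Passing tests therefore demonstrate that the
pipeline recovers the signal its own data model generates — a necessary
correctness property, not clinical validity.

## Preprocessing

The axial head extent is the index range of slices whose fraction of
pixels above the volume's 5th-percentile intensity exceeds 0.5% (both
thresholds configurable); slices are taken at `head_start + k·stride` up to
the head end. With 480 axial slices, a 300-slice head extent, and stride
15 this yields exactly 20 slices. Thick-slice acquisition can additionally
be emulated by `slab_average` (e.g. 5 mm slabs). Per-slice Z-score
normalization maps each slice to mean 0 / SD 1 (a constant slice maps to
zeros with a warning). Label-mask smoothing uses morphological closing with
a square 5×5 structuring element; closing is extensive and idempotent.

## Segmentation network

A U-style fully-convolutional encoder–decoder: `n_stages` encoder stages of
3×3 convolution + batch norm + ReLU followed by 2×2 max-pooling, a
bottleneck with dropout, and mirrored decoder stages of nearest-neighbour
2× upsampling + convolution, with skip connections from the last three
encoder stages to their mirror decoder stages. A final 1×1 convolution
produces 12 class maps at input resolution (inputs not divisible by the
total downsampling factor are padded and cropped back, never rejected).
Loss is unweighted sparse softmax cross-entropy plus an L2 penalty,
optimized by Adam.

Inputs are the normalized slice plus three fixed coordinate channels: two
in-plane maps and one constant per-slice axial-position channel (the slice
index normalized to [−1, 1] across the head extent — information any
acquisition has). Lobar ROIs are defined by position; without coordinates a
small encoder's receptive field cannot distinguish frontal from occipital
eCSF (same intensity, mirrored position) nor parietal from temporal
(differs only by slice height).

Training details: augmentation flips image and label together left–right
with probability 0.5 and adds a brightness offset U[−50, 50] in raw
intensity units *before* re-normalization (the ±50 range is meaningful only
on raw intensities); the output bias is initialized to the empirical log
class priors, which removes the many early updates a rare structure (the
ventricles occupy <1% of pixels) otherwise spends escaping the
background-dominated softmax; batches and shuffles are seeded, so training
is bit-reproducible single-threaded.

The desk preset (8 base channels ×2 per stage, 3 stages, batch 4, lr 1e-2,
weight decay 1e-4, dropout 0.5, 30 epochs) is sized for minutes-scale CPU
training. A wider "full" preset records the clinical-scale selected
hyperparameters (batch 4, dropout 0.5, lr 1e-4, weight decay 1e-5, 4
stages); the printed 2×3×3×2 hyperparameter grid is available via
`seg_grid_configs`. Epoch count and early stopping are deliberately simple
(fixed epochs) since no stopping rule is prescribed for this stage.
Evaluation is the Dice similarity coefficient with TP/FP/FN pooled over a
subject's full stack, then averaged across subjects (normal-approximation
95% CI across subjects); cross-validation always splits by subject, never
by slice.

## Quantification

Per ROI, features are (segmented-pixel sum over the stack, age, sex) and
the target is the 3D-derived truth measure. The regressor is a
two-hidden-layer MLP (ReLU, Adam, dropout, early stop on a training-loss
plateau with patience 20); inputs and regression targets are standardized
with training-set statistics stored on the model. Hyperparameter selection
runs repeated k-fold CV (default 10 repeats × 10 folds) with subject-level,
seeded fold assignments shared across grid points; the score is the mean of
fold-level RMSEs (not pooled residuals — one documented reading of
"minimum RMSE" under repeated CV), and the winner is refit on the full
table. The full printed grid (5 batch sizes × 3 dropouts × 2 learning
rates × 2 weight decays × 4 first-layer × 5 second-layer sizes = 1200
configurations) is exposed by `full_mlp_grid()`; the default desk grid is a
2-point subset for runtime. Both CSF-volume and cortical-thickness
regressors are trained; downstream biomarkers consume only the 7 CSF
volumes.

## Biomarkers

* **DAT classifier / atrophy similarity.** Sigmoid-output MLP on the 7 CSF
  volumes + age + sex, labels CU = 0 / DAT = 1, selected by mean CV AUC.
  The continuous output in [0, 1] is the AD-specific atrophy similarity.
  The decision threshold maximizes Youden's J on development scores (the
  criterion behind an unspecified "optimal threshold"; ties break toward
  the lower threshold, and a score exactly at the threshold is labeled
  DAT).
* **W-scores.** Per ROI, OLS of volume on (1, age, sex) over a CU-only
  reference cohort; `sigma_CU` is the residual standard error with
  denominator n − 3 (a switch offers n − 1; "standard deviation of the
  residuals" admits both readings). `W = (V − E_CU)/sigma_CU`; scores are
  affine-equivariant and have exact zero mean on the fitting reference.
  `sigma_CU` below 1e−8 × the mean reference volume is rejected as a
  degenerate normative model.
* **Brain age / BAI.** An MLP regresses true brain age on the 7 CSF
  volumes + age + sex (minimum mean CV RMSE selection), and
  `BAI = predicted brain age − chronological age`. Two recorded
  assumptions: BAI is defined by that subtraction (the source never writes
  the formula), and chronological age is both an input feature and the BAI
  reference — a leakage-prone but faithful reading of the stated feature
  list; the phantom's generative brain age stands in for an external
  brain-age ground truth.

## Statistics

Dice uses the exact `2TP/(2TP+FP+FN)` formula; two empty masks are a 0/0
case returning 1 with a warning (configurable to an error), since ROI
absence in sparse stacks is routine. AUC uses midranks (equals the
normalized Mann–Whitney U, verified against exhaustive concordant-pair
counting); AUPRC is non-interpolated step integration. DeLong's test uses
placement values with midranks and a two-sided normal p-value; comparing a
score vector with itself returns p = 1 exactly. Pearson CIs use the Fisher
transform with `z ± z_crit/√(n−3)`. Bland–Altman reports
`mean(x−y) ± 1.96·SD(x−y)` (sample SD). Two-group comparisons screen each
group with Shapiro–Wilk at α = 0.05 to choose Student's t versus
Mann–Whitney U; categorical variables use chi-square; significance is read
at p < 0.05.

## Orchestration and reproducibility

`run_pipeline` executes simulate → preprocess → segment → quantify →
biomarkers → stats from a single `RunConfig`: one global seed feeds every
stage, a diagnosis-stratified test set (default ⅓) is held out before any
fit, and a JSON manifest records config, dev/test id sets, and SHA-256
checksums of every CSV output; a rerun with the identical config reproduces
identical checksums single-threaded. Stage toggles allow reusing a previous
run's segmentation model and regressors (the "measurement machinery") on a
fresh cohort — that is how the null-effect arm (c_dx = 0, no temporal-horn
gain) is scored without refitting the imaging stages.

Desk problem sizes used by the default study (and by
`scripts/acceptance.py`): 60 CU + 60 DAT subjects; stride 5 (≈12 slices per
subject); the FCN trained on every 2nd slice of 12 development subjects
(≈72 slices, 30 epochs); pipeline-internal CV reduced to 2×5-fold; an
isolated 40-subject CU reference cohort for W-scores. These sizes were
fixed once as the package's desk-scale experimental design.

## Numerical choices and edge cases

Convolutions run in float32 NHWC with im2col GEMMs; dense/MLP paths run in
float64. Gradients of every layer and of the assembled network are
finite-difference checked in the test suite. Adam uses the classic L2
penalty folded into the gradient. Degenerate inputs have defined behavior:
constant slices normalize to zeros (warning); empty head extents and
out-of-range labels raise; a stride exceeding the head extent returns the
single head-start slice with a logged warning; negative pixel sums are
rejected at prediction time.

## Known limitations

The phantom's simplicity means segmentation accuracy here exceeds anything
achievable on clinical data; absolute metric levels are not comparable to
clinical results — only the qualitative orderings (ventricles easiest,
sulcal eCSF hardest; CSF volumes better recovered than cortical thickness)
are expected to transfer. The coordinate-channel design assumes roughly
consistent head positioning, true for the phantom and for standard clinical
positioning but not for arbitrary orientations. The desk encoder is far
smaller than a clinical-scale Inception-style model; its contract (shapes,
skips, loss, reproducibility), not its capacity, is what the tests assert.
The classifier's near-perfect phantom AUC reflects the generative
separation of the default study conditions, not expected clinical
performance.
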
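# Methods

`cine4ch` implements a fully automated pipeline for four-chamber (4CH)
cine cardiac MR: per-frame semantic segmentation of the left and right
ventricles and atria, morphological cleanup, segmentation-quality metrics,
functional parameters (EDA/ESA/FAC), and BSA-indexed chamber-enlargement
detection with method-agreement statistics.  Because no patient data ships
with the package, a synthetic phantom generator reproduces the geometry
and dynamics of the study inputs with exact ground truth, and every stage
is validated against it.

## The phantom

A phantom subject is four non-overlapping quasi-elliptical blood pools on
a square raster (default 128x128 px over a 350 mm field of view, i.e.
2.734 mm/px; a 352x352 "acquisition-like" mode exercises the
down-sampling path).  Ventricles occupy the lower half, atria the upper
half, with a septal gap of at least 2 px enforced at render time.

Dynamics: a cine has `n_phases` = 20 frames over one heartbeat.  Each
chamber's analytic area follows

    area(p) = EDA * (1 - s * cf * w(p)),

where `s` = +1 for ventricles (contract) and -1 for atria (expand),
`cf` is the chamber's fractional excursion, and `w` is a piecewise
raised-cosine weight with `w(0) = 0` and a unique maximum `w(peak) = 1`
at the shared mid-cycle `peak_phase` (drawn from phases 8-12).  Phase 0
is therefore exactly end-diastole and `peak_phase` end-systole, matching
the first-phase EDA convention of the analysis stage.

Rendering selects, for each chamber, the `N` raster pixels with smallest
normalized elliptical distance to the chamber center, where
`N = round(area(p) / pixel_area)`.  This pins the rendered pixel count to
the analytic curve within a single pixel — naive inside-the-ellipse
rasterization can miss small ellipses by several percent — while the
region remains an ellipse up to pixelization.  Intensities caricature
bright-blood SSFP contrast in three levels (blood 200, myocardial rim 60,
background 30) plus additive Gaussian noise (default SD 10 on the 8-bit
scale).  The rim thickness is chamber-specific (LV 4 px, RV 3 px, LA 2 px,
RA 1 px), ordered as in the real heart, where the LV wall is much thicker
than the RV wall and atrial walls are thin.  This matters for training:
with vertical-flip augmentation a flipped ventricle occupies an atrium's
image position, so position alone cannot identify a chamber and wall
thickness/shape must carry the distinction, exactly as in real 4CH
images.  Aspect ratios differ per chamber for the same reason (LV 1.55,
RV 1.30, LA 1.10, RA 0.95, rows over columns).

Cohort sampling: sex is a fair coin; BSA is Gaussian (men 1.7 +/- 0.2,
women 1.5 +/- 0.15 m^2, clipped to [1.3, 2.2]), consistent with the kind
of cohort the enlargement cut-offs were reported for.  Each chamber's
BSA-indexed EDA is drawn uniformly in [0.65, 0.90] x cutoff for normal
subjects and [1.10, 1.35] x cutoff for enlarged ones — a controlled >= 20%
separation so that detection *should* succeed when segmentation is
accurate.  The cut-offs are the published sex-specific reference values
(LA 11.9/12.7, RV 13.6/12.6, RA 11.1/11.0 cm^2/m^2 for men/women); the LV
reference is volumetric (EDV/BSA) and unreachable from a single slice, so
the LV uses the ROC-derived area cut-off 23.8 cm^2/m^2 for both sexes.
Contraction fractions are physiologic: ventricles U(0.35, 0.55)
(ventricular FAC 35-55%), atria U(0.35, 0.50).  All randomness flows from
one integer seed per call; equal seeds give bit-identical cohorts.

What the phantom does *not* model: MR physics (bias fields, SSFP banding,
motion artifacts), anatomical contour shapes, through-plane motion,
arrhythmic cycles, or the correlated chamber dilatation of real disease.
Passing tests therefore show the pipeline's machinery is correct and
learnable on geometry of this scale — not that the network generalizes to
patient images.

## Pre-processing

Acquisition frames are center-cropped to square if needed, down-sampled
to 128x128 (desk scale: 64x64) by nearest-neighbour sampling with
pixel-center alignment (`src = floor((i + 0.5) * scale)`), and windowed
to 256 levels with each frame's own min/max, rounding half up.  Nearest
neighbour is used for masks too, so label codes survive resampling.  A
constant frame maps to zeros with a warning rather than an error, keeping
batch jobs alive.  Down-sampling precedes rescaling; with
nearest-neighbour sampling the order does not change any output value.

## Segmentation network and training

One multi-class U-Net segments all four chambers jointly (5-way softmax:
background + 4 chambers).  The architecture is the canonical
encoder-decoder: per stage two 3x3 same-padding convolutions, each
followed by instance normalization (per-sample, per-channel, with
learnable affine) and a leaky rectifier (negative slope 0.1); 2x2 max
pooling with filter count doubling from `base_filters`;
nearest-neighbour upsampling with skip concatenation on the way up; a
final 1x1 convolution.  Instance norm is the decisive stabilizer for the
short training budgets used here: without it, runs on some seeds learned
a chamber-size identity rule instead of the wall-thickness cue and
mis-assigned chambers at the cycle extremes.  Per-sample statistics keep
inference deterministic with no running averages.  Full-scale defaults
are depth 4 / 32 base filters at 128x128; the desk-scale configuration
used throughout the tests is depth 2 / 8 filters at 64x64.

The network and its backpropagation are implemented directly on numpy
(im2col + BLAS matmul, float32) — a deliberately small, dependency-free
runtime that trains the desk-scale model in about 1.5 minutes on one CPU
core.  A finite-difference gradient check and an overfit-one-sample test
guard the implementation.

Training follows the study protocol: mini-batch SGD with momentum 0.9,
batch size 10, weight decay 5e-4 on the kernels, per-pixel cross-entropy,
augmentation by a rotation drawn uniformly in +/-5 degrees (bilinear for
frames, nearest for masks) plus a probability-0.5 vertical flip, redrawn
per sample per epoch, and 100 epochs at full scale with a learning rate
of 0.002.  Model selection keeps the epoch with the best validation mean
foreground Dice.  Inputs are standardized per frame (zero mean, unit
variance), which conditions the short desk-scale runs far better than
[0,1] scaling.  Two fixed coordinate channels (row and column in [-1, 1],
describing the output grid and therefore never flipped or rotated with the
image) are appended to the input: a plain convolution stack can only infer
absolute position weakly from border padding, and without the explicit
position signal short runs sometimes latch onto chamber size instead of
wall thickness and mis-assign left/right chambers on unlucky seeds.
Appearance cues still carry the ventricle-vs-atrium distinction because
flip augmentation actively decouples it from position.

The desk-scale run compresses the protocol into 5 epochs (400 updates),
which needs a proportionally larger learning rate: peak 0.08 on a
warmup-cosine schedule (linear ramp over the first 10% of steps, cosine
decay to a tenth of the peak), with global gradient-norm clipping at 2.0
(early-step norms reach ~7; after a few steps clipping never binds).
Constant low rates (0.02 and below) leave some chamber unlearned within
the 400-step budget, and unclipped high rates occasionally diverge.  The
leaky rectifier (negative slope 0.1, rather than a hard ReLU) is the
default nonlinearity because hard rectifiers can die irreversibly at
these rates.
Everything is seeded; inference is deterministic, and a
saved checkpoint (config + weights in one `.npz`) reproduces predictions
bit-identically.

Open choices resolved here: the study's plural "segmentation models" is
read as one joint 5-class model (simpler and sufficient); the loss is
per-pixel cross-entropy; momentum coefficient 0.9; best-validation
checkpointing.

## Post-processing

Raw class maps can contain spurious blood-pool fragments.  Per chamber
class, independently: grayscale morphological closing with a
3-pixel-radius Euclidean disk, binarization at the Otsu threshold, and
retention of the largest 8-connected component (ties to the earliest
row-major component).  The Otsu cut is computed exactly over every split
between adjacent distinct values rather than on a binned histogram:
class maps are float-valued, and binning can misassign values that fall
between a bin center and its edge.  On 8-bit data the exact cut
reproduces the classic histogram method.  The four cleaned chambers are
composed into one label raster; a pixel claimed by several chambers goes
to the class with the higher closed score.  Each output chamber is a
single connected component or empty, and chamber regions are disjoint.

## Metrics

DSC = 2|X n Y| / (|X| + |Y|).  Two empty masks return 1 with a warning
(perfect agreement on absence); empty-vs-nonempty returns 0.

Mahalanobis distance: each mask becomes a point cloud of its contour
pixels (foreground with a background 4-neighbour; the filled variant is
available for sensitivity checks), and

    MD = sqrt((x_bar - y_bar)' S^-1 (x_bar - y_bar)),

with S the (n-1)-weighted pooled covariance of the two clouds — the
standard two-sample pooling.  Identical masks give 0; the measure is
invariant under common translations.  A singular pooled covariance
(collinear clouds) receives a Tikhonov ridge of 1e-6 * trace(S)/2 with a
warning; clouds of fewer than 3 points are an error.

## Functional analysis

Chamber areas are pixel counts times the squared pixel spacing (cm^2).
EDA is the area at phase 0; ESA the minimum over the cycle for ventricles
and the maximum for atria (ties to the earliest phase);
FAC = 100 * |EDA - ESA| / EDA.  The absolute value keeps atrial FAC
positive (a literal signed difference would be negative for atria, whose
ESA exceeds EDA).  Enlargement is called when EDA/BSA strictly exceeds
the chamber- and sex-specific cut-off.

## Statistics

Automated vs reference values are compared with Spearman's rho (mid-rank
ties, t-approximation p-value), Bland-Altman bias with 1.96 SD limits of
agreement (SD with n-1), and the one-way random single-measures
ICC(1,1) = (MSB - MSW) / (MSB + MSW) for k = 2, banded as excellent
(>= 0.75), good (0.60-0.74), moderate (0.40-0.59), poor (<= 0.39).
Negative ICC moment estimates are reported as-is and band as poor.
Detection of enlargement from the automated BSA-indexed EDA is scored by
ROC: trapezoidal AUC over all distinct-score thresholds (equal to the
normalized Mann-Whitney U with half-weight ties), Youden-J optimal
cut-off reported as the midpoint between the adjacent distinct scores,
and a DeLong 95% CI (placement-value variance, Wald interval clipped to
[0, 1]).

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
cohorts of 40/10/20 training/validation/test subjects (mirroring the
70/30/50-subject full protocol at reduced size), 64x64 frames, the
depth-2/8-filter network, 5 epochs.  One end-to-end run takes about two
minutes on a single CPU core.  Oracle comparisons (Dice vs set counting,
Mahalanobis vs a direct-formula route, ICC vs explicit sums of squares,
AUC vs exhaustive pairwise concordance) are exact or at 1e-10.  With a
fixed seed every stage — cohort, split, training, inference, statistics —
is reproducible bit-for-bit at a fixed thread count.

## Known limitations

- The phantom's simplicity means segmentation accuracy here is an upper
  bound on nothing; it demonstrates correctness of the pipeline, not
  clinical performance.
- Single-slice areas ignore through-plane volume changes; the LV
  enlargement call in particular substitutes an area cut-off for the
  volumetric reference.
- The numpy U-Net is CPU-bound and not intended for full-resolution,
  100-epoch training runs at scale (that configuration exists and works,
  but expect hours, not minutes).
- ICC variants other than one-way random single measures (e.g.
  two-way mixed) are out of scope, as are Hausdorff/surface distances and
  temporal regularization across phases.
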
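# cine4ch

Fully automated segmentation and functional assessment of the four cardiac
chambers in four-chamber (4CH) cine cardiac MR, end to end: synthetic
phantom cines with exact ground truth, a lightweight CPU U-Net, morphological
post-processing, Dice / Mahalanobis segmentation metrics, EDA/ESA/FAC
extraction, and BSA-indexed chamber-enlargement detection with full
method-agreement statistics.

## Who this is for

A 4CH cine shows the left and right ventricles and atria in a single plane
over one heartbeat (here 20 reconstructed phases).  Manually contouring all
four chambers in every phase is slow and subjective; this package automates
the measurement chain and quantifies how well the automated chain agrees
with a reference.  Because patient data cannot be redistributed, the package
ships a phantom generator that emulates the study inputs (128x128 8-bit
frames over a 350 mm field of view, 20 phases, ventricles contracting and
atria expanding towards mid-cycle) so every stage is testable with known
truth.

## The measurement chain

1. **Pre-process**: nearest-neighbour down-sampling from acquisition
   resolution (352x352) to 128x128 and per-frame min/max windowing to 256
   levels.
2. **Segment**: a U-Net maps each frame to five class probability maps
   (background + LV/LA/RV/RA).  Training follows the study protocol —
   SGD with momentum 0.9, batch size 10, weight decay 5e-4, +/-5 degree
   rotation and vertical-flip augmentation, best-validation-Dice model
   selection.  The network is implemented directly on numpy (im2col
   convolutions with hand-written backprop), so no deep-learning runtime is
   required.
3. **Post-process**: per chamber, grayscale closing with a 3-px-radius
   disk, Otsu binarization, largest connected component.
4. **Evaluate**: Dice similarity DSC = 2|X∩Y|/(|X|+|Y|) and the
   Mahalanobis distance between mask contours,
   MD = sqrt((x̄−ȳ)ᵀ S⁻¹ (x̄−ȳ)) with S the pooled (n−1) covariance.
5. **Analyze**: per chamber, EDA (first-phase area), ESA (ventricular
   minimum / atrial maximum), FAC = 100·|EDA−ESA|/EDA, and an enlargement
   call when EDA/BSA strictly exceeds the sex-specific cut-off
   (LA 11.9/12.7, RV 13.6/12.6, RA 11.1/11.0 cm²/m² for men/women; LV uses
   the ROC-derived area cut-off 23.8 cm²/m²).
6. **Report**: Spearman ρ, Bland-Altman bias and 1.96·SD limits, one-way
   random single-measures ICC(1,1) with the conventional bands, and an
   enlargement-detection ROC (trapezoidal AUC, DeLong 95% CI, Youden-J
   optimal cut-off).

See `docs/methods.md` for every modelling and numerical decision.

## Worked example

```python
import warnings
from cine4ch import PipelineConfig, run_pipeline

config = PipelineConfig(seed=11)      # 40/10/20 phantom subjects, 64x64,
with warnings.catch_warnings():       # depth-2 U-Net, 5 epochs (~2 min CPU)
    warnings.simplefilter("ignore")
    bundle = run_pipeline(config)

metrics = bundle["metrics"]
print(metrics.dsc.median(), metrics.md.median())
print(metrics.groupby("chamber").dsc.median())
```

Running `python examples/06_full_pipeline.py` (the same computation)
prints:

```
test cohort: 20 subjects, 1600 chamber-phase scores
median DSC 1.000; median Mahalanobis 0.000

per-chamber median DSC:
chamber
LA    1.0
LV    1.0
RA    1.0
RV    1.0

chamber quantity   rho   icc  icc_band  auc  optimal_cutoff
     LV  eda_cm2 0.999 1.000 excellent  1.0          23.948
     LA  eda_cm2 1.000 1.000 excellent  1.0          12.353
     RV  eda_cm2 1.000 1.000 excellent  1.0          13.321
     RA  eda_cm2 0.992 0.997 excellent  1.0          10.831
```

Read: on the 20 held-out phantom subjects, more than half of all
chamber-phase masks are pixel-perfect (median Dice 1.0 — the phantom's
clean geometry is far easier than patient data), the automated and
ground-truth EDA agree at ICC ~1, and the automated BSA-indexed EDA
separates enlarged from normal chambers perfectly (AUC 1.0), with
data-driven cut-offs landing near the reference values the cohort was
sampled around.  The
other scripts in `examples/` each demonstrate one capability (phantom
generation, preprocessing, training, metrics, functional statistics) in a
few seconds.

A thin CLI mirrors the stages: `cine4ch simulate | preprocess | train |
predict | postprocess | evaluate | analyze | report | run-all` (see
`cine4ch --help`).

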
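# Methods

This note documents the models and procedures implemented in `mr2sct`, the
parameter defaults and why they were chosen, the synthetic data the package
is exercised on, and the numerical decisions a maintainer should know about.

## Problem setting

A synthetic CT (sCT) is an HU-valued image predicted from MRI so that
radiotherapy dose calculation can proceed without a CT scan. T2-weighted MR
intensity is arbitrary, scanner-dependent, and maps to HU non-monotonically
(air and cortical bone are both dark; CSF is bright but near 0 HU), so the
prediction must use spatial context, not a per-pixel lookup. The workflow
has four stages: intensity standardization, CT/MR registration, a
convolutional MR→HU regressor, and tissue-stratified error evaluation.

## Synthetic phantoms

Real paired head CT/MR data cannot ship with the package, so all tests and
experiments run on generated phantoms (`phantom` module). A phantom is a
2-D axial head slice built from parametric shapes painted in a fixed order
(body soft tissue → subcutaneous fat → skull bone annulus → air cavities →
CSF ventricles; later tissues overwrite earlier ones). Each tissue carries
a CT mean/SD in HU and an MR mean/SD in arbitrary units:

| tissue | CT (HU)      | MR (a.u.)  |
|--------|--------------|------------|
| air    | −1000        | 30 ± 5     |
| soft   | 40 ± 10      | 500 ± 30   |
| fat    | −100 ± 10    | 180 ± 20   |
| bone   | 1200 ± 80    | 80 ± 15    |
| CSF    | 15 ± 5       | 950 ± 40   |

These values are chosen for qualitative fidelity to head anatomy at
T2-weighted contrast (fat partially suppressed, CSF bright, cortical bone
dark) and so the 300-HU bone/soft split is unambiguous; they are validated
structurally (bone > 300 HU, air ≤ −900 HU, soft classes in [−200, 300)).

The image-formation chain is: paint tissue means → blur with an acquisition
PSF (default FWHM 1.5 px, modelling partial-volume averaging; without it
the MR histogram has empty gaps between tissue modes that no clinical
histogram has) → add per-tissue Gaussian texture → for MR, multiply by a
smooth random bias field (default ±15%) and apply Rician noise (magnitude
of signal plus complex Gaussian, σ = 20 a.u. ≈ 4% of soft tissue); for CT,
add Gaussian noise (σ = 15 HU). Setting PSF, texture, bias and noise to
zero recovers the exact piecewise-constant analytic limit used by the
oracle tests. Cohorts draw per-subject anatomy jitter (±10% size, ±2 px
position) and a global MR gain in [0.75, 1.3] — the between-scan intensity
drift that standardization exists to remove — from per-subject seeds
spawned off one cohort seed. An optional rigid misalignment is applied to
the MR image only, with the ground truth stored for registration scoring.

What the phantoms do **not** model: realistic anatomy and tissue
heterogeneity, 3-D geometry, MR geometric distortion, metal or motion
artifacts, scanner-specific noise correlations. Passing tests therefore
demonstrate the correctness of the algorithms under their stated
assumptions, not clinical-grade sCT accuracy.

## Intensity standardization

Classical two-stage landmark matching. Landmarks are the foreground
percentiles `(p1, p10, …, p90, p99)`; the foreground is the Otsu threshold
of the MR image; percentiles use linear interpolation between order
statistics. Caps default to (1, 99) to suppress outlier tails; the interior
convention defaults to the nine decile boundaries and is configurable. The
standard scale is the per-position mean of the training subjects'
landmarks, with an isotonic (pool-adjacent-violators) repair that can only
trigger on numerical ties, since means of monotone vectors are monotone.
Application is the monotone piecewise-linear map sending own landmarks onto
standard landmarks; beyond the caps the boundary segments are extended
linearly rather than clamped, so background air keeps its contrast instead
of being pinned to the low-cap value (clamping was tried and breaks Otsu
masking of standardized images).

Round-trip behaviour: after standardization a subject's deciles equal the
standard scale up to percentile resolution on its foreground sample. The
concrete tolerance used in tests is the Freedman–Diaconis bin width of the
subject's standardized foreground histogram, with percentiles recomputed on
the fitting mask — re-running Otsu on the standardized image can flip a few
boundary pixels and move a decile that sits at a tissue-mode edge by more
than any bin width, which is mask instability rather than transform error.

## Registration

Simplified, self-contained 2-D implementation of the standard multimodal
design: Mattes-style mutual information on a joint intensity histogram
(32 bins default), a 3-level Gaussian pyramid (downsample by 2 per level),
rigid transform (rotation about the image centre + translation), and an
optional coarse B-spline free-form refinement.

Numerical choices that matter:

* **Overlap masking.** The metric is computed over the overlap domain only;
  filling out-of-field pixels with a constant measurably biases the joint
  histogram (the exact-valued fill sharpens a histogram peak and creates
  spurious optima).
* **Binning.** `mattes_mi` defaults to the Parzen cubic-B-spline window.
  The *optimizer* defaults to hard binning: with the smoothed kernel the
  self-similarity optimum of noisy images sits a fraction of a degree off
  identity (resampling interpolation denoises the moving image, which
  genuinely raises MI) — a known interpolation artifact. Hard binning
  recovers exact identity and passes the same 1 px / 1° recovery bounds.
* **Optimizer.** Powell direction-set search per pyramid level, preceded at
  the coarsest level by an exhaustive grid sweep over ±12° and ±16 px so
  large captures cannot fall into local optima. An adaptive stochastic
  finite-difference gradient variant (`method='asgd'`) is available; Powell
  proved markedly more reliable at desk scale and is the default. A final
  MI below a configurable floor flags the result low-confidence (e.g. when
  registering pure noise).
* **Deformable stage.** The rigid init is baked into a one-time resample;
  control-point displacements (spacing ≥ 4 px) are then optimized by
  L-BFGS-B with finite-difference gradients on
  `MI − w · bending_energy`. The dense field is the interpolating bicubic
  spline through the control displacements, which reproduces affine fields
  exactly, so the bending energy (analytic second derivatives of the
  spline, integrated over the pixel grid) has the correct affine null
  space. Default penalty weight 1e-4 keeps a ~3 px synthetic warp
  recoverable while a weight of 1e3 collapses the field to the rigid init.
* **Resampling** is bilinear everywhere; out-of-field fill is −1000 HU for
  CT and 0 for MR.

Expected accuracy (measured, 128×128 phantoms, defaults): median recovery
error ≈ 0.1 px and ≈ 0.5° over random misalignments up to 10° / 15 px.

## U-net regressor

The network is written directly in NumPy (convolution via shifted
tensor-contractions, analytic backprop for every layer, Adam optimizer);
gradient correctness is asserted against central differences in the test
suite. Architecture, with `depth` = number of resolution levels:

* contracting stage *i*: two 3×3 convolutions → batch norm → leaky ReLU
  (slope 0.01), channels `base·2^i`, then 2×2 max-pool (except the deepest
  level); dropout (rate 0.5) after the two deepest stages;
* expansive stage: 2×2 up-convolution halving the channels, concatenation
  with the equal-resolution contracting feature map, two 3×3 conv blocks;
* final 1×1 convolution to one HU channel.

Conv-layer count is `2·depth + 3·(depth−1) + 1 = 5·depth − 2`: 23 at the
full-size depth-5 / base-64 / 512-input configuration. The input size must
be divisible by `2^depth` so every pooling sees an even layer. Default
padding is `same` so output size equals input size; an `unpadded` mode with
centre-cropped skips exists for the classical valid-convolution variant.
Whole slices (not patches) are the training unit, and no data augmentation
is applied.

Targets are scaled linearly from [−1024, 2000] HU to [−1, 1] before the L2
loss and inverted at prediction; inputs are shifted/scaled to zero mean and
unit SD over the training set (constants stored in the trained model).
Training re-initializes the weights from the run seed, so a `TrainCfg`
fully determines the result. Prediction requires the MR to carry the
`standardized` units flag and records per-slice runtime.

Desk-scale defaults used throughout the tests and the acceptance script:
64×64 slices, depth 3, base 16 channels, 80 epochs, batch 4, Adam at 1e-3
— about a minute of single-core training for a 23-subject cohort. The
width/epoch choice is a convergence decision: with 8 base channels or 60
epochs the loss is still visibly decreasing and occasional seeds stall at
a poor optimum where soft-tissue error rivals bone error; at base 16 / 80
epochs runs converge consistently to ~20% of the no-skill baseline MAE.
The full-size configuration is constructed and introspected but not
trained.

## Evaluation

`MAE = (1/n) Σ |CT − sCT|` and `ME = (1/n) Σ (CT − sCT)` over the body
mask; positive ME means the sCT underestimates HU. The body mask is Otsu's
threshold on the true CT (guarded by a minimum 300 HU class separation so
an all-air slice errors out) followed by closing with a 3-px disk, hole
filling, and largest-connected-component selection. Bone is true CT > 300
HU within the body; soft tissue is the complement; masks always partition
the body and are derived from the true CT only. Metrics pool all of a
subject's pixels (per-subject, not per-slice). Cohort summaries report the
mean and the population SD (ddof = 0) across subjects. Expected identities
used as calibration checks: MAE ≥ |ME| always, and corrupting a CT with
Laplace(0, b) noise yields MAE = b.

## Pipeline

One config drives cohort generation → 23/10 random split (train size =
round(n × fraction)) → optional rigid registration (automatic when any pair
is misaligned; skippable) → standard-scale fit on training subjects only
(fingerprinted, and recorded in the trained model so leakage is auditable)
→ training → held-out prediction and cohort report, plus a no-skill
baseline report (training-mean HU everywhere). All stage seeds derive from
one master seed. A `train_only` misalignment scope supports the paired
misregistration experiment: training pairs carry a known misalignment while
held-out evaluation stays aligned, isolating the effect of corrupted
training correspondence — which raises held-out MAE substantially, the
expected signature of registration error in training data.

## Known limitations

* 2-D slices only; thin stacks are handled as lists, not volumes.
* The NumPy network is single-core and desk-scale; the full 512×512
  configuration is architecture-complete but impractical to train here.
* The B-spline stage optimizes at most a few hundred control parameters;
  it is a refinement stage, not a general diffeomorphic registration.
* Phantom experiments bound algorithmic correctness, not clinical accuracy;
  dosimetric evaluation is out of scope.
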
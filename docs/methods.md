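# Methods

## Quantification model

The package targets bolus-plus-constant-infusion (B/I) PET acquisitions in
which the bolus fraction (K_bol, expressed as minutes of infusion) is tuned
so that tissue and plasma activities reach a sustained equilibrium during
the scan.  At true equilibrium the total volume of distribution and the
non-displaceable binding potential are ratios of activity concentrations,

    V_T   = C_T / C_p,
    BP_ND = (C_T − C_ND) / C_ND,

where C_T is the voxel (tissue) activity, C_p the metabolite-corrected
venous plasma activity (a single scalar supplied as a text file — the lab
procedure that produces it is outside the package), and C_ND the mean
activity of a reference region assumed free of specific binding.  Both
maps are computed voxel-wise **in native space**; spatial normalisation is
applied to the finished parametric image, never before estimation.  The
pipeline records stage ordering in a provenance log so this can be audited.

Reference extraction follows threshold-then-mean semantics: the (generally
probabilistic, because it was warped) reference mask is binarised at 0.5
and the mean of surviving voxels is taken.  In cerebellar-reference mode
the mask is first multiplied voxel-wise by the subject's GM probability
segment and the 0.5 threshold is applied **after** the product (so a
0.9 × 0.6 = 0.54 voxel is kept, 0.9 × 0.55 = 0.495 is dropped).  Whether
the GM restriction should multiply probabilities or binarise first is
genuinely open; product-then-threshold was chosen because it uses the
probabilistic information of both masks and reduces to the plain threshold
when either mask is binary.  Pons-style reference regions skip the GM
restriction.

Normalised activity concentration (NAC) images — C_T divided by its mean
over the GM segment — serve as PET-to-PET registration targets.  They are
invariant under global rescaling of the input (dose, scanner calibration),
which is what makes them comparable across subjects.

## Equilibrium and motion QC

* The grey-matter TAC is normalised to its own mean over the expected
  equilibrium window.  A scan passes if every frame whose midpoint lies in
  the resting-state window deviates from the in-window mean by less than
  10 % (fractional).  The rule is applied per frame against the window
  mean; the deviation baseline is not specified more precisely by the
  protocol this mirrors, and the per-frame-vs-mean reading is the
  conservative one (a single outlying frame fails the scan).  Both the
  threshold and the window are configurable.
* Frames enter the analysis only if their overlap with the resting-state
  window exceeds 50 % of their own duration (strict inequality, window
  membership by interval overlap, not midpoint — coverage is a statement
  about acquisition time).
* Motion QC passes only if all translations are below 3 mm and all
  rotations below 3.5° relative to the first frame — thresholds matched to
  the spatial resolution of the data the workflow is designed for.

## Synthetic phantom

The phantom is the package's ground-truth surface, not a realistic brain:

* **Geometry.**  Nested ellipsoids on a 48³ grid at 2.5 mm (defaults):
  a cortical-GM shell, an inferior reference region (GM-like, BP_ND = 0),
  a WM core, a central CSF space and up to six deep-GM nuclei with
  distinct binding potentials (2.0, 3.0, 1.5, …).  48³ is large enough for
  a radius-4 correlation window and 2.5 mm morphology yet small enough for
  seconds-scale tests.
* **Truth encoding.**  C_eq = cp · V_T per region with
  V_T = V_T,ref (1 + BP_ND), cp = 2 kBq/mL and V_T,ref = 2 mL/mL, so
  BP_ND = C_eq/C_eq,ref − 1 holds by construction and the ratio method is
  exactly invertible on noiseless data.
* **Kinetics.**  Mono-exponential approach to equilibrium,
  C(t) = C_eq (1 − e^(−t/τ)), with τ drawn per region around
  400 s (GM), 550 s (WM), 150 s (CSF) ±15 %.  The bolus peak is not
  modelled: quantification only uses the plateau, and the QC rules need a
  pre-equilibrium rise plus a plateau, which this provides.  K_bol is
  carried as acquisition metadata only.
* **Noise.**  Additive Gaussian with sd = f · C_eq / √(duration/300 s) — a
  count-statistics proxy in which longer frames are less noisy; voxel noise
  in OSEM-reconstructed images is approximately Gaussian.  Noise scales
  with local C_eq, so background air stays at zero; tests that need
  background texture add their own.
* **Motion.**  Optional per-frame rigid motion (mm/degrees, relative to
  frame 0), applied by resampling the frame through the inverse rigid map.
* **Deformations.**  Gaussian-smoothed white-noise vector fields rescaled
  to a chosen peak displacement (default 3 mm at 10 mm smoothness), plus an
  optional sub-degree/sub-mm random affine folded into the dense field.
  The generator rejects folding maps (finite-difference Jacobian
  determinant ≤ 0) and computes the inverse by fixed-point iteration,
  raising if the forward∘inverse residual exceeds 0.1 voxel.  Storing the
  affine jitter inside the dense field keeps application and inversion on
  a single displacement-field code path; the affine part is retained as
  metadata.

What passing phantom tests do **not** show: realistic anatomy, scanner
point-spread, attenuation/scatter artefacts, plasma measurement error, or
kinetic heterogeneity within regions.  Conclusions about those require
real data.

## Numerical choices

* **Resampling** is pull-back (iterate target voxels, sample source at the
  transformed world coordinate), trilinear or nearest, zero fill outside
  the field of view (PET background is air).  Trilinear resampling of a
  binary mask intentionally yields fractional border values — downstream
  code treats such masks probabilistically.
* **Smoothing** uses per-axis σ = FWHM/(2√(2 ln 2))/voxel, mirror boundary
  (approximate mass conservation near edges); FWHM 0 is the identity.
* **Morphology** uses a voxelised world-space ball: integer offsets with
  ‖offset · voxel_mm‖ ≤ radius.  At 2.5 mm radius on 1.25 mm voxels this
  is the 33-voxel ball.  A radius below half the largest voxel dimension
  degenerates to a single voxel and triggers a warning.
* **Rigid estimation** minimises masked MSE over six parameters
  (translations mm, intrinsic roll-pitch-yaw degrees about the fixed
  image's centre of mass) with a two-level multi-resolution Powell search.
  The objective resamples through cubic splines with precomputed
  coefficients: trilinear resampling blurs the moving image, which biases
  an MSE objective toward the identity whenever the moving frame was
  itself produced by interpolation; cubic interpolation keeps the minimum
  at the true alignment.  Final image resampling remains trilinear.  On
  non-convergence the best-so-far transform is returned with a warning.
  Nonlinear transform *estimation* is deliberately out of scope — the
  package applies externally estimated displacement fields (or
  phantom-provided truth); partial-volume correction is a pluggable no-op
  interface for the same reason.
* **Similarity metrics.**  MI uses a 32 × 32 joint histogram with
  equal-width bins over each image's masked range (32 is a common
  registration default; configurable), reported in nats.  Local CC is the
  mean over masked voxels of the squared window correlation in a cubic
  (2r+1)³ window, r = 4 voxels, windows clipped at volume edges,
  zero-variance windows contributing 0 — computed with box-filter running
  sums that are algebraically identical to the explicit window loop.
  gSSim evaluates the SSIM formula once on whole-volume means, variances
  and covariance with C1 = (0.01 L)², C2 = (0.03 L)², L the larger of the
  two images' dynamic ranges.  MSE is the masked voxel-wise mean squared
  difference.
* **Statistics.**  The Wilcoxon signed-rank test drops zero differences,
  assigns mid-ranks to ties and enumerates all 2ⁿ sign patterns for
  n ≤ 20 (exact two-sided p; typical region-by-subject designs fit), with
  a tie-corrected normal approximation above.  Paired comparisons use
  two-sided paired t tests with **no** multiple-comparison correction by
  default, mirroring the reporting convention of the workflow this package
  supports; `holm_correction` is available for users who want adjusted
  values.
* **Warp effect.**  δ = (x_w − x_n)/x_n · 100 on probability-weighted ROI
  means (weights = atlas ROI × GM probability in each space).  The
  weighted-mean convention (validation) and the 0.5-threshold convention
  (reference extraction) deliberately coexist; which applies is a per-call
  choice, since the two extraction styles serve different steps of the
  workflow and are not interchangeable.

## Problem sizes

Tests and the acceptance script run the phantom study at 48³ voxels
(32³ for registration-heavy pipeline tests), 3–20 frames, 10 subjects in
the registration benchmark and 1,000 randomized cases per QC rule — sizes
chosen so the full suite completes in a few minutes while every statistic
retains enough samples to be meaningful.

## Known limitations

* The rigid estimator is a plain MSE optimiser; it assumes comparable
  intensity scales between frames and can fall into local minima for
  displacements far beyond the multi-resolution capture range (several
  voxels).  It is a frame-realignment tool, not a general-purpose
  registrar.
* The deformation generator produces smooth, small-amplitude fields; it
  does not emulate topology-preserving-but-extreme anatomical variability.
* Exact BP_ND recovery holds on the equilibrium plateau; frames taken
  during the approach phase bias C_T low by a factor (1 − e^(−t/τ)), and
  no kinetic correction is attempted (the QC rules exist to exclude such
  frames).
* Literature test–retest variability bands for the two tracer families
  this workflow targets (σ ≈ 4.0–16.0 % and 3.9–9.5 %) are stored as
  reference constants for report context only; the package never computes
  them.
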
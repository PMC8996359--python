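# receptormap

Equilibrium quantification and template tooling for **bolus-plus-constant-infusion
(B/I) brain PET**, with simultaneous-PET/MR workflows in mind.

When a tracer is given as a bolus followed by a constant infusion, tissue and
plasma activity reach a sustained equilibrium, and the kinetic quantities that
normally require dynamic modelling reduce to simple ratios of activity
concentrations:

```
V_T   = C_T / C_p            (total volume of distribution, mL/mL)
BP_ND = (C_T − C_ND) / C_ND  (non-displaceable binding potential)
```

with `C_T` the tissue activity, `C_p` the metabolite-corrected venous plasma
activity and `C_ND` the activity of a reference region devoid of specific
binding (e.g. cerebellar grey matter for mGluR5 tracers, pons for GABA_A
tracers).  The package implements the desk-side half of such a workflow:

* **TAC quality control** — grey-matter time-activity curves normalised to the
  equilibrium window; scans are accepted only if every frame in the
  resting-state window deviates from the window mean by less than 10 %, frames
  qualify only if they cover more than 50 % of the resting-state interval, and
  scans with motion of 3 mm / 3.5° or more are rejected.
* **Preprocessing** — rigid frame-to-frame motion correction, world-space
  Gaussian smoothing (default 2.5 mm FWHM), frame averaging, spherical-kernel
  mask morphology, and application of affine or dense-displacement transforms
  (pull-back convention, trilinear or nearest).
* **Parametric mapping** — voxel-wise `V_T`, `BP_ND` and GM-normalised
  activity (NAC) maps, computed strictly in native space; reference values use
  threshold-at-0.5-then-mean mask semantics, optionally after multiplying the
  warped reference mask with the subject's GM segment.
* **Template construction** — voxel-wise averaging of warped subject maps;
  parametric templates are masked with a brain mask dilated by a 2.5 mm
  spherical kernel, NAC templates stay unmasked.
* **Validation** — warp-effect percent error `δ = (x_w − x_n)/x_n × 100` on
  probability-weighted ROI means, exact two-sided Wilcoxon signed-rank tests,
  and a PET-to-PET registration benchmark with four similarity metrics:
  mutual information (32-bin, nats), local cross-correlation (radius 4
  voxels), a global structural similarity index and masked MSE, compared with
  paired t tests (no multiple-comparison correction).
* **Synthetic phantom** — a nested-ellipsoid brain with known per-region
  `BP_ND`/`V_T`, mono-exponential approach to equilibrium, duration-scaled
  Gaussian noise, per-frame rigid motion and smooth invertible deformations,
  so every stage has a ground-truth test surface.

## Worked example

```python
import numpy as np
from receptormap import (FrameSchedule, average_frames, compute_bpnd,
                         make_phantom, reference_value, roi_mean,
                         simulate_dynamic)
from receptormap.imageio import Image3D

phantom = make_phantom(seed=1)                      # 48³ voxels at 2.5 mm
schedule = FrameSchedule.uniform(20, 300.0)         # 20 × 5 min frames
dyn = simulate_dynamic(phantom, schedule, noise_sd_frac=0.05, seed=1)

mean_pet = average_frames(dyn, [15, 16, 17, 18, 19])   # plateau frames
ref = reference_value(mean_pet, phantom.reference_mask, phantom.gm_prob)
bp = compute_bpnd(mean_pet, ref)

print(f"C_ND = {ref.c_nd:.3f} kBq/mL from {ref.n_voxels} voxels")
bp_img = Image3D(bp.data, bp.affine, units="")
for r in phantom.regions:
    est = roi_mean(bp_img, phantom.region_mask(r.label))
    print(f"{r.name:12s}  true BP_ND = {r.true_bpnd:5.2f}   est = {est:6.3f}")
```

Output:

```
C_ND = 3.997 kBq/mL from 334 voxels
cortical_gm   true BP_ND =  1.00   est =  1.001
reference     true BP_ND =  0.00   est =  0.000
white_matter  true BP_ND =  0.25   est =  0.251
csf           true BP_ND = -0.60   est = -0.600
nucleus_1     true BP_ND =  2.00   est =  2.002
nucleus_2     true BP_ND =  3.00   est =  2.989
```

The reference estimate sits within noise of the true non-displaceable
concentration (cp·V_T,ref = 4 kBq/mL), and every regional binding potential is
recovered to well under 1 % despite 5 % frame noise, because averaging five
plateau frames and taking regional means suppresses the voxel noise.

A command-line interface mirrors the library
(`receptormap simulate | tac-qc | moco | smooth | morph | warp | param |
template | warp-check | reg-bench | run`); see `receptormap --help`.

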
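"""Equilibrium ratio-method parametric imaging (V_T, BP_ND, NAC).

At sustained bolus-infusion equilibrium the total volume of distribution
and the non-displaceable binding potential reduce to simple ratios of
activity concentrations:

    V_T   = C_T / C_p
    BP_ND = (C_T - C_ND) / C_ND

with C_T the tissue activity, C_p the metabolite-corrected plasma activity
and C_ND the non-displaceable (reference-region) tissue activity.  C_ND is
extracted with 0.5-threshold-then-mean semantics: the (possibly
probabilistic) reference mask — optionally multiplied voxel-wise by a GM
segment to exclude non-GM voxels — is thresholded at 0.5 and the mean of
the surviving voxels is taken.  Estimation is performed strictly in native
space; any warping to a standard space happens afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from receptormap.imageio import Image3D, PlasmaValue, ProbMask


@dataclass
class ParametricImage:
    """A voxel-wise parametric map with provenance.

    ``kind`` is ``VT`` (mL/mL), ``BPND`` (unitless) or ``NAC``
    (GM-normalised activity concentration, unitless).
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("VT", "BPND", "NAC"):
            raise ValueError("kind must be VT, BPND or NAC")
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def as_image(self) -> Image3D:
        return Image3D(self.data, self.affine, units="")


@dataclass
class ReferenceValue:
    """Non-displaceable concentration C_ND with extraction provenance."""

    c_nd: float
    n_voxels: int
    mask_provenance: str = "reference mask, threshold 0.5"

    def __post_init__(self) -> None:
        if not np.isfinite(self.c_nd) or self.c_nd <= 0:
            raise ValueError("C_ND must be positive and finite")
        if self.n_voxels < 1:
            raise ValueError("reference extraction used no voxels")


def roi_mean(image: Image3D, mask: ProbMask) -> float:
    """Mean of image voxels where the mask exceeds 0.5.

    Mirrors the threshold-binarise-then-mean extraction convention: the
    mask is binarised at 0.5 and the mean is taken over surviving voxels,
    which drops low-probability border voxels from the statistic.
    """
    if mask.data.shape != image.data.shape:
        raise ValueError("mask grid does not match the image grid")
    sel = mask.data > 0.5
    if not np.any(sel):
        raise ValueError("mask is empty after thresholding at 0.5")
    return float(image.data[sel].mean())


def reference_value(mean_pet: Image3D, ref_mask: ProbMask,
                    gm_segment: ProbMask | None = None) -> ReferenceValue:
    """Extract C_ND from the mean equilibrium frame.

    When a GM segment is supplied (cerebellar-reference mode) the effective
    mask is the voxel-wise product ref * gm, thresholded at 0.5 after the
    multiplication; without one (pons mode) the reference mask alone is
    used.
    """
    if gm_segment is not None:
        if gm_segment.data.shape != ref_mask.data.shape:
            raise ValueError("GM segment grid does not match the reference mask")
        effective = ProbMask(ref_mask.data * gm_segment.data, ref_mask.affine)
        provenance = "reference mask x GM segment, product > 0.5"
    else:
        effective = ref_mask
        provenance = "reference mask, threshold 0.5"
    sel = effective.data > 0.5
    if not np.any(sel):
        raise ValueError("effective reference mask empty after thresholding")
    value = float(mean_pet.data[sel].mean())
    return ReferenceValue(c_nd=value, n_voxels=int(sel.sum()),
                          mask_provenance=provenance)


def compute_vt(mean_pet: Image3D, plasma: PlasmaValue) -> ParametricImage:
    """Voxel-wise total volume of distribution V_T = C_T / C_p."""
    return ParametricImage(mean_pet.data / plasma.cp, mean_pet.affine, kind="VT",
                           provenance={"cp_kBq_mL": plasma.cp})


def compute_bpnd(mean_pet: Image3D, reference: ReferenceValue) -> ParametricImage:
    """Voxel-wise binding potential BP_ND = (C_T - C_ND) / C_ND."""
    data = (mean_pet.data - reference.c_nd) / reference.c_nd
    return ParametricImage(data, mean_pet.affine, kind="BPND",
                           provenance={"c_nd_kBq_mL": reference.c_nd,
                                       "n_ref_voxels": reference.n_voxels,
                                       "ref_mask": reference.mask_provenance})


def normalize_activity(mean_pet: Image3D, gm_mask: ProbMask) -> ParametricImage:
    """GM-normalised activity concentration: C_T / mean(C_T in GM).

    The GM mean of the output equals 1 by construction, and the result is
    invariant under global rescaling of the input — the property that makes
    these images usable as registration templates across subjects.
    """
    gm_mean = roi_mean(mean_pet, gm_mask)
    if gm_mean == 0:
        raise ValueError("GM mean activity is zero; cannot normalise")
    return ParametricImage(mean_pet.data / gm_mean, mean_pet.affine, kind="NAC",
                           provenance={"gm_mean_kBq_mL": gm_mean})
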
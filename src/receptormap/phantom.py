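"""Synthetic dynamic-PET phantom with known kinetic and spatial truth.

The phantom emulates the aspects of a bolus-plus-constant-infusion brain
acquisition that the processing pipeline actually consumes:

* nested-ellipsoid regions with GM/WM/CSF-like composition, a reference
  region free of specific binding (true BP_ND = 0) and GM-like target
  regions with known BP_ND / V_T;
* frame-wise kinetics as a mono-exponential approach to the equilibrium
  plateau, C(t) = C_eq (1 - exp(-t/tau)) — the bolus peak is not modelled
  because only the plateau enters quantification, while the approach phase
  exercises the equilibrium QC rules;
* Gaussian voxel noise with variance inversely proportional to frame
  duration, a count-statistics proxy for reconstructed OSEM images;
* optional per-frame rigid motion;
* smooth invertible deformation fields with a known inverse, standing in
  for a nonlinear normalisation estimated by an external tool.

Per-voxel equilibrium activity encodes the truth: C_eq = cp * V_T, and for
any region BP_ND = C_eq / C_eq,ref - 1 with C_eq,ref the reference-region
(non-displaceable) concentration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from receptormap.imageio import (
    FrameSchedule,
    Image3D,
    Image4D,
    PlasmaValue,
    ProbMask,
    write_image,
)
from receptormap.preprocess import RigidTransform, Transform, apply_transform


@dataclass
class RegionSpec:
    label: int
    name: str
    true_bpnd: float
    true_vt: float
    c_eq: float      # kBq/mL
    tau_s: float     # time constant of the approach to equilibrium
    tissue: str      # gm | wm | csf | none


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic subject."""

    labels: np.ndarray
    affine: np.ndarray
    regions: list
    cp: PlasmaValue
    reference_label: int
    kbol_min: float = 46.2   # bolus fraction in minutes of infusion; metadata only

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def _region_map(self, attr: str, background: float = 0.0) -> np.ndarray:
        out = np.full(self.labels.shape, background, dtype=float)
        for r in self.regions:
            out[self.labels == r.label] = getattr(r, attr)
        return out

    @property
    def c_eq_map(self) -> np.ndarray:
        return self._region_map("c_eq")

    @property
    def tau_map(self) -> np.ndarray:
        return self._region_map("tau_s", background=1.0)

    @property
    def true_vt_map(self) -> np.ndarray:
        return self._region_map("true_vt")

    @property
    def true_bpnd_map(self) -> np.ndarray:
        """Per-voxel BP_ND truth; background carries 0 by convention."""
        return self._region_map("true_bpnd")

    @property
    def c_nd(self) -> float:
        """Reference-region (non-displaceable) equilibrium concentration."""
        return self.region(self.reference_label).c_eq

    def region(self, label: int) -> RegionSpec:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(f"no region with label {label}")

    def _tissue_prob(self, tissue: str) -> ProbMask:
        labels = [r.label for r in self.regions if r.tissue == tissue]
        data = np.isin(self.labels, labels).astype(float)
        return ProbMask(data, self.affine)

    @property
    def gm_prob(self) -> ProbMask:
        return self._tissue_prob("gm")

    @property
    def wm_prob(self) -> ProbMask:
        return self._tissue_prob("wm")

    @property
    def csf_prob(self) -> ProbMask:
        return self._tissue_prob("csf")

    @property
    def brain_mask(self) -> ProbMask:
        return ProbMask((self.labels > 0).astype(float), self.affine)

    @property
    def reference_mask(self) -> ProbMask:
        return ProbMask((self.labels == self.reference_label).astype(float), self.affine)

    def region_mask(self, label: int) -> ProbMask:
        return ProbMask((self.labels == label).astype(float), self.affine)

    def manifest(self) -> dict:
        return {
            "cp_kBq_mL": self.cp.cp,
            "kbol_min": self.kbol_min,
            "reference_label": self.reference_label,
            "regions": [
                {
                    "label": r.label,
                    "name": r.name,
                    "true_bpnd": r.true_bpnd,
                    "true_vt": r.true_vt,
                    "c_eq": r.c_eq,
                    "tau_s": r.tau_s,
                    "tissue": r.tissue,
                }
                for r in self.regions
            ],
        }

    def write(self, outdir) -> Path:
        """Write label map, tissue probabilities and a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_image(Image3D(self.labels.astype(float), self.affine, units=""),
                    outdir / "labels.nii.gz")
        write_image(self.gm_prob, outdir / "gm_prob.nii.gz")
        write_image(self.wm_prob, outdir / "wm_prob.nii.gz")
        write_image(self.csf_prob, outdir / "csf_prob.nii.gz")
        write_image(self.brain_mask, outdir / "brain_mask.nii.gz")
        write_image(self.reference_mask, outdir / "reference_mask.nii.gz")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=1)
        return outdir


def _ellipsoid(shape, center_frac, semi_frac) -> np.ndarray:
    """Boolean ellipsoid; center and semi-axes as fractions of the grid size."""
    shape = np.asarray(shape, dtype=float)
    grids = np.indices([int(s) for s in shape]).astype(float)
    center = center_frac * (shape - 1)
    semi = semi_frac * shape
    d2 = sum(((grids[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return d2 <= 1.0


# target-region binding potentials cycled through as n_regions grows
_TARGET_BP = (2.0, 3.0, 1.5, 2.5, 0.8, 1.2)


def make_phantom(shape=(48, 48, 48), voxel_mm=2.5, n_regions=6, seed=0,
                 cp_kbq_ml=2.0, vt_ref=2.0) -> PhantomTruth:
    """Build a nested-ellipsoid brain phantom with known equilibrium truth.

    Regions (labels): 1 = cortical-GM shell, 2 = reference region (GM-like,
    BP_ND = 0), 3 = WM core, 4 = central CSF, 5+ = deep GM target nuclei
    with distinct BP_ND.  ``n_regions`` counts non-background regions and
    must be at least 3 (GM target, reference, and one more tissue).

    Equilibrium activities follow C_eq = cp * V_T with
    V_T = V_T,ref * (1 + BP_ND), so BP_ND = C_eq/C_eq,ref - 1 holds by
    construction and the reference region carries BP_ND = 0.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 16:
        raise ValueError("phantom shape must be at least 16 voxels per axis")
    if n_regions < 3:
        raise ValueError("need at least 3 regions (GM target, reference, plus one)")
    if n_regions > 4 + len(_TARGET_BP):
        raise ValueError(f"at most {4 + len(_TARGET_BP)} regions supported")

    rng = np.random.default_rng(seed)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0  # centred world origin

    labels = np.zeros(shape, dtype=np.int32)
    brain = _ellipsoid(shape, np.array([0.5, 0.5, 0.5]), np.array([0.40, 0.42, 0.38]))
    labels[brain] = 1  # GM shell by default

    # reference region: off-centre inferior ellipsoid (cerebellum-like)
    ref = _ellipsoid(shape, np.array([0.5, 0.32, 0.30]), np.array([0.10, 0.09, 0.08]))
    labels[brain & ref] = 2

    region_defs = [(1, "cortical_gm", 1.0, "gm"), (2, "reference", 0.0, "gm")]

    if n_regions >= 3:  # WM core
        wm = _ellipsoid(shape, np.array([0.5, 0.54, 0.55]), np.array([0.22, 0.24, 0.20]))
        labels[brain & wm & ~ref] = 3
        region_defs.append((3, "white_matter", 0.25, "wm"))
    if n_regions >= 4:  # central CSF (ventricle-like)
        csf = _ellipsoid(shape, np.array([0.5, 0.54, 0.55]), np.array([0.07, 0.09, 0.06]))
        labels[brain & csf] = 4
        region_defs.append((4, "csf", -0.6, "csf"))
    # deep GM nuclei, placed symmetrically off the midline inside the WM core
    nuclei_centers = [
        np.array([0.36, 0.54, 0.55]), np.array([0.64, 0.54, 0.55]),
        np.array([0.40, 0.66, 0.52]), np.array([0.60, 0.66, 0.52]),
        np.array([0.40, 0.44, 0.60]), np.array([0.60, 0.44, 0.60]),
    ]
    for k in range(n_regions - 4):
        lbl = 5 + k
        nucleus = _ellipsoid(shape, nuclei_centers[k], np.array([0.055, 0.06, 0.05]))
        labels[(labels == 3) & nucleus] = lbl
        region_defs.append((lbl, f"nucleus_{k + 1}", _TARGET_BP[k], "gm"))

    cp = PlasmaValue(cp_kbq_ml)
    # tau drawn per region from a realistic 200-600 s band (deterministic per seed)
    taus = {"gm": 400.0, "wm": 550.0, "csf": 150.0}
    regions = []
    for lbl, name, bp, tissue in region_defs:
        if not np.any(labels == lbl):
            raise ValueError(f"shape {shape} too small to place region {name}")
        vt = vt_ref * (1.0 + bp)
        tau = taus[tissue] * float(rng.uniform(0.85, 1.15))
        regions.append(RegionSpec(lbl, name, bp, vt, cp.cp * vt, tau, tissue))

    return PhantomTruth(labels=labels, affine=affine, regions=regions,
                        cp=cp, reference_label=2)


def simulate_dynamic(truth: PhantomTruth, schedule: FrameSchedule,
                     noise_sd_frac: float = 0.0, motion_params=None,
                     seed: int = 0) -> Image4D:
    """Simulate a dynamic acquisition of the phantom.

    Frame value per voxel: ``C_eq * (1 - exp(-t_mid/tau))`` plus Gaussian
    noise with sd ``noise_sd_frac * C_eq / sqrt(duration_s / 300)`` — noise
    variance scales inversely with frame duration, as for count-limited
    reconstructions.  ``motion_params`` is an optional (n_frames, 6) array
    of (tx, ty, tz [mm], roll, pitch, yaw [deg]) rigid motion per frame,
    relative to frame 0.  Deterministic for fixed seed.
    """
    if noise_sd_frac < 0:
        raise ValueError("noise_sd_frac must be non-negative")
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    rng = np.random.default_rng(seed)
    c_eq = truth.c_eq_map
    tau = truth.tau_map
    t_mid = schedule.t_mid_s

    frames = np.empty(truth.labels.shape + (len(schedule),), dtype=float)
    if motion_params is not None:
        motion_params = np.asarray(motion_params, dtype=float)
        if motion_params.shape != (len(schedule), 6):
            raise ValueError("motion_params must have shape (n_frames, 6)")

    shape = truth.labels.shape
    center_world = (truth.affine @ np.append((np.asarray(shape) - 1) / 2.0, 1.0))[:3]
    for i in range(len(schedule)):
        base = c_eq * (1.0 - np.exp(-t_mid[i] / tau))
        if noise_sd_frac > 0:
            sd = noise_sd_frac * c_eq / np.sqrt(schedule.duration_s[i] / 300.0)
            base = base + rng.normal(size=base.shape) * sd
        if motion_params is not None and np.any(motion_params[i] != 0):
            rigid = RigidTransform(*motion_params[i], center=center_world)
            # the object moves by `rigid`: the observed frame samples the
            # resting object at the pre-motion position (pull-back of the inverse)
            img = apply_transform(
                Image3D(base, truth.affine),
                Transform.from_rigid(rigid.inverse()),
                target_affine=truth.affine, target_shape=shape,
            )
            base = img.data
        frames[..., i] = base
    return Image4D(frames, truth.affine, schedule)


# --------------------------------------------------------------------------
# ground-truth deformations
# --------------------------------------------------------------------------

@dataclass
class DeformationTruth:
    """A smooth invertible deformation with a numerically exact inverse.

    ``displacement`` holds the forward mapping phi(x) = x + u(x) (native ->
    warped world coordinates, mm, one vector per voxel of the reference
    grid); ``inverse_displacement`` holds v with phi(x + v(x)) ~= x.  Any
    small random affine jitter is folded into both dense fields so that a
    single displacement-field path applies and inverts the transform;
    ``affine_part`` records the jitter for provenance.
    """

    affine_part: np.ndarray
    displacement: np.ndarray
    inverse_displacement: np.ndarray
    affine: np.ndarray           # voxel-to-world of the reference grid
    max_residual_mm: float = 0.0

    def transform_to_native(self) -> Transform:
        """Pull-back transform that resamples a warped-space image into native space."""
        return Transform.from_displacement(self.displacement, self.affine,
                                           direction="inverse")

    def transform_to_warped(self) -> Transform:
        """Pull-back transform that resamples a native-space image into warped space."""
        return Transform.from_displacement(self.inverse_displacement, self.affine,
                                           direction="forward")


def _sample_field(field: np.ndarray, coords_vox: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a (x,y,z,3) field at fractional voxel coords."""
    out = np.empty(coords_vox.shape[1:] + (3,), dtype=float)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(field[..., c], coords_vox,
                                              order=1, mode="nearest")
    return out


def make_deformation(shape=(48, 48, 48), voxel_mm=2.5, amplitude_mm=3.0,
                     smoothness_mm=10.0, seed=0, affine_jitter=True) -> DeformationTruth:
    """Generate a smooth random deformation scaled to a peak displacement.

    The nonlinear part is a Gaussian-smoothed white-noise vector field
    rescaled so that max |u| = ``amplitude_mm``; a small random affine
    (sub-degree rotation, sub-mm translation) is added when
    ``affine_jitter`` is set.  The inverse is computed by fixed-point
    iteration.  Raises if the map folds (non-positive Jacobian determinant
    anywhere) or if the inverse residual exceeds 0.1 voxel.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be non-negative")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0

    u = np.zeros(shape + (3,), dtype=float)
    if amplitude_mm > 0:
        sigma_vox = smoothness_mm / voxel_mm
        for c in range(3):
            u[..., c] = ndimage.gaussian_filter(rng.normal(size=shape), sigma_vox,
                                                mode="constant")
        peak = np.max(np.linalg.norm(u, axis=-1))
        if peak > 0:
            u *= amplitude_mm / peak

    affine_part = np.eye(4)
    if affine_jitter and amplitude_mm > 0:
        ang = np.deg2rad(rng.uniform(-0.3, 0.3))
        ca, sa = np.cos(ang), np.sin(ang)
        rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        affine_part[:3, :3] = rot
        affine_part[:3, 3] = rng.uniform(-0.3, 0.3, size=3)
        # fold the jitter into the dense field: phi(x) = A x + u_s(x)
        idx = np.indices(shape, dtype=float)
        world = np.einsum("ij,j...->i...", affine[:3, :3], idx) + affine[:3, 3][:, None, None, None]
        aff_disp = (np.einsum("ij,j...->i...", affine_part[:3, :3] - np.eye(3), world)
                    + affine_part[:3, 3][:, None, None, None])
        u = u + np.moveaxis(aff_disp, 0, -1)

    _check_no_folding(u, voxel_mm)

    # fixed-point inverse: v(x) = -u(x + v(x)), iterated on the grid
    inv_affine = np.linalg.inv(affine)
    idx = np.indices(shape, dtype=float)
    world = np.einsum("ij,j...->i...", affine[:3, :3], idx) + affine[:3, 3][:, None, None, None]
    world = np.moveaxis(world, 0, -1)  # (x,y,z,3)
    v = np.zeros_like(u)
    for _ in range(100):
        pts = world + v
        vox = np.einsum("ij,...j->i...", inv_affine[:3, :3], pts) + inv_affine[:3, 3][:, None, None, None]
        v_new = -_sample_field(u, vox)
        step = np.max(np.abs(v_new - v))
        v = v_new
        if step < 1e-4 * voxel_mm:
            break

    # residual of phi(x + v(x)) - x on interior voxels
    pts = world + v
    vox = np.einsum("ij,...j->i...", inv_affine[:3, :3], pts) + inv_affine[:3, 3][:, None, None, None]
    resid = pts + _sample_field(u, vox) - world
    interior = (slice(2, -2),) * 3
    max_resid = float(np.max(np.linalg.norm(resid[interior], axis=-1)))
    if max_resid > 0.1 * voxel_mm:
        raise ValueError(
            f"inverse residual {max_resid:.3f} mm exceeds 0.1 voxel; "
            "reduce amplitude or increase smoothness"
        )
    return DeformationTruth(affine_part=affine_part, displacement=u,
                            inverse_displacement=v, affine=affine,
                            max_residual_mm=max_resid)


def _check_no_folding(u: np.ndarray, voxel_mm: float) -> None:
    """Verify det(J) > 0 everywhere for phi(x) = x + u(x), by central differences."""
    grads = np.empty(u.shape[:3] + (3, 3), dtype=float)
    for c in range(3):
        g = np.gradient(u[..., c], voxel_mm, edge_order=1)
        for ax in range(3):
            grads[..., c, ax] = g[ax]
    jac = grads + np.eye(3)
    det = np.linalg.det(jac)
    if np.any(det <= 0):
        raise ValueError("deformation folds (Jacobian determinant <= 0); "
                         "reduce amplitude or increase smoothness")
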
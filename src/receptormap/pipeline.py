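"""End-to-end orchestration: QC -> preprocess -> native-space estimation -> warp.

The subject-level flow mirrors the processing order that keeps the
quantification honest: motion QC and equilibrium QC first, then smoothing
and averaging of the accepted frames, then ratio-method estimation **in
native space**, and only afterwards warping of the finished parametric map
into the template space.  Every stage appends to a provenance log so the
ordering is auditable; a QC failure halts the subject with a
machine-readable reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from receptormap.imageio import (
    Image3D,
    Image4D,
    PlasmaValue,
    ProbMask,
    read_affine_text,
    read_displacement,
    read_image,
    read_plasma,
    write_image,
)
from receptormap.param_est import (
    compute_bpnd,
    compute_vt,
    normalize_activity,
    reference_value,
)
from receptormap.preprocess import (
    Transform,
    apply_transform,
    average_frames,
    motion_correct,
    smooth_gaussian,
)
from receptormap.tac_qc import (
    check_equilibrium,
    check_motion,
    extract_tac,
    normalize_tac,
    select_frames,
)
from receptormap.template_builder import TemplateSpec, build_template
from receptormap.validation import warp_delta

log = logging.getLogger("receptormap")


@dataclass
class Subject:
    """One subject's loaded inputs (native space unless noted)."""

    name: str
    pet: Image4D
    gm: ProbMask
    ref_mask: ProbMask
    brain_mask: ProbMask
    plasma: PlasmaValue | None = None
    to_template: Transform | None = None   # pull-back transform producing template-space output
    to_native: Transform | None = None     # pull-back transform producing native-space output

    @classmethod
    def from_paths(cls, name, pet, gm, ref_mask, brain_mask, plasma=None,
                   to_template=None, to_native=None, template_affine=None) -> "Subject":
        pet_img = read_image(pet)
        if not isinstance(pet_img, Image4D):
            raise ValueError(f"{pet}: subject PET must be 4D")

        def _mask(p):
            img = read_image(p)
            return ProbMask(np.clip(img.data, 0, 1), img.affine)

        def _xfm(p, affine):
            if p is None:
                return None
            p = Path(p)
            if p.suffix in (".txt", ".mat"):
                return Transform.from_affine(read_affine_text(p))
            return Transform.from_displacement(read_displacement(p), affine)

        return cls(
            name=name, pet=pet_img, gm=_mask(gm), ref_mask=_mask(ref_mask),
            brain_mask=_mask(brain_mask),
            plasma=read_plasma(plasma) if plasma else None,
            to_template=_xfm(to_template, template_affine),
            to_native=_xfm(to_native, pet_img.affine),
        )


@dataclass
class PipelineConfig:
    """Run-wide settings; defaults follow the workflow's standard values."""

    mode: str = "bpnd"                 # vt | bpnd | nac
    fwhm_mm: float = 2.5
    rest_window: tuple = (1800.0, 3600.0)
    deviation_threshold: float = 0.10
    coverage_threshold: float = 0.50
    motion_t_limit_mm: float = 3.0
    motion_r_limit_deg: float = 3.5
    dilation_radius_mm: float = 2.5
    use_gm_for_reference: bool = True  # cerebellar mode; pons mode sets False
    run_motion_correction: bool = True
    template_shape: tuple | None = None
    template_affine: np.ndarray | None = None
    out_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("mode", "fwhm_mm", "deviation_threshold", "coverage_threshold",
                    "motion_t_limit_mm", "motion_r_limit_deg", "dilation_radius_mm",
                    "use_gm_for_reference", "run_motion_correction", "out_dir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "rest_window" in raw:
            kwargs["rest_window"] = tuple(float(v) for v in raw["rest_window"])
        if "template_affine" in raw:
            kwargs["template_affine"] = np.asarray(raw["template_affine"], dtype=float)
        if "template_shape" in raw:
            kwargs["template_shape"] = tuple(int(v) for v in raw["template_shape"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("vt", "bpnd", "nac"):
            raise ValueError("mode must be vt, bpnd or nac")
        if not (0 < self.deviation_threshold < 1):
            raise ValueError("deviation threshold must be in (0, 1)")
        if not (0 < self.coverage_threshold <= 1):
            raise ValueError("coverage threshold must be in (0, 1]")
        if self.rest_window[1] <= self.rest_window[0]:
            raise ValueError("rest window must have positive length")


@dataclass
class SubjectResult:
    name: str
    passed: bool
    halt_stage: str = ""
    halt_reason: str = ""
    provenance: list = field(default_factory=list)
    motion_qc: dict | None = None
    tac_qc: dict | None = None
    selected_frames: list = field(default_factory=list)
    native_map: object = None       # ParametricImage in native space
    warped_map: Image3D | None = None

    def _log(self, stage: str, **params) -> None:
        self.provenance.append({"stage": stage, **params})

    def provenance_json(self) -> str:
        return json.dumps({"subject": self.name, "passed": self.passed,
                           "halt_stage": self.halt_stage,
                           "halt_reason": self.halt_reason,
                           "stages": self.provenance}, indent=1)


def run_subject(config: PipelineConfig, subject: Subject) -> SubjectResult:
    """Process one subject through QC, estimation and warping."""
    result = SubjectResult(name=subject.name, passed=False)
    pet = subject.pet

    # 1. motion correction + motion QC
    if config.run_motion_correction and pet.n_frames >= 2:
        pet, motion = motion_correct(pet)
        result._log("motion_correct", reference_frame=0)
        motion_qc = check_motion(motion, config.motion_t_limit_mm,
                                 config.motion_r_limit_deg)
        result.motion_qc = motion_qc.to_dict()
        result._log("motion_qc", passed=motion_qc.passed,
                    t_limit_mm=config.motion_t_limit_mm,
                    r_limit_deg=config.motion_r_limit_deg)
        if not motion_qc.passed:
            result.halt_stage, result.halt_reason = "motion_qc", motion_qc.reason
            return result

    # 2. TAC QC on the GM curve normalised to its equilibrium-window mean
    gm_tac = extract_tac(pet, subject.gm, "gm")
    norm = normalize_tac(gm_tac, gm_tac, config.rest_window)
    eq = check_equilibrium(norm, config.rest_window, config.deviation_threshold)
    result.tac_qc = eq.to_dict()
    result._log("tac_qc", passed=eq.passed, rest_window=list(config.rest_window),
                deviation_threshold=config.deviation_threshold)
    if not eq.passed:
        result.halt_stage, result.halt_reason = "tac_qc", eq.reason
        return result

    # 3. frame selection by resting-state coverage
    frames = select_frames(pet.schedule, config.rest_window,
                           config.coverage_threshold)
    result.selected_frames = frames
    result._log("select_frames", rest_window=list(config.rest_window),
                coverage_threshold=config.coverage_threshold, selected=frames)
    if not frames:
        result.halt_stage = "select_frames"
        result.halt_reason = "no frame covers enough of the resting-state window"
        return result

    # 4. smooth then average the accepted frames
    smoothed = smooth_gaussian(pet, config.fwhm_mm)
    mean_pet = average_frames(smoothed, frames)
    result._log("smooth", fwhm_mm=config.fwhm_mm)
    result._log("average_frames", indices=frames)

    # 5. native-space estimation (always before any warping)
    if config.mode == "vt":
        if subject.plasma is None:
            raise ValueError(f"{subject.name}: V_T mode requires a plasma value")
        pmap = compute_vt(mean_pet, subject.plasma)
    elif config.mode == "bpnd":
        ref = reference_value(mean_pet, subject.ref_mask,
                              subject.gm if config.use_gm_for_reference else None)
        pmap = compute_bpnd(mean_pet, ref)
    else:
        pmap = normalize_activity(mean_pet, subject.gm)
    pmap.data[subject.brain_mask.data <= 0.5] = 0.0
    result.native_map = pmap
    result._log("estimate", mode=config.mode, space="native",
                **{k: v for k, v in pmap.provenance.items()
                   if isinstance(v, (int, float, str))})

    # 6. warp the finished parametric map to template space
    if subject.to_template is not None:
        target_affine = (config.template_affine if config.template_affine is not None
                         else pet.affine)
        target_shape = (config.template_shape if config.template_shape is not None
                        else pet.data.shape[:3])
        result.warped_map = apply_transform(pmap.as_image(), subject.to_template,
                                            target_affine=target_affine,
                                            target_shape=target_shape)
        result._log("warp_to_template", space="template")
    result.passed = True
    return result


def run_group(config: PipelineConfig, subjects, template_brain_mask=None,
              warp_rois=None):
    """Process a cohort: per-subject runs, template, optional warp-effect table.

    ``warp_rois`` maps region name -> (native ProbMask per subject,
    template-space ProbMask) for delta computation on subjects that also
    carry a ``to_native`` transform for the template-space map.
    """
    results = [run_subject(config, s) for s in subjects]
    passing = [r for r in results if r.passed]
    if not passing:
        raise ValueError("no subject passed QC; cannot build a template")

    template = None
    warped_maps = [r.warped_map for r in passing if r.warped_map is not None]
    if warped_maps:
        spec = TemplateSpec(kind=config.mode.upper() if config.mode != "nac" else "NAC",
                            dilation_radius_mm=config.dilation_radius_mm)
        template = build_template(
            warped_maps, spec,
            brain_mask=template_brain_mask if spec.masked else None)

    deltas = []
    if warp_rois:
        for region, (native_rois, template_roi) in warp_rois.items():
            for r, native_roi in zip(passing, native_rois):
                if r.warped_map is None:
                    continue
                deltas.append({
                    "subject": r.name, "region": region,
                    "delta_pct": warp_delta(r.native_map.as_image(), r.warped_map,
                                            native_roi, template_roi),
                })
    return {"results": results, "template": template, "warp_deltas": deltas}


def write_subject_outputs(result: SubjectResult, out_dir) -> None:
    out_dir = Path(out_dir) / result.name
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "provenance.json").write_text(result.provenance_json())
    if result.native_map is not None:
        write_image(result.native_map.as_image(), out_dir / "param_native.nii.gz")
    if result.warped_map is not None:
        write_image(result.warped_map, out_dir / "param_template.nii.gz")
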
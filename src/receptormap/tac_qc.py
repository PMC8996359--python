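"""Time-activity-curve extraction, normalisation and equilibrium QC.

A bolus-plus-constant-infusion protocol only supports ratio-method
quantification while tissue and plasma are in sustained equilibrium.  The
rules here decide, per scan, whether that condition holds and which frames
may enter the analysis:

* TACs are normalised to the mean grey-matter activity over the expected
  equilibrium window;
* a scan passes if every frame within the resting-state window deviates
  from the window mean of the normalised curve by less than 10 %
  (fractional, relative to the window mean);
* frames qualify for averaging when they cover more than 50 % of the
  resting-state acquisition interval;
* scans with inter-frame motion of 3 mm or more (translation) or 3.5 deg
  or more (rotation) relative to the first frame are rejected, since such
  motion exceeds the image resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from receptormap.imageio import FrameSchedule, Image4D, ProbMask


@dataclass
class TAC:
    """Mean activity in a mask as a function of frame mid-time."""

    t_mid_s: np.ndarray
    value: np.ndarray
    mask_name: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t_mid_s = np.asarray(self.t_mid_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t_mid_s.shape != self.value.shape or self.t_mid_s.ndim != 1:
            raise ValueError("t_mid_s and value must be 1D arrays of equal length")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("TAC contains non-finite values")

    def __len__(self) -> int:
        return len(self.value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self)),
                             "t_mid_s": self.t_mid_s, "value": self.value})


@dataclass
class QCResult:
    passed: bool
    max_deviation_frac: float = 0.0
    selected_frames: list = field(default_factory=list)
    reason: str = ""

    def to_dict(self) -> dict:
        return {"passed": bool(self.passed),
                "max_deviation_frac": float(self.max_deviation_frac),
                "selected_frames": [int(i) for i in self.selected_frames],
                "reason": self.reason}


@dataclass
class MotionParams:
    """Per-frame rigid parameters (tx,ty,tz mm; roll,pitch,yaw deg) vs frame 0."""

    table: np.ndarray  # (n_frames, 6)

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 2 or self.table.shape[1] != 6:
            raise ValueError("motion table must be (n_frames, 6)")
        if np.any(self.table[0] != 0):
            raise ValueError("frame 0 motion parameters must be zero (reference frame)")

    @property
    def translations_mm(self) -> np.ndarray:
        return self.table[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.table[:, 3:]


def extract_tac(image4d: Image4D, mask: ProbMask, mask_name: str = "") -> TAC:
    """Per-frame mean activity over voxels where the mask exceeds 0.5."""
    if mask.data.shape != image4d.data.shape[:3]:
        raise ValueError("mask grid does not match the image grid")
    sel = mask.data > 0.5
    if not np.any(sel):
        raise ValueError("mask is empty after thresholding at 0.5")
    values = image4d.data[sel].mean(axis=0)
    return TAC(image4d.schedule.t_mid_s, values, mask_name=mask_name)


def normalize_tac(tac: TAC, gm_tac: TAC, equilibrium_window) -> TAC:
    """Divide by the mean GM activity over the expected equilibrium window."""
    t0, t1 = float(equilibrium_window[0]), float(equilibrium_window[1])
    if len(tac) != len(gm_tac):
        raise ValueError("TAC and GM TAC lengths differ")
    inside = (gm_tac.t_mid_s >= t0) & (gm_tac.t_mid_s <= t1)
    if not np.any(inside):
        raise ValueError("equilibrium window overlaps no frames")
    norm = gm_tac.value[inside].mean()
    if norm == 0:
        raise ValueError("zero GM activity over the equilibrium window")
    return TAC(tac.t_mid_s, tac.value / norm, mask_name=tac.mask_name, normalized=True)


def check_equilibrium(norm_tac: TAC, rest_window,
                      deviation_threshold: float = 0.10) -> QCResult:
    """Equilibrium acceptance rule on a normalised TAC.

    Every frame whose midpoint falls in the resting-state window must
    deviate from the in-window mean by less than ``deviation_threshold``
    (fractional).  Deviations are relative, so the verdict is invariant to
    global rescaling of the TAC.
    """
    if not norm_tac.normalized:
        raise ValueError("check_equilibrium expects a normalised TAC")
    t0, t1 = float(rest_window[0]), float(rest_window[1])
    inside = np.flatnonzero((norm_tac.t_mid_s >= t0) & (norm_tac.t_mid_s <= t1))
    if inside.size == 0:
        raise ValueError("resting-state window contains no frame midpoints")
    window_vals = norm_tac.value[inside]
    wmean = window_vals.mean()
    if wmean == 0:
        raise ValueError("window mean is zero; deviations undefined")
    dev = np.abs(window_vals - wmean) / abs(wmean)
    max_dev = float(dev.max())
    passed = bool(max_dev < deviation_threshold)
    reason = "" if passed else (
        f"max fractional deviation {max_dev:.3f} >= {deviation_threshold:.3f}")
    return QCResult(passed=passed, max_deviation_frac=max_dev,
                    selected_frames=list(inside), reason=reason)


def select_frames(schedule: FrameSchedule, rest_window,
                  coverage_threshold: float = 0.50) -> list:
    """Frames whose overlap with the resting-state window exceeds the
    coverage fraction of their own duration (strict >)."""
    t0, t1 = float(rest_window[0]), float(rest_window[1])
    if t1 <= t0:
        raise ValueError("rest window must have positive length")
    overlap = np.minimum(schedule.end_s, t1) - np.maximum(schedule.start_s, t0)
    overlap = np.clip(overlap, 0.0, None)
    return [int(i) for i in
            np.flatnonzero(overlap > coverage_threshold * schedule.duration_s)]


def check_motion(motion: MotionParams, t_limit_mm: float = 3.0,
                 r_limit_deg: float = 3.5) -> QCResult:
    """Motion acceptance: all |translation| < 3 mm and |rotation| < 3.5 deg."""
    t_ok = np.all(np.abs(motion.translations_mm) < t_limit_mm)
    r_ok = np.all(np.abs(motion.rotations_deg) < r_limit_deg)
    passed = bool(t_ok and r_ok)
    max_t = float(np.max(np.abs(motion.translations_mm)))
    max_r = float(np.max(np.abs(motion.rotations_deg)))
    reason = "" if passed else (
        f"motion exceeds limits: max |t| = {max_t:.2f} mm "
        f"(limit {t_limit_mm}), max |angle| = {max_r:.2f} deg (limit {r_limit_deg})")
    return QCResult(passed=passed,
                    max_deviation_frac=max(max_t / t_limit_mm, max_r / r_limit_deg),
                    reason=reason)
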
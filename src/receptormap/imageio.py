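"""NIfTI image containers and plain-text sidecar IO.

Conventions used throughout the package:

* voxel indices are 0-based; world coordinates are millimetres via the
  NIfTI voxel-to-world affine; images are processed in stored orientation
  (no implicit reorientation);
* 4D images carry a frame schedule (per-frame start and duration in
  seconds) in a JSON sidecar, because the NIfTI header only stores a
  uniform TR while bolus-infusion framing differs between studies;
* out-of-field-of-view voxels resample to 0 (PET background is air).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class FrameSchedule:
    """Per-frame acquisition timing in seconds."""

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        if self.start_s.shape != self.duration_s.shape or self.start_s.ndim != 1:
            raise ValueError("start_s and duration_s must be 1D arrays of equal length")
        if len(self.start_s) == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(self.duration_s <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(self.start_s) <= 0):
            raise ValueError("frame starts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.start_s)

    @property
    def t_mid_s(self) -> np.ndarray:
        return self.start_s + self.duration_s / 2.0

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @classmethod
    def uniform(cls, n_frames: int, duration_s: float, start_s: float = 0.0) -> "FrameSchedule":
        starts = start_s + duration_s * np.arange(n_frames)
        return cls(starts, np.full(n_frames, float(duration_s)))

    def to_dict(self) -> dict:
        return {"start_s": self.start_s.tolist(), "duration_s": self.duration_s.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(np.asarray(d["start_s"]), np.asarray(d["duration_s"]))


@dataclass
class Image3D:
    """A 3D scalar volume with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray
    units: str = "kBq/mL"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Image3D requires 3D data, got shape {self.data.shape}")
        _check_affine(self.affine)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite voxels")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_mm(self) -> np.ndarray:
        """Voxel edge lengths along each axis, mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "Image3D | ProbMask", atol: float = 1e-4) -> bool:
        return self.data.shape[:3] == other.data.shape[:3] and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class Image4D:
    """A dynamic series (x, y, z, frame) with a frame schedule."""

    data: np.ndarray
    affine: np.ndarray
    schedule: FrameSchedule
    units: str = "kBq/mL"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Image4D requires 4D data, got shape {self.data.shape}")
        _check_affine(self.affine)
        if self.data.shape[3] != len(self.schedule):
            raise ValueError(
                f"{self.data.shape[3]} frames but schedule has {len(self.schedule)} entries"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite voxels")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def frame(self, i: int) -> Image3D:
        return Image3D(self.data[..., i], self.affine, self.units)


@dataclass
class ProbMask:
    """A probabilistic mask: values in [0, 1] on an image grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ProbMask requires 3D data")
        _check_affine(self.affine)
        if np.any(self.data < -1e-9) or np.any(self.data > 1 + 1e-9):
            raise ValueError("mask values must lie in [0, 1]")
        self.data = np.clip(self.data, 0.0, 1.0)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class PlasmaValue:
    """Metabolite-corrected venous plasma activity at equilibrium, kBq/mL."""

    cp: float

    def __post_init__(self) -> None:
        self.cp = float(self.cp)
        if not np.isfinite(self.cp) or self.cp <= 0:
            raise ValueError("plasma activity must be a positive finite number")


def _check_affine(affine: np.ndarray) -> None:
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")


# --------------------------------------------------------------------------
# file IO
# --------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_image(path, schedule: FrameSchedule | None = None):
    """Read a NIfTI volume; 4D files need a schedule (argument or JSON sidecar).

    Returns an :class:`Image3D` or :class:`Image4D`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    affine = np.asarray(img.affine, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim == 3:
        return Image3D(data, affine)
    if data.ndim == 4:
        if schedule is None:
            sidecar = _sidecar_path(path)
            if not sidecar.exists():
                raise ValueError(
                    f"4D image {path} requires a frame schedule "
                    f"(pass one or provide sidecar {sidecar.name})"
                )
            with open(sidecar) as fh:
                schedule = FrameSchedule.from_dict(json.load(fh))
        return Image4D(data, affine, schedule)
    raise ValueError(f"unsupported dimensionality: {data.ndim}")


def write_image(image, path) -> Path:
    """Write an Image3D/Image4D/ProbMask as NIfTI (+ JSON schedule sidecar for 4D)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nii = nib.Nifti1Image(np.asarray(image.data, dtype=np.float64), image.affine)
    nib.save(nii, str(path))
    if isinstance(image, Image4D):
        with open(_sidecar_path(path), "w") as fh:
            json.dump(image.schedule.to_dict(), fh, indent=1)
    return path


def read_plasma(path) -> PlasmaValue:
    """Read a single metabolite-corrected plasma activity value from a text file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"plasma file {path} is empty")
    try:
        value = float(text.split()[0])
    except ValueError as exc:
        raise ValueError(f"plasma file {path} is not numeric: {text!r}") from exc
    return PlasmaValue(value)


def write_plasma(plasma: PlasmaValue, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(f"{plasma.cp}\n")
    return path


def read_affine_text(path) -> np.ndarray:
    """Read a 4x4 affine transform from whitespace-delimited text."""
    mat = np.loadtxt(path)
    if mat.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}, got {mat.shape}")
    return mat


def write_affine_text(matrix: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.12g")
    return path


def read_displacement(path) -> np.ndarray:
    """Read a dense displacement field (4D NIfTI, last axis = 3, mm in world space)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 5 and data.shape[3] == 1:  # ANTs-style (x,y,z,1,3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"displacement field must be (x,y,z,3), got {data.shape}")
    return data


def write_displacement(field: np.ndarray, affine: np.ndarray, path) -> Path:
    field = np.asarray(field, dtype=float)
    if field.ndim != 4 or field.shape[-1] != 3:
        raise ValueError("displacement field must be (x,y,z,3)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(field, affine), str(path))
    return path


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

_ORDERS = {"nearest": 0, "trilinear": 1}


def resample_to_grid(image, target_affine, target_shape, interpolation="trilinear"):
    """Express ``image`` on a new grid; out-of-FOV voxels are 0.

    ``interpolation`` is ``"nearest"`` or ``"trilinear"``.  Returns an object
    of the same class as the input (Image3D or ProbMask).
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"interpolation must be one of {sorted(_ORDERS)}")
    target_affine = np.asarray(target_affine, dtype=float)
    _check_affine(target_affine)
    # voxel(target) -> world -> voxel(source)
    vox2vox = np.linalg.inv(image.affine) @ target_affine
    matrix = vox2vox[:3, :3]
    offset = vox2vox[:3, 3]
    out = ndimage.affine_transform(
        image.data,
        matrix,
        offset=offset,
        output_shape=tuple(target_shape),
        order=_ORDERS[interpolation],
        mode="constant",
        cval=0.0,
    )
    if isinstance(image, ProbMask):
        return ProbMask(np.clip(out, 0.0, 1.0), target_affine)
    return Image3D(out, target_affine, getattr(image, "units", "kBq/mL"))
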
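"""Group template and atlas-table construction in a standard space.

Templates are voxel-wise unweighted means of subject maps that have
already been warped onto a common grid.  Parametric (V_T / BP_ND)
templates are masked with a brain mask dilated by a spherical kernel
(default radius 2.5 mm) so that no information near the brain edge is cut
off; normalised-activity (NAC) templates are left unmasked because they
serve as registration targets and benefit from extra-cerebral context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from receptormap.imageio import Image3D, ProbMask
from receptormap.preprocess import morph_mask


@dataclass
class TemplateSpec:
    kind: str = "BPND"            # VT | BPND | NAC
    masked: bool = True           # NAC templates are conventionally unmasked
    dilation_radius_mm: float = 2.5

    def __post_init__(self) -> None:
        if self.kind not in ("VT", "BPND", "NAC"):
            raise ValueError("kind must be VT, BPND or NAC")
        if self.kind == "NAC":
            self.masked = False


def build_template(images, spec: TemplateSpec,
                   brain_mask: ProbMask | None = None) -> Image3D:
    """Average subject maps on a common grid into a template.

    All inputs must share the template grid.  For masked specs the mean is
    multiplied by the brain mask dilated with a spherical kernel of
    ``spec.dilation_radius_mm``.
    """
    images = list(images)
    if not images:
        raise ValueError("no images to average")
    ref = images[0]
    for img in images[1:]:
        if img.data.shape != ref.data.shape or not np.allclose(img.affine, ref.affine,
                                                               atol=1e-4):
            raise ValueError("all template inputs must share one grid")
    mean = np.mean([img.data for img in images], axis=0)
    if spec.masked:
        if brain_mask is None:
            raise ValueError("masked template requires a brain mask")
        if brain_mask.data.shape != ref.data.shape:
            raise ValueError("brain mask grid does not match the template grid")
        dilated = morph_mask(brain_mask, "dilate", spec.dilation_radius_mm)
        mean = mean * dilated.data
    return Image3D(mean, ref.affine, units="")


def region_table(template: Image3D, atlas_labels: np.ndarray,
                 labels=None) -> pd.DataFrame:
    """Per-label mean and voxel count over an integer atlas volume.

    ``labels`` selects which labels to tabulate (default: all non-zero
    labels present).  Labels with no voxels are flagged empty rather than
    raising, so sparse atlases can be tabulated wholesale.
    """
    atlas_labels = np.asarray(atlas_labels)
    if atlas_labels.shape != template.data.shape:
        raise ValueError("atlas grid does not match the template grid")
    if labels is None:
        labels = [int(v) for v in np.unique(atlas_labels) if v != 0]
    rows = []
    for label in labels:
        sel = atlas_labels == label
        n = int(sel.sum())
        rows.append({
            "label": int(label),
            "n_voxels": n,
            "mean": float(template.data[sel].mean()) if n else np.nan,
            "empty": n == 0,
        })
    return pd.DataFrame(rows, columns=["label", "n_voxels", "mean", "empty"])
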
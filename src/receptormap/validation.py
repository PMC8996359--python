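"""Warp-effect assessment and registration-quality benchmarking.

Two validation procedures for spatially normalised parametric PET:

1. **Warp effect.**  Nonlinear normalisation changes voxel values through
   volumetric distortion and interpolation.  The effect on a regional
   estimate is quantified as the percent error between the warped-space
   and native-space weighted ROI means,

       delta = (x_w - x_n) / x_n * 100,

   where each mean uses the probabilistic ROI values (atlas ROI times GM
   probability, each in its own space) as weights.

2. **Registration benchmark.**  Candidate registrations of the same
   subject are compared against a reference ("ground truth") registration
   with four similarity metrics inside a brain mask: mutual information
   (MI, nats, 32-bin joint histogram), local cross-correlation (CC, mean
   squared neighbourhood correlation in a cubic window of radius 4
   voxels), a global structural similarity index (gSSim, SSIM evaluated on
   whole-volume moments) and the voxel-wise mean squared error (MSE).
   Candidates are compared per metric with paired two-sample t tests; no
   multiple-comparison correction is applied (a Holm option exists for
   users who want one).

The Wilcoxon signed-rank test used for regional native-vs-warped
comparisons is exact (full 2^n sign enumeration with mid-ranks) up to
n = 20 pairs, which covers typical region-by-subject designs, and falls
back to a tie-corrected normal approximation above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from receptormap.imageio import Image3D, ProbMask


@dataclass
class RegionStat:
    region: str
    native_value: float
    warped_value: float
    delta_pct: float
    n_subjects: int = 1
    p_value: float = np.nan


@dataclass
class SimilarityReport:
    mi: float
    cc: float
    gssim: float
    mse: float
    mask_provenance: str = ""

    def to_dict(self) -> dict:
        return {"mi": self.mi, "cc": self.cc, "gssim": self.gssim, "mse": self.mse,
                "mask_provenance": self.mask_provenance}


# --------------------------------------------------------------------------
# weighted ROI statistics and the warp effect
# --------------------------------------------------------------------------

def _as_array(x) -> np.ndarray:
    """Accept Image3D/ProbMask/plain arrays alike."""
    if isinstance(x, np.ndarray):
        return np.asarray(x, dtype=float)
    return np.asarray(getattr(x, "data", x), dtype=float)


def weighted_roi_mean(image, prob_roi) -> float:
    """Probability-weighted mean:  sum(w x) / sum(w) over all voxels."""
    data = _as_array(image)
    w = _as_array(prob_roi)
    if w.shape != data.shape:
        raise ValueError("weights do not match the image grid")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all weights are zero")
    return float((w * data).sum() / total)


def warp_delta(native_img, warped_img, native_roi, warped_roi) -> float:
    """Percent error of the warped-space regional mean vs native space."""
    native = weighted_roi_mean(native_img, native_roi)
    warped = weighted_roi_mean(warped_img, warped_roi)
    if native == 0:
        raise ValueError("native-space regional mean is zero; delta undefined")
    return float((warped - native) / native * 100.0)


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def wilcoxon_signed_rank(paired_a, paired_b):
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ties in |difference| receive mid-ranks.
    The statistic is W+ (sum of ranks of positive differences).  For
    n <= 20 retained pairs the p value is exact, from full enumeration of
    all 2^n sign assignments of the observed ranks; beyond that a normal
    approximation with tie correction is used.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1D arrays of equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())

    if n <= 20:
        # exact null: every sign pattern equally likely
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        p_le = np.mean(totals <= w_plus + 1e-12)
        p_ge = np.mean(totals >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return w_plus, float(p)


def paired_t_test(paired_a, paired_b):
    """Paired two-sample t test (two-sided), no multiplicity correction."""
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1D arrays of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(a - b) == 0:
        raise ValueError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p values (optional; off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adjusted = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


# --------------------------------------------------------------------------
# similarity metrics
# --------------------------------------------------------------------------

def _masked(a, b, mask):
    a = _as_array(a)
    b = _as_array(b)
    if a.shape != b.shape:
        raise ValueError("images must share a grid")
    if mask is None:
        sel = np.ones(a.shape, dtype=bool)
    else:
        m = _as_array(mask)
        if m.shape != a.shape:
            raise ValueError("mask must share the image grid")
        sel = m > 0.5
    if not np.any(sel):
        raise ValueError("mask is empty")
    return a, b, sel


def mutual_information(a, b, mask=None, bins: int = 32) -> float:
    """Mutual information of the joint intensity histogram, in nats.

    Equal-width bins over each image's masked intensity range.
    """
    a, b, sel = _masked(a, b, mask)
    x, y = a[sel], b[sel]
    if x.size < bins ** 2:
        raise ValueError(f"need at least bins^2 = {bins ** 2} masked voxels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant image: mutual information undefined")
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def binned_entropy(a, mask=None, bins: int = 32) -> float:
    """Marginal entropy of the binned masked intensities, nats (= MI(a, a))."""
    a, _, sel = _masked(a, a, mask)
    x = a[sel]
    hist, _ = np.histogram(x, bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def local_cc(a, b, mask=None, radius: int = 4) -> float:
    """Mean squared local correlation over cubic windows of half-width ``radius``.

    At each masked voxel the correlation between the two images is computed
    over the surrounding (2r+1)^3 window (clipped at volume edges), squared,
    and averaged; windows with zero variance in either image contribute 0.
    """
    a, b, sel = _masked(a, b, mask)
    size = 2 * radius + 1

    def wsum(x):
        return ndimage.uniform_filter(x, size=size, mode="constant", cval=0.0) * size ** 3

    ones = np.ones_like(a)
    n = wsum(ones)
    sa, sb = wsum(a), wsum(b)
    saa, sbb, sab = wsum(a * a), wsum(b * b), wsum(a * b)
    cov = sab - sa * sb / n
    var_a = saa - sa ** 2 / n
    var_b = sbb - sb ** 2 / n
    denom = var_a * var_b
    cc = np.zeros_like(a)
    good = (var_a > 0) & (var_b > 0)
    cc[good] = cov[good] ** 2 / denom[good]
    return float(np.clip(cc[sel], 0.0, 1.0).mean())


def global_ssim(a, b) -> float:
    """Structural similarity index from whole-volume moments.

    SSIM with constants C1 = (0.01 L)^2, C2 = (0.03 L)^2 where L is the
    larger of the two images' dynamic ranges, evaluated once on the global
    means, variances and covariance rather than over sliding windows.
    """
    a = _as_array(a)
    b = _as_array(b)
    if a.shape != b.shape:
        raise ValueError("images must share a grid")
    L = max(np.ptp(a), np.ptp(b))
    if L == 0:
        if np.array_equal(a, b):
            return 1.0
        raise ValueError("both images constant but unequal: gSSim undefined")
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    return float(num / den)


def mse(a, b, mask=None) -> float:
    """Mean squared voxel-wise error over the masked voxels."""
    a, b, sel = _masked(a, b, mask)
    return float(np.mean((a[sel] - b[sel]) ** 2))


def similarity_report(candidate, reference, mask=None, cc_radius: int = 4,
                      mi_bins: int = 32, provenance: str = "") -> SimilarityReport:
    """All four metrics of a candidate against a reference image."""
    return SimilarityReport(
        mi=mutual_information(candidate, reference, mask, bins=mi_bins),
        cc=local_cc(candidate, reference, mask, radius=cc_radius),
        gssim=global_ssim(candidate, reference),
        mse=mse(candidate, reference, mask),
        mask_provenance=provenance,
    )


_METRICS = ("mi", "cc", "gssim", "mse")


def registration_benchmark(references, candidates, mask=None, cc_radius: int = 4,
                           mi_bins: int = 32, smoothed_arm=None):
    """Benchmark candidate registrations against per-subject references.

    Parameters
    ----------
    references : list of Image3D
        The reference ("ground truth") registration result per subject.
    candidates : dict mapping name -> list of Image3D
        Candidate registration results, one list entry per subject, at
        least two candidates.
    mask : ProbMask, optional
        Brain mask restricting MI, CC and MSE.
    smoothed_arm : dict, optional
        Additional candidate sets evaluated against 8-mm-smoothed targets
        or other control references; same structure as ``candidates`` with
        values (candidate list, reference list).

    Returns
    -------
    dict with ``scores`` (DataFrame: subject x candidate x metric) and
    ``tests`` (DataFrame: per metric and candidate pair, paired t statistic
    and uncorrected two-sided p value).
    """
    names = sorted(candidates)
    if len(names) < 2:
        raise ValueError("need at least two candidate registrations")
    n_subj = len(references)
    for name in names:
        if len(candidates[name]) != n_subj:
            raise ValueError(f"candidate {name!r} has a mismatched subject count")

    rows = []
    for s in range(n_subj):
        for name in names:
            rep = similarity_report(candidates[name][s], references[s], mask,
                                    cc_radius=cc_radius, mi_bins=mi_bins,
                                    provenance=f"subject {s}")
            rows.append({"subject": s, "candidate": name, **rep.to_dict()})
    if smoothed_arm:
        for name, (cands, refs) in smoothed_arm.items():
            for s in range(n_subj):
                rep = similarity_report(cands[s], refs[s], mask,
                                        cc_radius=cc_radius, mi_bins=mi_bins,
                                        provenance=f"subject {s} (smoothed arm)")
                rows.append({"subject": s, "candidate": name, **rep.to_dict()})
    scores = pd.DataFrame(rows)

    tests = []
    for metric in _METRICS:
        for i, name_a in enumerate(names):
            for name_b in names[i + 1:]:
                va = scores.loc[scores.candidate == name_a, metric].to_numpy()
                vb = scores.loc[scores.candidate == name_b, metric].to_numpy()
                try:
                    t, p = paired_t_test(va, vb)
                except ValueError:
                    t, p = np.nan, np.nan
                tests.append({"metric": metric, "candidate_a": name_a,
                              "candidate_b": name_b, "t": t, "p": p})
    return {"scores": scores, "tests": pd.DataFrame(tests)}


# Literature test-retest variability bands for the two tracers this workflow
# targets; used only to contextualise delta values in reports, never computed.
TEST_RETEST_SIGMA_PCT = {"ABP688": (4.0, 16.0), "FMZ": (3.9, 9.5)}


def warp_effect_table(native_imgs, warped_imgs, native_rois, warped_rois,
                      region_names=None) -> pd.DataFrame:
    """Per-region warp-effect table across subjects with Wilcoxon p values.

    ``native_rois`` / ``warped_rois`` map region name -> per-subject list of
    probabilistic ROIs in the respective space; ``native_imgs`` and
    ``warped_imgs`` are per-subject parametric maps.
    """
    n_subj = len(native_imgs)
    if len(warped_imgs) != n_subj:
        raise ValueError("native and warped subject counts differ")
    regions = list(region_names) if region_names is not None else sorted(native_rois)
    rows = []
    for region in regions:
        native_vals = np.array([weighted_roi_mean(native_imgs[s], native_rois[region][s])
                                for s in range(n_subj)])
        warped_vals = np.array([weighted_roi_mean(warped_imgs[s], warped_rois[region][s])
                                for s in range(n_subj)])
        deltas = (warped_vals - native_vals) / native_vals * 100.0
        try:
            _, p = wilcoxon_signed_rank(warped_vals, native_vals)
        except ValueError:
            p = np.nan
        rows.append({"region": region,
                     "native_mean": float(native_vals.mean()),
                     "warped_mean": float(warped_vals.mean()),
                     "delta_pct_mean": float(deltas.mean()),
                     "delta_pct_sd": float(deltas.std(ddof=1)) if n_subj > 1 else 0.0,
                     "delta_pct_max_abs": float(np.abs(deltas).max()),
                     "n_subjects": n_subj, "p_wilcoxon": p})
    return pd.DataFrame(rows)
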
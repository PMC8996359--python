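import itertools

import numpy as np
import pytest
from scipy import stats

from receptormap import (
    Image3D,
    ProbMask,
    apply_transform,
    global_ssim,
    local_cc,
    make_deformation,
    mse,
    mutual_information,
    paired_t_test,
    registration_benchmark,
    warp_delta,
    weighted_roi_mean,
    wilcoxon_signed_rank,
)
from receptormap.preprocess import RigidTransform, Transform
from receptormap.validation import binned_entropy, holm_correction, warp_effect_table


def _img(data, affine=None):
    return Image3D(np.asarray(data, dtype=float),
                   np.eye(4) if affine is None else affine)


# --------------------------------------------------------------------------
# weighted means and the warp effect
# --------------------------------------------------------------------------

class TestWeightedRoiMean:
    def test_equal_weights(self):
        vals = np.zeros((2, 1, 1))
        vals[:, 0, 0] = [2.0, 4.0]
        w = np.ones((2, 1, 1))
        assert weighted_roi_mean(vals, w) == 3.0

    def test_unequal_weights(self):
        vals = np.zeros((2, 1, 1))
        vals[:, 0, 0] = [0.0, 10.0]
        w = np.zeros((2, 1, 1))
        w[:, 0, 0] = [0.2, 0.8]
        assert weighted_roi_mean(vals, w) == pytest.approx(8.0, rel=1e-12)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(7, 6, 5))
        w = rng.uniform(size=(7, 6, 5))
        num, den = 0.0, 0.0
        for i in range(7):
            for j in range(6):
                for k in range(5):
                    num += w[i, j, k] * vals[i, j, k]
                    den += w[i, j, k]
        assert weighted_roi_mean(vals, w) == pytest.approx(num / den, abs=1e-12)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_roi_mean(np.ones((3, 3, 3)), np.zeros((3, 3, 3)))


class TestWarpDelta:
    def test_formula_arithmetic(self):
        native = _img(np.full((4, 4, 4), 1.00))
        warped = _img(np.full((4, 4, 4), 1.03))
        roi = ProbMask(np.ones((4, 4, 4)), np.eye(4))
        assert warp_delta(native, warped, roi, roi) == pytest.approx(3.0, rel=1e-12)

    def test_identity_gives_zero_for_every_roi(self, phantom):
        img = Image3D(phantom.true_bpnd_map, phantom.affine)
        for r in phantom.regions:
            if r.true_bpnd == 0:
                continue  # zero native mean: delta undefined by definition
            roi = phantom.region_mask(r.label)
            assert abs(warp_delta(img, img, roi, roi)) < 1e-10

    def test_zero_native_mean_rejected(self):
        native = _img(np.zeros((4, 4, 4)))
        roi = ProbMask(np.ones((4, 4, 4)), np.eye(4))
        with pytest.raises(ValueError):
            warp_delta(native, native, roi, roi)

    def test_roundtrip_delta_matches_explicit_recomputation(self, phantom):
        d = make_deformation(shape=phantom.labels.shape, amplitude_mm=3.0,
                             smoothness_mm=12.0, seed=31)
        native = Image3D(phantom.true_bpnd_map, phantom.affine)
        warped = apply_transform(native, d.transform_to_warped())
        gm_native = phantom.gm_prob
        gm_warped = apply_transform(gm_native, d.transform_to_warped())
        roi_native = ProbMask(gm_native.data * phantom.region_mask(1).data,
                              phantom.affine)
        roi_w = apply_transform(phantom.region_mask(1), d.transform_to_warped())
        roi_warped = ProbMask(gm_warped.data * roi_w.data, phantom.affine)

        delta = warp_delta(native, warped, roi_native, roi_warped)
        assert delta != 0.0 and abs(delta) < 15.0

        # independent recomputation with explicit loops over flat arrays
        def loop_mean(img, w):
            num = den = 0.0
            for x, ww in zip(img.data.ravel(), w.data.ravel()):
                num += ww * x
                den += ww
            return num / den

        n_val = loop_mean(native, roi_native)
        w_val = loop_mean(warped, roi_warped)
        expected = (w_val - n_val) / n_val * 100.0
        assert delta == pytest.approx(expected, abs=1e-10)


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

class TestWilcoxon:
    def test_all_positive_n5_exact_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.zeros(5)
        stat, p = wilcoxon_signed_rank(a, b)
        assert stat == 15.0
        assert p == pytest.approx(2.0 / 32.0, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        s1, p1 = wilcoxon_signed_rank(a, b)
        s2, p2 = wilcoxon_signed_rank(b, a)
        n = 8  # no zero differences with continuous data
        assert s1 + s2 == pytest.approx(n * (n + 1) / 2)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_full_enumeration_oracle_n10(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            d = rng.normal(size=10)
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            # brute force over all 2^10 sign patterns
            dist = []
            for signs in itertools.product([0, 1], repeat=10):
                dist.append(sum(r for s, r in zip(signs, ranks) if s))
            dist = np.asarray(dist, dtype=float)
            p_exp = min(1.0, 2 * min((dist <= w_obs + 1e-12).mean(),
                                     (dist >= w_obs - 1e-12).mean()))
            stat, p = wilcoxon_signed_rank(d, np.zeros(10))
            assert stat == pytest.approx(w_obs)
            assert p == pytest.approx(p_exp, abs=1e-12)

    def test_agrees_with_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        _, p = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=40)
        b = a + 0.3 + rng.normal(size=40)
        _, p = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, alternative="two-sided",
                             method="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))


class TestPairedT:
    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test(np.arange(5.0), np.arange(5.0))

    def test_near_constant_difference_gives_extreme_t(self):
        rng = np.random.default_rng(5)
        a = np.ones(6) + 1e-9 * rng.normal(size=6)
        b = np.zeros(6)
        t, p = paired_t_test(a, b)
        assert abs(t) > 1e6
        assert p < 1e-10

    def test_matches_textbook_formula(self):
        a = np.array([3.0, 5.0, 4.0, 6.0])
        b = np.array([2.0, 4.5, 2.5, 5.0])
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(t_expected, rel=1e-12)
        p_expected = 2 * stats.t.sf(abs(t_expected), df=3)
        assert p == pytest.approx(p_expected, rel=1e-12)

    def test_holm_correction_monotone(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = holm_correction(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)


# --------------------------------------------------------------------------
# similarity metrics
# --------------------------------------------------------------------------

class TestMutualInformation:
    def test_self_information_equals_binned_entropy(self, structured_image):
        mi = mutual_information(structured_image, structured_image)
        h = binned_entropy(structured_image)
        assert mi == pytest.approx(h, rel=1e-10)

    def test_shuffled_partner_has_near_zero_mi(self, structured_image):
        rng = np.random.default_rng(6)
        flat = structured_image.data.ravel().copy()
        rng.shuffle(flat)
        shuffled = flat.reshape(structured_image.shape)
        mi = mutual_information(structured_image, _img(shuffled,
                                                       structured_image.affine))
        assert mi < 0.05

    def test_invariant_to_affine_rescaling(self, structured_image):
        a = structured_image
        b = _img(2.0 * a.data + 5.0, a.affine)
        assert mutual_information(a, b) == pytest.approx(
            mutual_information(a, a), rel=1e-10)

    def test_constant_image_rejected(self):
        a = _img(np.zeros((16, 16, 16)))
        with pytest.raises(ValueError):
            mutual_information(a, a)


class TestLocalCC:
    def test_self_correlation_is_one(self, structured_image):
        mask = ProbMask((structured_image.data > 0.1).astype(float),
                        structured_image.affine)
        cc = local_cc(structured_image, structured_image, mask)
        assert cc == pytest.approx(1.0, abs=1e-9)

    def test_sign_invariance_of_squared_form(self, structured_image):
        neg = _img(-structured_image.data, structured_image.affine)
        mask = ProbMask((structured_image.data > 0.1).astype(float),
                        structured_image.affine)
        cc = local_cc(structured_image, neg, mask)
        assert cc == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_window_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(9, 9, 9))
        b = 0.5 * a + rng.normal(size=(9, 9, 9))
        radius = 2
        size = 2 * radius + 1

        def window_cc(i, j, k):
            sl = tuple(slice(max(0, c - radius), min(9, c + radius + 1))
                       for c in (i, j, k))
            wa, wb = a[sl].ravel(), b[sl].ravel()
            va = ((wa - wa.mean()) ** 2).sum()
            vb = ((wb - wb.mean()) ** 2).sum()
            if va <= 0 or vb <= 0:
                return 0.0
            cov = ((wa - wa.mean()) * (wb - wb.mean())).sum()
            return min(1.0, cov ** 2 / (va * vb))

        expected = np.mean([window_cc(i, j, k)
                            for i in range(9) for j in range(9) for k in range(9)])
        got = local_cc(a, b, None, radius=radius)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_empty_mask_rejected(self):
        a = np.ones((8, 8, 8))
        with pytest.raises(ValueError):
            local_cc(a, a, ProbMask(np.zeros((8, 8, 8)), np.eye(4)))


class TestGlobalSsim:
    def test_identical_images_score_one(self, structured_image):
        assert global_ssim(structured_image, structured_image) == pytest.approx(1.0)

    def test_constant_offset_penalised(self, structured_image):
        offset = _img(structured_image.data + 5.0 * np.ptp(structured_image.data),
                      structured_image.affine)
        assert global_ssim(structured_image, offset) < 1.0

    def test_matches_longhand_formula(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(size=(6, 6, 6))
        b = a + 0.1 * rng.normal(size=(6, 6, 6))
        L = max(np.ptp(a), np.ptp(b))
        c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
        mu_a, mu_b = a.mean(), b.mean()
        cov = np.mean((a - mu_a) * (b - mu_b))
        expected = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
            (mu_a ** 2 + mu_b ** 2 + c1) * (a.var() + b.var() + c2))
        assert global_ssim(a, b) == pytest.approx(expected, rel=1e-12)

    def test_equal_constants_return_one(self):
        a = np.full((6, 6, 6), 2.0)
        assert global_ssim(a, a.copy()) == 1.0


class TestMse:
    def test_identical_images_give_zero(self, structured_image):
        assert mse(structured_image, structured_image) == 0.0

    def test_unit_offset_gives_one(self):
        a = np.zeros((6, 6, 6))
        assert mse(a, a + 1.0) == 1.0

    def test_matches_explicit_loop(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(5, 5, 5))
        b = rng.normal(size=(5, 5, 5))
        total = 0.0
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    total += (a[i, j, k] - b[i, j, k]) ** 2
        assert mse(a, b) == pytest.approx(total / 125, rel=1e-12)


# --------------------------------------------------------------------------
# registration benchmark
# --------------------------------------------------------------------------

def _shift_image(img, voxels):
    shift = RigidTransform(tx=voxels * img.voxel_mm[0])
    return apply_transform(img, Transform.from_rigid(shift))


class TestRegistrationBenchmark:
    def test_identical_candidate_attains_ideal_metrics(self, structured_image,
                                                       phantom):
        mask = phantom.brain_mask
        from receptormap.validation import similarity_report

        rep = similarity_report(structured_image, structured_image, mask)
        assert rep.mse == 0.0
        assert rep.gssim == pytest.approx(1.0)
        assert rep.cc == pytest.approx(1.0, abs=1e-9)
        assert rep.mi == pytest.approx(binned_entropy(structured_image, mask),
                                       rel=1e-10)

    def test_metrics_degrade_monotonically_with_misalignment(self,
                                                             structured_image,
                                                             phantom):
        mask = phantom.brain_mask
        mis = [_shift_image(structured_image, v) for v in range(5)]
        from receptormap.validation import similarity_report

        reps = [similarity_report(m, structured_image, mask) for m in mis]
        mi = [r.mi for r in reps]
        cc = [r.cc for r in reps]
        gs = [r.gssim for r in reps]
        ms = [r.mse for r in reps]
        assert all(x >= y - 1e-12 for x, y in zip(mi, mi[1:]))
        assert all(x >= y - 1e-12 for x, y in zip(cc, cc[1:]))
        assert all(x >= y - 1e-12 for x, y in zip(gs, gs[1:]))
        assert all(x <= y + 1e-12 for x, y in zip(ms, ms[1:]))

    def test_aligned_candidate_beats_shifted_everywhere(self, phantom):
        from receptormap import make_phantom, smooth_gaussian

        rng = np.random.default_rng(10)
        refs, aligned, shifted = [], [], []
        for s in range(10):
            truth = make_phantom(seed=200 + s)
            base = smooth_gaussian(Image3D(truth.c_eq_map, truth.affine), 5.0)
            noise = lambda: 0.05 * rng.normal(size=base.shape)
            refs.append(_img(base.data + noise(), base.affine))
            good = _img(base.data + noise(), base.affine)
            aligned.append(good)
            shifted.append(_shift_image(good, 2))
        report = registration_benchmark(refs, {"aligned": aligned,
                                               "shifted": shifted},
                                        mask=phantom.brain_mask)
        scores = report["scores"]
        for s in range(10):
            row_a = scores[(scores.subject == s) & (scores.candidate == "aligned")].iloc[0]
            row_b = scores[(scores.subject == s) & (scores.candidate == "shifted")].iloc[0]
            assert row_a.mi > row_b.mi
            assert row_a.cc > row_b.cc
            assert row_a.gssim > row_b.gssim
            assert row_a.mse < row_b.mse
        tests = report["tests"]
        for metric in ("mi", "mse"):
            p = tests[tests.metric == metric].iloc[0]["p"]
            assert p < 0.05

    def test_mismatched_subject_counts_rejected(self, structured_image):
        with pytest.raises(ValueError):
            registration_benchmark([structured_image],
                                   {"a": [structured_image], "b": []})


class TestWarpEffectTable:
    def test_table_reports_deltas_and_pvalues(self, phantom):
        rng = np.random.default_rng(11)
        n_subj = 6
        native_imgs, warped_imgs = [], []
        for s in range(n_subj):
            base = phantom.true_bpnd_map + 0.02 * rng.normal(size=phantom.labels.shape)
            native_imgs.append(Image3D(base, phantom.affine))
            warped_imgs.append(Image3D(base * (1.0 + 0.03 + 0.01 * rng.normal()),
                                       phantom.affine))
        roi = ProbMask(phantom.gm_prob.data * phantom.region_mask(1).data,
                       phantom.affine)
        rois = {"cortical_gm": [roi] * n_subj}
        table = warp_effect_table(native_imgs, warped_imgs, rois, rois)
        row = table.iloc[0]
        assert row["region"] == "cortical_gm"
        assert row["delta_pct_mean"] == pytest.approx(3.0, abs=1.5)
        assert 0.0 <= row["p_wilcoxon"] <= 1.0
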
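"""Preprocessing, GLM, z maps, smoothness and thresholds."""

import numpy as np
import pytest
from scipy import stats as sps

from cvrpipe import mapping, regional, synthetic


def _series(data, tr=2.0, voxel=3.0, mask=None):
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return mapping.BoldSeries(data=data, tr=tr, voxel_size=(voxel,) * 3, mask=mask)


class TestSmoothSpatial:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        s = _series(rng.normal(size=(8, 8, 8, 5)))
        out = mapping.smooth_spatial(s, 0.0)
        assert np.array_equal(out.data, s.data)

    def test_constant_volume_unchanged_inside_mask(self):
        s = _series(np.full((10, 10, 10, 3), 7.0))
        out = mapping.smooth_spatial(s, 6.0)
        assert np.allclose(out.data[s.mask], 7.0)

    def test_impulse_becomes_gaussian_with_expected_width(self):
        """6 mm FWHM on 3 mm voxels: half maximum one voxel from the peak."""
        data = np.zeros((21, 21, 21, 1))
        data[10, 10, 10, 0] = 1.0
        out = mapping.smooth_spatial(_series(data), 6.0).data[..., 0]
        ratio = out[11, 10, 10] / out[10, 10, 10]
        assert ratio == pytest.approx(0.5, abs=0.03)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            mapping.smooth_spatial(_series(np.zeros((4, 4, 4, 2))), -1.0)


class TestHighpassTemporal:
    def test_linear_drift_removed_mean_preserved(self):
        t = np.arange(100) * 2.0
        drift = 0.5 * t
        data = np.tile(100.0 + drift, (3, 3, 3, 1))
        out = mapping.highpass_temporal(_series(data), sigma_s=1000.0)
        v = out.data[1, 1, 1]
        assert np.allclose(v, v.mean(), atol=1e-6)
        assert v.mean() == pytest.approx(data[1, 1, 1].mean())

    def test_constant_series_unchanged(self):
        data = np.full((3, 3, 3, 50), 42.0)
        out = mapping.highpass_temporal(_series(data), sigma_s=50.0)
        assert np.allclose(out.data, 42.0)

    def test_fast_oscillation_preserved_drift_removed(self):
        """A 20 s sinusoid rides through a sigma=50 s filter within 5%."""
        n, tr = 200, 2.0
        t = np.arange(n) * tr
        sine = np.sin(2 * np.pi * t / 20.0)
        data = (100.0 + 0.2 * t + 3.0 * sine).reshape(1, 1, 1, n)
        out = mapping.highpass_temporal(_series(data, tr=tr), sigma_s=50.0).data[0, 0, 0]
        basis = np.column_stack([np.sin(2 * np.pi * t / 20.0), np.cos(2 * np.pi * t / 20.0)])
        amp = np.hypot(*np.linalg.lstsq(basis, out - out.mean(), rcond=None)[0])
        assert amp == pytest.approx(3.0, rel=0.05)
        # residual drift: correlation with time should be tiny
        assert abs(np.corrcoef(out, t)[0, 1]) < 0.05

    def test_short_sigma_rejected_without_override(self):
        s = _series(np.zeros((2, 2, 2, 30)), tr=2.0)
        with pytest.raises(ValueError):
            mapping.highpass_temporal(s, sigma_s=1.0)
        mapping.highpass_temporal(s, sigma_s=1.0, allow_short=True)


class TestFitGlm:
    def test_noiseless_voxel_recovers_exact_slope(self):
        x = np.array([0.0, 0, 0, 10, 10, 10, 5, 5, 0, 10])
        data = (500.0 * (1 + 0.002 * x)).reshape(1, 1, 1, -1)
        glm = mapping.fit_glm(_series(data), mapping.make_design(x))
        assert glm.beta["petco2"][0, 0, 0] == pytest.approx(1.0)
        assert glm.resid_var[0, 0, 0] == pytest.approx(0.0, abs=1e-18)
        assert glm.dof == len(x) - 2

    def test_two_group_design_matches_closed_form_ols(self):
        """Oracle: hand-computed OLS slope on a 20-volume step design."""
        x = np.concatenate([np.zeros(10), np.full(10, 10.0)])
        rng = np.random.default_rng(3)
        y = 500.0 * (1 + 0.002 * x) + rng.normal(0, 2.0, 20)
        slope_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        glm = mapping.fit_glm(_series(y.reshape(1, 1, 1, -1)), mapping.make_design(x))
        assert glm.beta["petco2"][0, 0, 0] == pytest.approx(slope_oracle, rel=1e-12)

    def test_rank_deficient_design_rejected(self):
        x = np.arange(20.0)
        design = mapping.make_design(x)
        design["dup"] = design["petco2"]
        with pytest.raises(ValueError, match="rank"):
            mapping.fit_glm(_series(np.zeros((2, 2, 2, 20))), design)


class TestCvrAndZ:
    def test_cvr_arithmetic(self):
        x = np.tile([0.0, 10.0], 10)
        data = (500.0 * (1 + 0.002 * x)).reshape(1, 1, 1, -1)  # beta 1.0, baseline ~500
        glm = mapping.fit_glm(_series(data), mapping.make_design(x))
        cvr = mapping.cvr_from_glm(glm)
        assert cvr[0, 0, 0] == pytest.approx(100.0 * 1.0 / data[0, 0, 0].mean(), rel=1e-9)

    def test_noiseless_round_trip_recovers_signed_cvr(self, noiseless_small_run, volume_schedule):
        truth = noiseless_small_run["truth"]["cvr"]
        cvr = noiseless_small_run["cvr"]
        m = noiseless_small_run["glm"].mask
        # percent normalization uses the voxel temporal mean, which sits at
        # the protocol-mean excursion rather than at zero excursion; the
        # noiseless map is exactly truth / (1 + truth/100 * mean(dPetCO2))
        xbar = volume_schedule.mean()
        expected = truth[m] / (1.0 + truth[m] / 100.0 * xbar)
        assert np.allclose(cvr[m], expected, atol=1e-9)
        assert (truth[m] < 0).any()  # the negative focus survives the round trip

    def test_nonpositive_baseline_voxels_dropped(self):
        x = np.tile([0.0, 10.0], 10)
        data = np.zeros((2, 1, 1, 20))
        data[0, 0, 0] = 500.0 * (1 + 0.002 * x)
        data[1, 0, 0] = -5.0
        glm = mapping.fit_glm(_series(data), mapping.make_design(x))
        cvr = mapping.cvr_from_glm(glm)
        assert not glm.mask[1, 0, 0]
        assert np.isnan(cvr[1, 0, 0])

    def test_z_reference_values(self):
        x = np.tile([0.0, 10.0], 30)
        glm = mapping.fit_glm(
            _series(np.zeros((1, 1, 1, 60))), mapping.make_design(x)
        )
        # t = 0 -> z = 0
        assert mapping.zstat_map(glm)[0, 0, 0] == 0.0
        # t -> z mapping at dof 100: 2.5 maps to 2.456
        z = sps.norm.isf(sps.t.sf(2.5, 100))
        assert z == pytest.approx(2.456, abs=5e-4)
        # asymptotic identity: huge dof leaves t unchanged
        assert sps.norm.isf(sps.t.sf(1.96, 10**7)) == pytest.approx(1.96, abs=1e-4)

    def test_z_and_cvr_share_sign(self, recovery_run):
        res = recovery_run["result"]
        m = res.glm.mask & np.isfinite(res.z)
        assert np.all(np.sign(res.z[m]) * np.sign(res.cvr[m]) >= 0)

    def test_cvr_invariant_to_intensity_rescaling(self, volume_schedule):
        phantom = synthetic.default_bold_phantom(shape=(10, 12, 10), seed=2)
        series, _ = synthetic.generate_bold_phantom(phantom, volume_schedule, 2.0)
        design = mapping.make_design(volume_schedule)
        cvr1 = mapping.cvr_from_glm(mapping.fit_glm(series, design))
        scaled = mapping.BoldSeries(series.data * 3.7, series.tr, series.voxel_size, series.mask)
        cvr2 = mapping.cvr_from_glm(mapping.fit_glm(scaled, design))
        m = series.mask
        assert np.allclose(cvr1[m], cvr2[m], rtol=1e-9)


class TestSmoothnessAndThreshold:
    def test_smoothed_noise_fwhm_recovered(self):
        from scipy import ndimage

        rng = np.random.default_rng(1)
        fwhm = 2.0
        sigma = fwhm / np.sqrt(8 * np.log(2))
        res = np.stack(
            [ndimage.gaussian_filter(rng.standard_normal((24, 24, 24)), sigma) for _ in range(8)],
            axis=-1,
        )
        mask = np.zeros((24, 24, 24), dtype=bool)
        mask[4:-4, 4:-4, 4:-4] = True  # avoid filter edge effects
        est = mapping.estimate_smoothness(res, mask)
        for f in est.fwhm:
            assert f == pytest.approx(fwhm, rel=0.10)

    def test_resel_count_is_volume_over_fwhm_product(self):
        est = mapping.SmoothnessEstimate(fwhm=(2.0, 2.0, 2.0), resel_count=1000.0, n_voxels=8000)
        assert est.n_voxels / np.prod(est.fwhm) == pytest.approx(1000.0)

    def test_unsmoothed_noise_resels_near_voxel_count(self):
        rng = np.random.default_rng(2)
        res = rng.standard_normal((16, 16, 16, 10))
        mask = np.ones((16, 16, 16), dtype=bool)
        est = mapping.estimate_smoothness(res, mask)
        assert est.resel_count == pytest.approx(mask.sum(), rel=0.25)

    def test_tiny_mask_rejected(self):
        with pytest.raises(ValueError):
            mapping.estimate_smoothness(np.zeros((2, 2, 2, 4)), np.ones((2, 2, 2), bool))

    def test_resel_bonferroni_reference_thresholds(self):
        one = mapping.SmoothnessEstimate((1.0, 1.0, 1.0), 1.0, 1)
        thr = mapping.resel_corrected_threshold(one, 0.05, method="resel_bonferroni")
        assert thr.z_threshold == pytest.approx(1.960, abs=5e-4)
        big = mapping.SmoothnessEstimate((2.0, 2.0, 2.0), 1000.0, 8000)
        thr = mapping.resel_corrected_threshold(big, 0.05, method="resel_bonferroni")
        assert thr.z_threshold == pytest.approx(4.056, abs=5e-4)
        # fewer comparisons than voxelwise Bonferroni -> lower threshold
        z_vox = sps.norm.isf(0.05 / (2 * 8000))
        assert thr.z_threshold < z_vox

    def test_grf_threshold_solves_expected_ec_equation(self):
        # smooth field where the GRF solution is not Bonferroni-capped
        big = mapping.SmoothnessEstimate((4.0, 4.0, 4.0), 1000.0, 64000)
        thr = mapping.resel_corrected_threshold(big, 0.05, method="grf")
        # independent check: expected Euler characteristic at z* equals alpha
        z = thr.z_threshold
        ec = 2 * 1000.0 * (4 * np.log(2)) ** 1.5 / (2 * np.pi) ** 2 * (z**2 - 1) * np.exp(-z**2 / 2)
        assert ec == pytest.approx(0.05, rel=1e-6)

    def test_grf_threshold_capped_by_voxel_bonferroni(self):
        # barely smooth field: plain Bonferroni is the sharper valid bound
        rough = mapping.SmoothnessEstimate((2.0, 2.0, 2.0), 1000.0, 8000)
        thr = mapping.resel_corrected_threshold(rough, 0.05, method="grf")
        assert thr.z_threshold == pytest.approx(sps.norm.isf(0.05 / (2 * 8000)), rel=1e-9)

    def test_grf_threshold_never_below_single_comparison(self):
        tiny = mapping.SmoothnessEstimate((4.0, 4.0, 4.0), 1.0, 64)
        thr = mapping.resel_corrected_threshold(tiny, 0.05, method="grf")
        assert thr.z_threshold >= sps.norm.isf(0.025) - 1e-12

    def test_alpha_out_of_range_rejected(self):
        est = mapping.SmoothnessEstimate((2.0, 2.0, 2.0), 10.0, 80)
        with pytest.raises(ValueError):
            mapping.resel_corrected_threshold(est, 1.5)


class TestSignificantMask:
    def test_all_zero_z_gives_empty_mask(self):
        z = np.zeros((4, 4, 4))
        assert not mapping.significant_mask(z, z, 1.96).any()

    def test_noiseless_phantom_mask_equals_true_support(self, noiseless_small_run):
        """Zero noise: the significance mask is exactly the nonzero-CVR set."""
        truth = noiseless_small_run["truth"]["cvr"]
        glm = noiseless_small_run["glm"]
        sig = mapping.significant_mask(
            noiseless_small_run["z"], noiseless_small_run["cvr"], 4.0
        )
        assert np.array_equal(sig, glm.mask & (truth != 0))

    def test_sign_selection(self, noiseless_small_run):
        cvr = noiseless_small_run["cvr"]
        z = noiseless_small_run["z"]
        pos = mapping.significant_mask(z, cvr, 4.0, sign="positive")
        neg = mapping.significant_mask(z, cvr, 4.0, sign="negative")
        assert not (pos & neg).any()
        assert np.all(cvr[pos] > 0) and np.all(cvr[neg] < 0)


class TestEndToEndRecovery:
    def test_compartment_means_recovered_within_tolerance(self, recovery_run):
        """1% noise, 6 s delay: tissue CVR means within 0.02 % per mmHg."""
        res = recovery_run["result"]
        truth = recovery_run["truth"]
        labels = recovery_run["phantom"].tissue_labels
        for name, m in regional.tissue_masks(labels).items():
            est, _ = regional.extract_region_cvr(res.cvr, m)
            assert est == pytest.approx(truth["cvr"][m].mean(), abs=0.02), name

    def test_gray_white_ratio_recovered_within_ten_percent(self, recovery_run):
        res = recovery_run["result"]
        truth = recovery_run["truth"]["cvr"]
        tm = regional.tissue_masks(recovery_run["phantom"].tissue_labels)
        gm = tm["gray_matter"] & (truth > 0.2)  # exclude negative foci
        wm = tm["white_matter"] & (truth > 0) & (truth < 0.2)
        ratio = res.cvr[gm].mean() / res.cvr[wm].mean()
        assert ratio == pytest.approx(2.0, rel=0.10)
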
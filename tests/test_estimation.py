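import numpy as np
import pytest

from dwiphantom.estimation import (
    estimate_noise,
    filter_low_signals,
    fit_adc_loglinear,
    fit_adc_ml,
    fit_microstructure,
    fit_microstructure_voxelwise,
    normalize_per_delta,
    roi_average_signals,
)
from dwiphantom.phantom import add_rician_noise, simulate_roi_signals

B_LADDER = np.array([0.0, 150.0, 500.0, 1000.0])


class TestEstimateNoise:
    def _volume(self, protocol, bg_value=1.0, roi_value=30.0):
        K = len(protocol)
        vol = np.full((6, 6, 1, K), bg_value)
        vol[3:5, 3:5] = roi_value
        bg = np.zeros((6, 6, 1), dtype=bool)
        bg[:2, :2] = True
        roi = np.zeros((6, 6, 1), dtype=bool)
        roi[3:5, 3:5] = True
        return vol, bg, roi

    def test_rayleigh_sigma_relation(self, micro_protocol):
        vol, bg, roi = self._volume(micro_protocol)
        est = estimate_noise(vol, bg, roi, micro_protocol)
        assert est.sigma == pytest.approx(np.sqrt(2 / np.pi), rel=1e-12)
        assert est.S_noise == est.S_bg == 1.0

    def test_snr_is_b0_mean_over_sigma(self, micro_protocol):
        sigma = np.sqrt(2 / np.pi)
        vol, bg, roi = self._volume(micro_protocol, roi_value=27.0 * sigma)
        est = estimate_noise(vol, bg, roi, micro_protocol)
        assert est.SNR == pytest.approx(27.0, rel=1e-12)

    def test_empty_or_overlapping_masks_rejected(self, micro_protocol):
        vol, bg, roi = self._volume(micro_protocol)
        with pytest.raises(ValueError):
            estimate_noise(vol, np.zeros_like(bg), roi, micro_protocol)
        with pytest.raises(ValueError):
            estimate_noise(vol, roi, roi, micro_protocol)


class TestADCFitting:
    def test_noiseless_ml_recovery(self):
        sig = 100.0 * np.exp(-B_LADDER * 1.5e-3)
        res = fit_adc_ml(sig[None, :], B_LADDER, sigma=1e-4)
        assert res.converged[0]
        assert res.ADC[0] == pytest.approx(1.5, abs=1e-6)

    def test_ml_less_biased_than_loglinear_at_low_snr(self):
        rng = np.random.default_rng(11)
        sigma, true_adc = 100.0 / 3.0, 1.5
        nu = 100.0 * np.exp(-B_LADDER * true_adc * 1e-3)
        obs = np.sqrt(
            (nu + rng.normal(0, sigma, (300, 4))) ** 2
            + rng.normal(0, sigma, (300, 4)) ** 2
        )
        ml = fit_adc_ml(obs, B_LADDER, sigma)
        ls = fit_adc_loglinear(obs, B_LADDER)
        assert abs(ml.ADC[ml.converged].mean() - true_adc) < abs(ls.ADC.mean() - true_adc)

    def test_ml_agrees_with_least_squares_at_high_snr(self):
        rng = np.random.default_rng(5)
        sigma = 100.0 / 25.0
        nu = 100.0 * np.exp(-B_LADDER * 1.5e-3)
        obs = np.sqrt(
            (nu + rng.normal(0, sigma, (200, 4))) ** 2
            + rng.normal(0, sigma, (200, 4)) ** 2
        )
        ml = fit_adc_ml(obs, B_LADDER, sigma)
        ls = fit_adc_loglinear(obs, B_LADDER)
        assert ml.ADC.mean() == pytest.approx(ls.ADC.mean(), rel=0.01)

    def test_flat_signals_pinned_at_zero_and_flagged(self):
        res = fit_adc_ml(np.full((1, 4), 50.0), B_LADDER, sigma=5.0)
        assert res.ADC[0] == pytest.approx(0.0, abs=1e-6)
        assert res.at_bound[0]

    def test_all_zero_voxel_flagged_not_fit(self):
        res = fit_adc_ml(np.zeros((1, 4)), B_LADDER, sigma=5.0)
        assert not res.converged[0]

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_adc_ml(np.ones((1, 4)), B_LADDER, sigma=0.0)
        with pytest.raises(ValueError):
            fit_adc_ml(np.ones((1, 2)), np.array([0.0, 500.0]), sigma=1.0)


class TestNormalization:
    def test_references_map_to_one_and_are_non_fitting(self, micro_protocol):
        rng = np.random.default_rng(0)
        sig = rng.uniform(0.5, 2.0, len(micro_protocol))
        nset = normalize_per_delta(sig, micro_protocol)
        G = micro_protocol.G_values
        assert np.all(nset.values[G == 0] == 1.0)
        assert not nset.fit_mask[G == 0].any()
        assert nset.fit_mask[G > 0].all()

    def test_amplitude_differences_between_groups_removed(self, micro_model, micro_protocol):
        clean = micro_model.predict(5.2, 0.35, 2.0)
        scaled = clean.copy()
        for Delta, factor in [(12.0, 1.0), (23.0, 0.85), (45.0, 0.68)]:
            idx = micro_protocol.Delta_values == Delta
            scaled[idx] *= factor
        nset = normalize_per_delta(scaled, micro_protocol)
        np.testing.assert_allclose(nset.values, clean, rtol=1e-12)

    def test_missing_reference_rejected(self, micro_protocol):
        keep = [i for i, m in enumerate(micro_protocol) if not (m.Delta == 23.0 and m.G == 0)]
        sub = micro_protocol.subset(keep)
        with pytest.raises(ValueError, match="23"):
            normalize_per_delta(np.ones(len(sub)), sub)


class TestLowSignalFilter:
    def test_all_above_threshold_unchanged(self, micro_protocol):
        sig = np.full(len(micro_protocol), 10.0)
        nset = normalize_per_delta(sig, micro_protocol)
        filtered, report = filter_low_signals(nset, S_noise=1.0)
        assert len(filtered) == len(nset)
        assert report.excluded == ()
        assert report.retained == report.total

    def test_boundary_equality_retained(self, micro_protocol):
        sig = np.full(len(micro_protocol), 10.0)
        # exactly 2*S_noise: the strictly-lower rule keeps the point
        sig[-1] = 2.0
        nset = normalize_per_delta(sig, micro_protocol)
        filtered, report = filter_low_signals(nset, S_noise=1.0)
        assert report.excluded == ()

    def test_only_weakest_entry_removed(self, micro_model, micro_protocol):
        # deep attenuation at the highest G, longest Delta; threshold set to
        # catch exactly that entry
        clean = 100.0 * micro_model.predict(5.2, 0.35, 2.0)
        nset = normalize_per_delta(clean, micro_protocol)
        lowest = clean[nset.fit_mask].min()
        second = np.sort(clean[nset.fit_mask])[1]
        filtered, report = filter_low_signals(nset, S_noise=(lowest + second) / 4.0)
        assert report.excluded == ((210.0, 45.0),)
        assert report.retained + len(report.excluded) == report.total

    def test_everything_below_threshold_is_an_error(self, micro_protocol):
        sig = np.full(len(micro_protocol), 1.0)
        nset = normalize_per_delta(sig, micro_protocol)
        with pytest.raises(ValueError, match="unfittable"):
            filter_low_signals(nset, S_noise=10.0)


class TestMicrostructureFit:
    def test_noise_free_recovery_within_one_percent(self, clean_micro_signals, micro_protocol):
        nset = normalize_per_delta(clean_micro_signals, micro_protocol)
        fit = fit_microstructure(nset, n_starts=50, seed=0)
        assert fit.params.R == pytest.approx(5.2, rel=0.01)
        assert fit.params.f_i == pytest.approx(0.35, rel=0.01)
        assert fit.params.D == pytest.approx(2.0, rel=0.01)
        assert not any(fit.at_bound.values())

    def test_fixed_D_is_returned_exactly(self, clean_micro_signals, micro_protocol):
        nset = normalize_per_delta(clean_micro_signals, micro_protocol)
        fit = fit_microstructure(nset, mode="fixed-D", fixed_D=2.01, n_starts=20, seed=1)
        assert fit.params.D == 2.01

    def test_same_seed_bit_identical(self, clean_micro_signals, micro_protocol):
        sig = np.asarray(
            add_rician_noise(clean_micro_signals, 0.02, np.random.default_rng(3))
        )
        nset = normalize_per_delta(sig, micro_protocol)
        f1 = fit_microstructure(nset, n_starts=30, seed=7)
        f2 = fit_microstructure(nset, n_starts=30, seed=7)
        assert f1.params == f2.params
        assert f1.objective == f2.objective

    def test_objective_non_increasing_in_start_count(self, micro_protocol):
        sig = simulate_roi_signals(micro_protocol, snr=25, seed=12)
        nset = normalize_per_delta(sig, micro_protocol)
        objs = [
            fit_microstructure(nset, n_starts=n, seed=4).objective for n in (1, 5, 25, 100)
        ]
        assert np.all(np.diff(objs) <= 1e-15)

    def test_compiled_and_scipy_engines_agree(self, clean_micro_signals, micro_protocol):
        sig = np.asarray(
            add_rician_noise(clean_micro_signals, 0.02, np.random.default_rng(8))
        )
        nset = normalize_per_delta(sig, micro_protocol)
        fc = fit_microstructure(nset, n_starts=20, seed=2, engine="compiled")
        fs = fit_microstructure(nset, n_starts=20, seed=2, engine="scipy")
        assert fc.objective == pytest.approx(fs.objective, rel=1e-6, abs=1e-12)
        assert fc.params.R == pytest.approx(fs.params.R, rel=1e-3, abs=1e-4)

    def test_mode_argument_contract(self, clean_micro_signals, micro_protocol):
        nset = normalize_per_delta(clean_micro_signals, micro_protocol)
        with pytest.raises(ValueError):
            fit_microstructure(nset, mode="fixed-D")  # fixed_D missing
        with pytest.raises(ValueError):
            fit_microstructure(nset, mode="all-free", fixed_D=2.0)

    def test_all_free_needs_two_delta_values(self, micro_protocol):
        keep = [i for i, m in enumerate(micro_protocol) if m.Delta == 12.0]
        sub = micro_protocol.subset(keep)
        nset = normalize_per_delta(np.ones(len(sub)), sub)
        with pytest.raises(ValueError, match="Delta"):
            fit_microstructure(nset)


class TestRoiAverageAndVoxelwise:
    def test_mean_over_mask(self, micro_protocol):
        K = len(micro_protocol)
        vol = np.zeros((2, 2, 1, K))
        vol[0, 0] = 1.0
        vol[0, 1] = 3.0
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, :2] = True
        np.testing.assert_allclose(roi_average_signals(vol, mask), np.full(K, 2.0))
        with pytest.raises(ValueError):
            roi_average_signals(vol, np.zeros_like(mask))

    def test_single_voxel_mask_matches_direct_fit(self, micro_model, micro_protocol):
        clean = micro_model.predict(5.2, 0.35, 2.0)
        vol = np.zeros((2, 1, 1, len(micro_protocol)))
        vol[0, 0, 0] = 100.0 * clean
        mask = np.zeros((2, 1, 1), dtype=bool)
        mask[0, 0, 0] = True
        maps, summary = fit_microstructure_voxelwise(
            vol, mask, micro_protocol, n_starts=20, seed=5
        )
        nset = normalize_per_delta(vol[0, 0, 0], micro_protocol)
        direct = fit_microstructure(nset, n_starts=20, seed=5)
        assert maps["R"][0, 0, 0] == pytest.approx(direct.params.R, rel=1e-9)
        assert summary.n_voxels == 1
        assert summary.at_bound_fraction["R"] == 0.0

    def test_noisy_voxels_report_at_bound_fraction(self, micro_model, micro_protocol):
        rng = np.random.default_rng(21)
        clean = micro_model.predict(5.2, 0.35, 2.0)
        n = 12
        vol = np.zeros((n, 1, 1, len(micro_protocol)))
        for i in range(n):
            vol[i, 0, 0] = np.asarray(add_rician_noise(100.0 * clean, 4.0, rng))
        mask = np.ones((n, 1, 1), dtype=bool)
        maps, summary = fit_microstructure_voxelwise(
            vol, mask, micro_protocol, n_starts=20, seed=6
        )
        assert summary.n_voxels == n
        assert 0.0 <= summary.at_bound_fraction["R"] <= 1.0
        med_all, _ = summary.median_iqr_all["R"]
        assert np.isfinite(med_all)
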
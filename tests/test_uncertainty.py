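import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dwiphantom.estimation import fit_microstructure, normalize_per_delta
from dwiphantom.phantom import add_rician_noise
from dwiphantom.uncertainty import (
    _resample_residuals,
    cov_percent,
    pearson_correlations,
    r_squared,
    repeatability_metrics,
    residual_bootstrap,
    stereology_correct,
    two_sample_ttest,
)


class TestResidualBootstrap:
    def test_zero_residuals_give_zero_width_intervals(self, clean_micro_signals, micro_protocol):
        nset = normalize_per_delta(clean_micro_signals, micro_protocol)
        fit = fit_microstructure(nset, n_starts=30, seed=0)
        boot = residual_bootstrap(fit, nset, B=25, seed=1, n_starts=3)
        for name in boot.param_names:
            width = boot.ci_upper[name] - boot.ci_lower[name]
            assert width == pytest.approx(0.0, abs=1e-5)

    def test_resampling_never_crosses_delta_strata(self):
        # residual values are disjoint across strata, so any leak is visible
        residuals = np.array([0.01, 0.02, 0.03, 10.0, 20.0, 30.0, -5.0, -6.0, -7.0])
        strata = np.array([12.0] * 3 + [23.0] * 3 + [45.0] * 3)
        rng = np.random.default_rng(0)
        pools = {12.0: {0.01, 0.02, 0.03}, 23.0: {10.0, 20.0, 30.0}, 45.0: {-5.0, -6.0, -7.0}}
        for _ in range(200):
            out = _resample_residuals(residuals, strata, rng)
            for s, pool in pools.items():
                assert set(out[strata == s]).issubset(pool)

    def test_interval_widens_with_noise(self, clean_micro_signals, micro_protocol):
        widths = []
        for sd in (0.005, 0.02):
            diffs = []
            for rep in range(5):
                sig = np.asarray(
                    add_rician_noise(clean_micro_signals, sd, np.random.default_rng(100 + rep))
                )
                nset = normalize_per_delta(sig, micro_protocol)
                fit = fit_microstructure(nset, n_starts=30, seed=rep)
                boot = residual_bootstrap(fit, nset, B=60, seed=rep, n_starts=5)
                diffs.append(boot.ci_upper["f_i"] - boot.ci_lower["f_i"])
            widths.append(np.mean(diffs))
        assert widths[1] > widths[0]

    def test_degenerate_signals_correlate_R_with_volume_fraction(
        self, clean_micro_signals, micro_protocol
    ):
        # larger spheres at higher volume fraction mimic smaller spheres at
        # lower volume fraction: bootstrap samples should show rho(R, f_i) > 0
        sig = np.asarray(
            add_rician_noise(clean_micro_signals, 0.01, np.random.default_rng(42))
        )
        nset = normalize_per_delta(sig, micro_protocol)
        fit = fit_microstructure(nset, n_starts=50, seed=3)
        boot = residual_bootstrap(fit, nset, B=150, seed=4, n_starts=8)
        i, j = boot.param_names.index("R"), boot.param_names.index("f_i")
        assert boot.correlations[i, j] > 0

    def test_requires_two_samples_and_enough_residuals(self, clean_micro_signals, micro_protocol):
        nset = normalize_per_delta(clean_micro_signals, micro_protocol)
        fit = fit_microstructure(nset, n_starts=10, seed=0)
        with pytest.raises(ValueError):
            residual_bootstrap(fit, nset, B=1)

    def test_deterministic_given_seed(self, clean_micro_signals, micro_protocol):
        sig = np.asarray(
            add_rician_noise(clean_micro_signals, 0.02, np.random.default_rng(9))
        )
        nset = normalize_per_delta(sig, micro_protocol)
        fit = fit_microstructure(nset, n_starts=20, seed=0)
        b1 = residual_bootstrap(fit, nset, B=30, seed=5, n_starts=4)
        b2 = residual_bootstrap(fit, nset, B=30, seed=5, n_starts=4)
        np.testing.assert_array_equal(b1.samples, b2.samples)


class TestCov:
    def test_closed_forms(self):
        assert cov_percent([5.0, 5.0, 5.0]) == 0.0
        assert cov_percent([1.0, 2.0, 3.0]) == pytest.approx(50.0, rel=1e-12)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        base = np.array([1.1, 1.4, 0.9, 1.2])
        assert cov_percent(scale * base) == pytest.approx(cov_percent(base), rel=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            cov_percent([1.0])
        with pytest.raises(ValueError):
            cov_percent([-1.0, 1.0])


class TestTTest:
    def test_identical_groups(self):
        t, p = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_separated_groups_highly_significant(self):
        # mirrors a short-vs-long diffusion-time ADC comparison
        rng = np.random.default_rng(1)
        a = rng.normal(1.44, 0.04, 200)
        b = rng.normal(1.20, 0.04, 200)
        _, p = two_sample_ttest(a, b)
        assert p < 1e-3

    def test_antisymmetric_statistic(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 3.0, 5.0]
        t1, p1 = two_sample_ttest(a, b)
        t2, p2 = two_sample_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_group_size_precondition(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_linear_relationships(self):
        x = np.arange(10.0)
        table = np.column_stack([x, 2 * x + 1, -x])
        c = pearson_correlations(table)
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(c), 1.0)
        np.testing.assert_allclose(c, c.T)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        table = rng.normal(size=(10_000, 2))
        assert abs(pearson_correlations(table)[0, 1]) < 0.05

    def test_zero_variance_column_flagged_nan(self):
        table = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        c = pearson_correlations(table)
        assert np.isnan(c[0, 1])
        assert c[1, 1] == 1.0


class TestRSquared:
    def test_extreme_cases(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(obs, obs) == 1.0
        assert r_squared(obs, np.full(4, obs.mean())) == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(4), np.ones(4))


class TestStereology:
    def test_wall_thickness_worked_example(self):
        # 2.1 um mean planar-section thickness -> 1.6 um after pi/4
        assert stereology_correct(2.1) == pytest.approx(1.649, abs=1e-3)
        assert round(stereology_correct(2.1), 1) == 1.6

    def test_identity_and_zero(self):
        assert stereology_correct(0.0) == 0.0
        assert stereology_correct(4.0 / np.pi) == pytest.approx(1.0, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stereology_correct(-0.1)


class TestRepeatability:
    def test_identical_pairs(self):
        assert repeatability_metrics([(1.2, 1.2), (0.9, 0.9)]) == 0.0

    def test_single_pair_closed_form(self):
        assert repeatability_metrics([(1.0, 1.1)]) == pytest.approx(100 * 0.1 / 1.05, rel=1e-9)

    def test_symmetric_in_pair_order(self):
        assert repeatability_metrics([(1.0, 1.3)]) == repeatability_metrics([(1.3, 1.0)])

    def test_positive_values_required(self):
        with pytest.raises(ValueError):
            repeatability_metrics([(0.0, 1.0)])
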
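import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import bisect
from scipy.special import jv, jvp

from dwiphantom.protocol import PGSEMeasurement
from dwiphantom.signals import (
    MicrostructureParams,
    bessel_roots,
    free_signal,
    hindered_signal,
    sphere_signal,
    two_compartment_signal,
)


def sphere_root_equation(x):
    """Independent evaluation of x J'_{3/2}(x) - (1/2) J_{3/2}(x)."""
    return x * jvp(1.5, x) - 0.5 * jv(1.5, x)


class TestBesselRoots:
    def test_first_root_matches_bisection_oracle(self):
        # independent sign-change scan on (0, 4] + bisection to 1e-10
        xs = np.arange(0.05, 4.0, 0.05)
        bracket = next(
            (a, b)
            for a, b in zip(xs[:-1], xs[1:])
            if np.sign(sphere_root_equation(a)) != np.sign(sphere_root_equation(b))
        )
        oracle = bisect(sphere_root_equation, *bracket, xtol=1e-10)
        assert bessel_roots(1).roots[0] == pytest.approx(oracle, abs=1e-8)
        assert oracle == pytest.approx(2.081576, abs=1e-6)

    def test_requested_count_strictly_increasing(self):
        table = bessel_roots(20)
        assert table.count == 20
        assert np.all(table.roots > 0)
        assert np.all(np.diff(table.roots) > 0)

    def test_returned_values_are_roots(self):
        for x in bessel_roots(10).roots:
            assert abs(sphere_root_equation(x)) < 1e-6

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bessel_roots(0)


class TestSphereSignal:
    def test_no_gradient_no_attenuation(self):
        m = PGSEMeasurement(G=0.0, delta=4.0, Delta=12.0)
        assert sphere_signal(m, R=5.0, D=2.0) == 1.0

    def test_free_limit_for_large_sphere_slow_diffusion(self):
        # diffusion length sqrt(2 D Delta) ~ 1.5 um << R = 25 um
        m = PGSEMeasurement(G=210.0, delta=4.0, Delta=12.0)
        s = sphere_signal(m, R=25.0, D=0.1)
        assert s == pytest.approx(free_signal(m.b(), 0.1), rel=0.01)

    def test_long_time_limit_independent_of_Delta(self):
        m45 = PGSEMeasurement(G=100.0, delta=4.0, Delta=45.0)
        m90 = PGSEMeasurement(G=100.0, delta=4.0, Delta=90.0)
        s45 = sphere_signal(m45, R=2.5, D=2.0)
        s90 = sphere_signal(m90, R=2.5, D=2.0)
        assert abs(s45 - s90) < 1e-3

    @pytest.mark.parametrize("R,D", [(0.1, 2.0), (0.1, 1e-3), (5.0, 1e-5)])
    def test_vanishing_restriction_gives_unit_signal(self, R, D):
        m = PGSEMeasurement(G=210.0, delta=4.0, Delta=45.0)
        assert sphere_signal(m, R=R, D=D) == pytest.approx(1.0, abs=1e-3)

    def test_series_truncation_converged_at_20_roots(self, micro_protocol):
        r20, r50 = bessel_roots(20), bessel_roots(50)
        for m in micro_protocol:
            for R in (1.0, 5.0, 12.0, 25.0):
                s20 = sphere_signal(m, R, 2.0, roots=r20)
                s50 = sphere_signal(m, R, 2.0, roots=r50)
                assert abs(s20 - s50) < 1e-6

    def test_invalid_parameters(self):
        m = PGSEMeasurement(G=100.0, delta=4.0, Delta=12.0)
        with pytest.raises(ValueError):
            sphere_signal(m, R=-1.0, D=2.0)
        with pytest.raises(ValueError):
            sphere_signal(m, R=5.0, D=0.0)


class TestHinderedSignal:
    def test_no_obstruction_is_free_diffusion(self):
        # b = 1000 s/mm^2, D = 2 um^2/ms -> exp(-2)
        m = _measurement_with_b(1000.0)
        s = hindered_signal(m, D=2.0, f_i=0.0)
        assert s == pytest.approx(np.exp(-m.b() * 2.0e-3), rel=1e-9)
        assert s == pytest.approx(0.1353, abs=2e-3)

    def test_full_packing_tortuosity(self):
        m = _measurement_with_b(1000.0)
        assert hindered_signal(m, D=2.0, f_i=1.0) == pytest.approx(
            np.exp(-m.b() * 2.0e-3 / 1.5), rel=1e-9
        )

    def test_monotone_increasing_in_volume_fraction(self):
        m = _measurement_with_b(800.0)
        values = [hindered_signal(m, D=2.0, f_i=f) for f in np.linspace(0, 1, 11)]
        assert np.all(np.diff(values) > 0)

    def test_invalid_volume_fraction(self):
        m = _measurement_with_b(500.0)
        with pytest.raises(ValueError):
            hindered_signal(m, D=2.0, f_i=1.5)


def _measurement_with_b(b_target):
    """Measurement at delta=4, Delta=12 whose G is tuned to the requested b."""
    from dwiphantom.protocol import compute_b

    G = np.sqrt(b_target / compute_b(1.0, 4.0, 12.0))
    return PGSEMeasurement(G=G, delta=4.0, Delta=12.0)


class TestTwoCompartment:
    @given(f_i=st.floats(0.05, 0.95), R=st.floats(1.0, 20.0), D=st.floats(0.2, 3.0))
    @settings(max_examples=30, deadline=None)
    def test_convex_combination_between_components(self, f_i, R, D):
        m = PGSEMeasurement(G=140.0, delta=4.0, Delta=23.0)
        s_i = sphere_signal(m, R, D)
        s_e = hindered_signal(m, D, f_i)
        s = two_compartment_signal(m, MicrostructureParams(R, f_i, D))
        assert min(s_i, s_e) - 1e-12 <= s <= max(s_i, s_e) + 1e-12
        assert 0 < s <= 1

    def test_single_compartment_limits(self):
        m = PGSEMeasurement(G=140.0, delta=4.0, Delta=23.0)
        s0 = two_compartment_signal(m, MicrostructureParams(5.0, 1e-12, 2.0))
        assert s0 == pytest.approx(free_signal(m.b(), 2.0), rel=1e-6)
        s1 = two_compartment_signal(m, MicrostructureParams(5.0, 1.0, 2.0))
        assert s1 == pytest.approx(sphere_signal(m, 5.0, 2.0), rel=1e-12)

    def test_unit_signal_without_gradient(self):
        m = PGSEMeasurement(G=0.0, delta=4.0, Delta=23.0)
        assert two_compartment_signal(m, MicrostructureParams(5.0, 0.4, 2.0)) == 1.0


class TestFreeSignal:
    def test_closed_form_values(self):
        assert free_signal(0.0, 2.0) == 1.0
        # free-water diffusivity 2.01 um^2/ms at b = 1000 s/mm^2
        assert free_signal(1000.0, 2.01) == pytest.approx(np.exp(-2.01), rel=1e-12)

    def test_monotone_decreasing_in_b(self):
        values = [free_signal(b, 2.0) for b in np.linspace(0, 2000, 9)]
        assert np.all(np.diff(values) < 0)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            free_signal(-1.0, 2.0)


class TestCompiledPredictor:
    def test_matches_numpy_reference_path(self, micro_model):
        for R, f_i, D in [(5.2, 0.35, 2.0), (0.1, 0.01, 0.1), (25.0, 1.0, 3.0), (12.0, 0.7, 0.5)]:
            fast = micro_model.predict(R, f_i, D)
            ref = micro_model._predict_numpy(R, f_i, D)
            np.testing.assert_allclose(fast, ref, rtol=1e-12, atol=1e-12)

    def test_matches_scalar_operations(self, micro_model, micro_protocol):
        pred = micro_model.predict(5.2, 0.35, 2.0)
        p = MicrostructureParams(5.2, 0.35, 2.0)
        # scalar path truncates the mode series at 1e-8 relative, so agreement
        # is to that order, not machine precision
        for k, m in enumerate(micro_protocol):
            assert pred[k] == pytest.approx(two_compartment_signal(m, p), rel=1e-7)
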
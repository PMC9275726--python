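"""Forward sedimentation model: Stokes kernel, aggregation kinetics,
piecewise curve assembly and the empirical sigmoid comparison fit."""
import numpy as np
import pytest
from scipy.integrate import quad

import esrkit as ek
from esrkit.physics import AggregationState, _curve_pieces

STOKES_DEFAULT = 9.482058878048781e-07  # direct arithmetic on the constants


class TestStokesVelocity:
    def test_default_constants(self, constants):
        assert ek.stokes_velocity(constants) == pytest.approx(STOKES_DEFAULT)

    def test_quadratic_radius_scaling(self, constants):
        doubled = constants.replace(r_ef=2 * constants.r_ef)
        assert ek.stokes_velocity(doubled) == pytest.approx(
            4 * ek.stokes_velocity(constants))

    def test_neutral_buoyancy_rejected(self):
        # equal densities mean no settling; the constants type forbids it
        with pytest.raises(ValueError):
            ek.PhysicalConstants(rho_e=1025.0, rho_p=1025.0)


class TestHinderedFactor:
    @pytest.mark.parametrize("ht,expected", [
        (0.0, 1.0),
        (1.0, 0.0),
        (0.40, 0.0929829486478389),
    ])
    def test_values(self, ht, expected):
        assert ek.hindered_factor(ht) == pytest.approx(expected, rel=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ek.hindered_factor(1.2)


class TestAggregateRadius:
    def test_limits_and_midpoint(self, constants):
        st = AggregationState(alpha=1.0, lam=10.0)
        ref = constants.r_ef
        assert ek.aggregate_radius(0.0, st) == pytest.approx(ref)
        assert ek.aggregate_radius(1e6, st) == pytest.approx(2 * ref)
        assert ek.aggregate_radius(10.0, st) == pytest.approx(
            ref * (2 - np.exp(-1)))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ek.aggregate_radius(-1.0, AggregationState(1.0, 10.0))


class TestVelocities:
    def test_initial_velocity_has_no_aggregation(self, constants):
        st = AggregationState(alpha=2.0, lam=30.0)
        v0 = ek.instantaneous_velocity(0.0, 0.3, st, constants)
        assert v0 == pytest.approx(
            ek.stokes_velocity(constants) * ek.hindered_factor(0.3))

    def test_long_time_limit_is_plateau(self, constants):
        st = AggregationState(alpha=2.0, lam=30.0)
        v_inf = ek.instantaneous_velocity(1e5, 0.3, st, constants)
        assert v_inf == pytest.approx(ek.plateau_velocity(0.3, 2.0, constants))

    def test_velocity_composes_from_radius(self, constants):
        st = AggregationState(alpha=1.5, lam=20.0)
        r = ek.aggregate_radius(20.0, st, constants)
        expected = (ek.stokes_velocity(constants) * ek.hindered_factor(0.3)
                    * (r / constants.r_ef) ** 2)
        assert ek.instantaneous_velocity(20.0, 0.3, st, constants) == \
            pytest.approx(expected, rel=1e-12)

    def test_plateau_scalings(self, constants):
        base = ek.plateau_velocity(0.3, 0.0, constants)
        assert base == pytest.approx(
            ek.stokes_velocity(constants) * ek.hindered_factor(0.3))
        assert ek.plateau_velocity(0.3, 1.0, constants) == pytest.approx(4 * base)
        assert ek.plateau_velocity(0.25, 2.0, constants) == pytest.approx(
            9 * STOKES_DEFAULT * ek.hindered_factor(0.25))

    def test_plateau_monotone_in_alpha_and_ht(self):
        alphas = np.linspace(0.1, 10, 20)
        v = [ek.plateau_velocity(0.3, a) for a in alphas]
        assert np.all(np.diff(v) > 0)
        hts = np.linspace(0.1, 0.5, 20)
        v = [ek.plateau_velocity(h, 2.0) for h in hts]
        assert np.all(np.diff(v) < 0)


class TestLagConstantDistance:
    def test_zero_time(self):
        assert ek.physics.distance_lag_constant(
            0.0, 0.3, AggregationState(1.0, 10.0)) == 0.0

    def test_no_aggregation_is_linear(self, constants):
        st = AggregationState(alpha=0.0, lam=10.0)
        t = 100.0
        expected = ek.stokes_velocity(constants) * ek.hindered_factor(0.3) * t
        assert ek.physics.distance_lag_constant(t, 0.3, st, constants) == \
            pytest.approx(expected, rel=1e-12)

    def test_matches_quadrature_on_grid(self, constants):
        # closed form vs adaptive quadrature of the velocity integrand;
        # certifies the analytic integral's coefficients
        for ht in (0.25, 0.325, 0.40):
            for alpha in (0.5, 3.0, 10.0):
                for lam in (5.0, 30.0, 120.0):
                    st = AggregationState(alpha, lam)
                    for t in (30.0, 600.0, 3600.0):
                        num, _ = quad(ek.instantaneous_velocity, 0.0, t,
                                      args=(ht, st, constants), limit=200)
                        ana = ek.physics.distance_lag_constant(
                            t, ht, st, constants)
                        assert ana == pytest.approx(num, rel=1e-8)

    def test_instant_aggregation_limit(self, constants):
        # lambda -> 0 collapses the lag phase: distance -> plateau * t
        st = AggregationState(alpha=3.0, lam=1e-6)
        t = 600.0
        assert ek.physics.distance_lag_constant(t, 0.3, st, constants) == \
            pytest.approx(ek.plateau_velocity(0.3, 3.0, constants) * t,
                          rel=1e-6)


class TestTransitionTime:
    def test_unit_velocity(self):
        assert ek.transition_time(1.0) == pytest.approx(10.317)

    def test_power_law(self):
        assert ek.transition_time(2.0) == pytest.approx(10.317 * 2**-0.57)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ek.transition_time(0.0)


class TestHInfinity:
    @pytest.mark.parametrize("ht,alpha,expected", [
        (0.25, 1.0, 81.6),
        (0.40, 1.0, 69.36),
    ])
    def test_values(self, ht, alpha, expected):
        assert ek.h_infinity(ht, alpha) == pytest.approx(expected)

    def test_decreasing_in_ht(self):
        hts = np.linspace(0.2, 0.5, 10)
        vals = [ek.h_infinity(h, 2.0) for h in hts]
        assert np.all(np.diff(vals) < 0)

    def test_alpha_edge_cases(self):
        with pytest.raises(ValueError):
            ek.h_infinity(0.3, 0.0)
        with pytest.warns(RuntimeWarning):
            ek.h_infinity(0.3, 0.005)


class TestPackingDistance:
    def test_continuity_asymptote_and_slope(self):
        tau, h_tau, v_tau, h_inf = 10.0, 20.0, 1.5, 80.0
        assert ek.packing_distance(tau, tau, h_tau, v_tau, h_inf) == \
            pytest.approx(h_tau)
        assert ek.packing_distance(1e6, tau, h_tau, v_tau, h_inf) == \
            pytest.approx(h_inf)
        eps = 1e-7
        slope = (ek.packing_distance(tau + eps, tau, h_tau, v_tau, h_inf)
                 - h_tau) / eps
        assert slope == pytest.approx(v_tau, rel=1e-5)

    def test_rejects_inverted_target(self):
        with pytest.raises(ValueError):
            ek.packing_distance(12.0, 10.0, 90.0, 1.0, 80.0)


class TestBuildCurve:
    def test_starts_at_zero_monotone_bounded(self):
        curve = ek.build_curve(0.30, AggregationState(8.0, 20.0))
        assert curve.distances[0] == 0.0
        assert np.all(np.diff(curve.distances) >= 0)
        assert curve.params["h_inf_mm"] is not None
        assert np.all(curve.distances <= curve.params["h_inf_mm"] + 1e-9)

    def test_matches_stepwise_integrator(self, constants):
        # brute-force oracle: forward-Euler velocity integration at
        # dt = 0.01 min switching to the packing relaxation at tau
        ht, st = 0.28, AggregationState(6.0, 25.0)
        _, tau, h_tau, v_tau = _curve_pieces(ht, st, constants)
        h_inf = ek.h_infinity(ht, st.alpha)
        dt = 0.01
        t_grid = np.arange(0.0, 60.0 + 1e-9, dt)
        h = np.zeros_like(t_grid)
        for i in range(1, t_grid.size):
            tm = 0.5 * (t_grid[i - 1] + t_grid[i])
            if tm <= tau:
                v = ek.instantaneous_velocity(tm * 60.0, ht, st, constants) \
                    * 1000.0 * 60.0
            else:
                hm = ek.packing_distance(tm, tau, h_tau, v_tau, h_inf)
                v = v_tau / (h_inf - h_tau) * (h_inf - hm)
            h[i] = h[i - 1] + v * dt
        curve = ek.build_curve(ht, st, constants, t_grid=t_grid)
        assert np.max(np.abs(curve.distances - h)) < 0.05

    def test_lag_regime_only_when_tau_beyond_grid(self):
        # a barely aggregating sample never reaches packing within 60 min
        curve = ek.build_curve(0.40, AggregationState(0.5, 10.0))
        assert curve.params["tau_min"] > 60.0
        assert curve.params["h_inf_mm"] is None


class TestPuccini:
    def test_anchor_points(self):
        assert ek.puccini_eval(0.0, 80.0, 20.0, 3.0) == 0.0
        assert ek.puccini_eval(20.0, 80.0, 20.0, 3.0) == pytest.approx(40.0)
        assert ek.puccini_eval(1e6, 80.0, 20.0, 3.0) == pytest.approx(80.0)

    def test_noiseless_round_trip(self):
        t = np.arange(0.0, 61.0, 1.0)
        curve = ek.SedimentationCurve(
            times=t, distances=ek.puccini_eval(t, 80.0, 20.0, 3.0),
            source="modeled")
        h_inf, t50, beta, resid = ek.fit_puccini(curve)
        assert h_inf == pytest.approx(80.0, rel=1e-6)
        assert t50 == pytest.approx(20.0, rel=1e-6)
        assert beta == pytest.approx(3.0, rel=1e-6)
        assert resid < 1e-6

    def test_quantized_round_trip(self):
        t = np.arange(0.0, 61.0, 1.0)
        h = np.round(ek.puccini_eval(t, 80.0, 20.0, 3.0) / 0.5) * 0.5
        curve = ek.SedimentationCurve(times=t, distances=h, source="measured")
        h_inf, t50, beta, _ = ek.fit_puccini(curve)
        assert h_inf == pytest.approx(80.0, rel=0.02)
        assert t50 == pytest.approx(20.0, rel=0.02)
        assert beta == pytest.approx(3.0, rel=0.02)

    def test_degenerate_curve_rejected(self):
        curve = ek.SedimentationCurve(times=np.arange(5.0),
                                      distances=np.zeros(5),
                                      source="measured")
        with pytest.raises(ValueError):
            ek.fit_puccini(curve)
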
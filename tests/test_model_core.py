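"""Closed-form growth, rate terms, and single-culture integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qsdyn import (
    GrowthParams,
    ModelState,
    QSParams,
    Trajectory,
    gompertz_growth,
    model_rhs,
    rate_terms,
    simulate,
)

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestGompertz:
    def test_limits(self, truth):
        gp, _ = truth
        assert gompertz_growth(-1e6, gp) == pytest.approx(gp.X0, rel=1e-12)
        assert gompertz_growth(1e6, gp) == pytest.approx(gp.X0 + gp.C, rel=1e-12)
        assert gompertz_growth(1e6, gp) == pytest.approx(5.9468, abs=1e-4)

    def test_inflection_value(self, truth):
        # at t = M the double exponential is 1/e
        gp, _ = truth
        expected = gp.X0 + gp.C / np.e
        assert gompertz_growth(gp.M, gp) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.2281, abs=2e-4)

    @given(t1=st.floats(-50, 50), dt=st.floats(1e-6, 50),
           X0=positive, C=positive, B=st.floats(0.01, 5), M=st.floats(0, 10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_nondecreasing(self, t1, dt, X0, C, B, M):
        gp = GrowthParams(X0, C, B, M)
        assert gompertz_growth(t1 + dt, gp) >= gompertz_growth(t1, gp)


class TestRateTerms:
    def test_half_saturation_production(self, truth):
        # at X = km1 the production Hill term is exactly 1/2 for any n1
        _, qp = truth
        r = rate_terms(qp.km1, ModelState(0.0, 0.0), qp)
        assert r.muA == pytest.approx(qp.kA / 2, rel=1e-12)
        assert r.muA == pytest.approx(780.84, rel=1e-6)

    def test_origin_kills_consumption_and_expression(self, truth):
        _, qp = truth
        r = rate_terms(1.0, ModelState(0.0, 0.0), qp)
        assert (r.muXA, r.muLA, r.muL, r.muAL, r.muR) == (0, 0, 0, 0, 0)
        assert r.muA > 0

    def test_lsr_terms_at_unit_scale(self, truth):
        # X = Xdelta, A = L = 1 makes the transporter terms equal their rates
        _, qp = truth
        r = rate_terms(qp.Xdelta, ModelState(1.0, 1.0), qp)
        assert r.muLA == pytest.approx(0.0044, rel=1e-12)
        assert r.muAL == pytest.approx(0.0028, rel=1e-12)

    def test_production_saturates(self, truth):
        _, qp = truth
        r = rate_terms(1000 * qp.km1, ModelState(0.0, 0.0), qp)
        assert r.muA == pytest.approx(qp.kA, rel=1e-3)

    def test_negative_state_rejected(self, truth):
        _, qp = truth
        with pytest.raises(ValueError):
            rate_terms(-0.1, ModelState(0.0, 0.0), qp)
        with pytest.raises(ValueError):
            rate_terms(1.0, (-1.0, 0.0), qp)

    @given(X=st.floats(0, 100), A=st.floats(0, 1e4), L=st.floats(0, 1e4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rates_nonnegative(self, truth, X, A, L):
        _, qp = truth
        r = rate_terms(X, (A, L), qp)
        assert min(r.muA, r.muXA, r.muLA, r.muL, r.muAL, r.muR) >= 0


class TestModelRhs:
    def test_origin_derivative_is_pure_production(self, truth):
        gp, qp = truth
        dA, dL = model_rhs(5.0, ModelState(0.0, 0.0), gp, qp)
        r = rate_terms(float(gompertz_growth(5.0, gp)), ModelState(0, 0), qp)
        assert dA == pytest.approx(r.muA)
        assert dL == 0.0

    def test_origin_fixed_point_without_production(self, truth):
        gp, qp = truth
        silent = qp.replace(kA=1e-300)  # kA must stay positive; effectively 0
        assert model_rhs(5.0, ModelState(0.0, 0.0), gp, silent) == \
            pytest.approx((0.0, 0.0), abs=1e-290)

    @given(A=st.floats(0, 1e4), L=st.floats(0, 1e4), t=st.floats(0, 12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_production_bounds_accumulation(self, truth, A, L, t):
        gp, qp = truth
        X = float(gompertz_growth(t, gp))
        r = rate_terms(X, (A, L), qp)
        dA, _ = model_rhs(t, (A, L), gp, qp)
        assert dA <= r.muA + 1e-12


class TestSimulate:
    def test_origin_invariant_without_production(self, truth):
        gp, qp = truth
        silent = qp.replace(kA=1e-300)
        traj = simulate(gp, silent, np.linspace(0, 12, 25))
        assert np.all(traj.A <= 1e-250)
        assert np.all(traj.L <= 1e-250)

    def test_published_dynamics_shape(self, reference_trajectory):
        """AI-2 rises then is depleted; expression rises then declines."""
        traj = reference_trajectory
        iA = int(np.argmax(traj.A))
        assert 0 < iA < len(traj.times) - 1
        assert traj.A[-1] < 0.05 * traj.peak_A  # depleted by 12 h
        iL = int(np.argmax(traj.L))
        assert 0 < iL < len(traj.times) - 1
        assert traj.L[-1] < traj.peak_L

    def test_growth_column_is_closed_form(self, truth, reference_trajectory):
        gp, _ = truth
        expected = gompertz_growth(reference_trajectory.times, gp)
        assert np.array_equal(reference_trajectory.X, expected)

    def test_nonnegative_states(self, reference_trajectory):
        assert np.all(reference_trajectory.A >= 0)
        assert np.all(reference_trajectory.L >= 0)

    def test_tolerance_convergence(self, truth):
        """Halving solver tolerances moves no reported value by > 1e-4."""
        gp, qp = truth
        grid = np.linspace(0, 12, 121)
        a = simulate(gp, qp, grid)
        b = simulate(gp, qp, grid, rtol=5e-9, atol=5e-11)
        for v in ("A", "L"):
            scale = np.max(np.abs(b.values(v)))
            assert np.max(np.abs(a.values(v) - b.values(v))) / scale < 1e-4

    def test_quadrature_limit_without_uptake(self, truth):
        """With uptake off, A is the integral of the production rate."""
        gp, qp = truth
        no_uptake = qp.replace(kXA=1e-300, kLA=1e-300)
        grid = np.linspace(0, 12, 241)
        traj = simulate(gp, no_uptake, grid)
        dense = np.linspace(0, 12, 20001)
        mu = np.array([rate_terms(float(gompertz_growth(t, gp)),
                                  (0.0, 0.0), qp).muA for t in dense])
        from scipy.integrate import cumulative_trapezoid
        cum = np.concatenate([[0.0], cumulative_trapezoid(mu, dense)])
        oracle = np.interp(grid, dense, cum)
        assert np.allclose(traj.A[1:], oracle[1:], rtol=1e-4)

    def test_response_monotone_in_production_rate(self, truth):
        """Stronger production raises the AI-2 peak and the whole
        accumulation phase.  (Pointwise monotonicity over ALL times does
        not hold: more AI-2 activates the lsr feedback earlier, so the
        depletion flanks of the curves cross.)"""
        gp, qp = truth
        grid = np.linspace(1.0, 12, 45)
        # accumulation phase, feedback still silent; t >= 2 keeps A well
        # above solver round-off (A(1) ~ 1e-16 is integration noise)
        rising = (grid >= 2.0) & (grid <= 3.0)
        prev = None
        for scale in (0.5, 1.0, 2.0):
            traj = simulate(gp, qp.replace(kA=qp.kA * scale), grid)
            if prev is not None:
                assert traj.peak_A > prev.peak_A
                assert np.all(traj.A[rising] > prev.A[rising])
            prev = traj

    def test_grid_validation(self, truth):
        gp, qp = truth
        with pytest.raises(ValueError):
            simulate(gp, qp, [])
        with pytest.raises(ValueError):
            simulate(gp, qp, [0.0, 2.0, 1.0])

    def test_trajectory_roundtrip(self, tmp_path, reference_trajectory):
        p = tmp_path / "traj.csv"
        reference_trajectory.to_csv(p)
        back = Trajectory.from_csv(p)
        assert np.allclose(back.A, reference_trajectory.A)
        assert back.X_ko is None
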
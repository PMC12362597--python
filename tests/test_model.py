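"""Kinetic core: growth-rate balance, closed-form stage solutions, inversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from fedbatch import (
    ConstantFeed,
    ExponentialFeed,
    InfeasibleStrategyError,
    LinearFeed,
    StagePhysiology,
    StageState,
    exponential_feed_start,
    specific_growth_rate,
    stage1_biomass_time_integral,
    stage1_constant,
    stage1_exponential,
    stage1_linear,
    stage1_solve,
    stage2_solve,
    time_for_feed_volume,
)

from conftest import ode_oracle, random_stage_case, strategy_feed_fn

STRATEGY_TYPES = ["constant", "linear", "exponential"]


class TestSpecificGrowthRate:
    def test_all_sinks_zero_direct_substitution(self):
        # no maintenance, no production: mu = y_xs * f*s_f/x
        phys = StagePhysiology(y_xs=0.5, y_ps=1.0)
        assert specific_growth_rate(1.0, 500.0, 500.0, phys) == pytest.approx(0.5)

    def test_feed_exactly_covers_maintenance_and_production(self):
        phys = StagePhysiology(y_xs=0.5, y_ps=0.4, m_s=0.03, beta=0.05)
        c = phys.m_s + phys.beta / phys.y_ps
        x, s_f = 10.0, 500.0
        f = c * x / s_f
        assert specific_growth_rate(f, x, s_f, phys) == pytest.approx(0.0, abs=1e-15)

    @settings(derandomize=True, max_examples=100)
    @given(
        y_xs=st.floats(0.1, 0.8), y_ps=st.floats(0.1, 0.8),
        m_s=st.floats(0.0, 0.1), alpha=st.floats(0.0, 0.5),
        beta=st.floats(0.0, 0.2), f=st.floats(0.001, 1.0),
        x=st.floats(0.5, 200.0), s_f=st.floats(50.0, 800.0),
    )
    def test_mu_solves_the_substrate_balance(self, y_xs, y_ps, m_s, alpha,
                                             beta, f, x, s_f):
        """Re-substituting mu into the implicit balance leaves no residual."""
        phys = StagePhysiology(y_xs=y_xs, y_ps=y_ps, m_s=m_s, alpha=alpha, beta=beta)
        mu = specific_growth_rate(f, x, s_f, phys)

        def balance(m):
            return f * s_f - x * (m / y_xs + (alpha * m + beta) / y_ps + m_s)

        # independent root-find of the same balance
        mu_ref = brentq(balance, -1e6, 1e6, xtol=1e-14, rtol=1e-15)
        assert mu == pytest.approx(mu_ref, rel=1e-12, abs=1e-12)
        assert abs(balance(mu)) <= 1e-12 * max(1.0, f * s_f)

    def test_rejects_bad_inputs(self):
        phys = StagePhysiology(y_xs=0.5, y_ps=0.5)
        with pytest.raises(ValueError):
            specific_growth_rate(float("nan"), 1.0, 500.0, phys)
        with pytest.raises(ValueError):
            specific_growth_rate(0.1, 0.0, 500.0, phys)
        with pytest.raises(ValueError):
            specific_growth_rate(-0.1, 1.0, 500.0, phys)


class TestStage1ClosedForms:
    @pytest.mark.parametrize("strategy_type", STRATEGY_TYPES)
    def test_zero_duration_is_identity(self, strategy_type, phys1, state0):
        _, _, _, strategy = random_stage_case(np.random.default_rng(0), strategy_type)
        out = stage1_solve(strategy, state0, phys1, 500.0, 0.0)
        assert (out.x, out.p, out.v, out.t) == (state0.x, state0.p, state0.v, state0.t)

    def test_constant_feed_degenerate_limit_linear_biomass(self, state0):
        # m_s = beta = alpha = 0: every gram of substrate becomes biomass
        phys = StagePhysiology(y_xs=0.5, y_ps=1.0)
        strat = ConstantFeed(rate=0.1)
        s_f, t = 500.0, 6.0
        out = stage1_constant(strat, state0, phys, s_f, t)
        assert out.x == pytest.approx(state0.x + 0.5 * 0.1 * s_f * t, rel=1e-14)
        assert out.p == state0.p
        assert out.v == pytest.approx(state0.v + 0.1 * t, rel=1e-14)

    def test_constant_feed_relaxes_to_steady_state(self, phys1, state0):
        """Biomass approaches X* = F s_f / c where the feed only covers
        maintenance + production and growth stops."""
        strat = ConstantFeed(rate=0.05)
        s_f = 500.0
        x_star = strat.rate * s_f / phys1.c
        out = stage1_constant(strat, state0, phys1, s_f, 2000.0)
        assert out.x == pytest.approx(x_star, rel=1e-9)
        assert out.mu == pytest.approx(0.0, abs=1e-12)

    def test_linear_with_zero_ramp_equals_constant(self, phys1, state0):
        const = ConstantFeed(rate=0.04)
        lin = LinearFeed(f_start=0.04, ramp=0.0)
        for t in [0.5, 3.0, 12.0]:
            a = stage1_constant(const, state0, phys1, 500.0, t)
            b = stage1_linear(lin, state0, phys1, 500.0, t)
            assert b.x == pytest.approx(a.x, rel=1e-14)
            assert b.p == pytest.approx(a.p, rel=1e-14)
            assert b.v == pytest.approx(a.v, rel=1e-14)
            assert b.mu == pytest.approx(a.mu, rel=1e-12, abs=1e-15)

    def test_linear_feed_that_turns_negative_is_infeasible(self, phys1, state0):
        with pytest.raises(InfeasibleStrategyError):
            stage1_linear(LinearFeed(f_start=0.02, ramp=-0.01), state0,
                          phys1, 500.0, 5.0)

    def test_exponential_growth_rate_is_exact(self, phys1, state0):
        strat = ExponentialFeed(mu_set=0.3)
        for t in [0.1, 1.0, 5.0, 10.0]:
            out = stage1_exponential(strat, state0, phys1, 500.0, t)
            assert out.mu == strat.mu_set  # identically, not approximately
            assert out.x == pytest.approx(state0.x * math.exp(0.3 * t), rel=1e-15)

    def test_exponential_product_and_volume_share_time_dependence(self, phys1, state0):
        """P - P0 and V - V0 are both proportional to exp(mu t) - 1."""
        strat = ExponentialFeed(mu_set=0.25)
        ratios = []
        for t in [0.5, 2.0, 4.0, 8.0]:
            out = stage1_exponential(strat, state0, phys1, 500.0, t)
            ratios.append((out.p - state0.p) / (out.v - state0.v))
        assert np.ptp(ratios) <= 1e-12 * abs(ratios[0])

    def test_exponential_respects_mu_max(self, state0):
        phys = StagePhysiology(y_xs=0.5, y_ps=0.45, mu_max=0.2)
        with pytest.raises(InfeasibleStrategyError):
            stage1_exponential(ExponentialFeed(mu_set=0.3), state0, phys, 500.0, 1.0)

    @pytest.mark.parametrize("strategy_type", STRATEGY_TYPES)
    def test_closed_forms_match_ode_oracle(self, strategy_type):
        """Analytic X/P/V agree with adaptive numeric integration."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            phys, state0, s_f, strategy = random_stage_case(rng, strategy_type)
            feed_fn = strategy_feed_fn(strategy, state0, phys, s_f)
            ts = np.linspace(0.5, 10.0, 5)
            ref = ode_oracle(feed_fn, state0, phys, s_f, ts)
            for i, t in enumerate(ts):
                out = stage1_solve(strategy, state0, phys, s_f, t)
                assert out.x == pytest.approx(ref[0][i], rel=1e-6)
                assert out.p == pytest.approx(ref[1][i], rel=1e-6)
                assert out.v == pytest.approx(ref[2][i], rel=1e-6)

    @pytest.mark.parametrize("strategy_type", STRATEGY_TYPES)
    def test_chaining_equals_direct_solution(self, strategy_type, phys1, state0):
        """Solving to t in one step or via an intermediate stop is identical."""
        _, _, _, strategy = random_stage_case(np.random.default_rng(7), strategy_type)
        s_f = 500.0
        mid = stage1_solve(strategy, state0, phys1, s_f, 3.0)
        chained = stage1_solve(strategy, mid, phys1, s_f, 5.0)
        direct = stage1_solve(strategy, state0, phys1, s_f, 8.0)
        assert chained.x == pytest.approx(direct.x, rel=1e-12)
        assert chained.p == pytest.approx(direct.p, rel=1e-12)
        assert chained.v == pytest.approx(direct.v, rel=1e-12)

    def test_small_c_is_continuous_with_degenerate_branch(self, state0):
        """The c > 0 solution tends to the c = 0 branch as c -> 0."""
        strat = ConstantFeed(rate=0.05)
        base = StagePhysiology(y_xs=0.5, y_ps=0.45)
        out0 = stage1_constant(strat, state0, base, 500.0, 5.0)
        tiny = StagePhysiology(y_xs=0.5, y_ps=0.45, m_s=1e-10)
        out1 = stage1_constant(strat, state0, tiny, 500.0, 5.0)
        assert out1.x == pytest.approx(out0.x, rel=1e-7)
        assert out1.p == pytest.approx(out0.p, rel=1e-6, abs=1e-9)

    @pytest.mark.parametrize("strategy_type", STRATEGY_TYPES)
    def test_per_stage_substrate_conservation(self, strategy_type):
        """Fed substrate = ΔX/y_xs + ΔP/y_ps + m_s ∫X dt, per stage."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            phys, state0, s_f, strategy = random_stage_case(rng, strategy_type)
            t = rng.uniform(1.0, 10.0)
            out = stage1_solve(strategy, state0, phys, s_f, t)
            int_x = stage1_biomass_time_integral(strategy, state0, phys, s_f, t)
            fed = s_f * (out.v - state0.v)
            consumed = ((out.x - state0.x) / phys.y_xs
                        + (out.p - state0.p) / phys.y_ps
                        + phys.m_s * int_x)
            assert abs(fed - consumed) / fed < 1e-8


class TestStage2:
    def test_required_feed_rate_direct_substitution(self):
        phys2 = StagePhysiology(y_xs=1.0, y_ps=0.5, m_s=0.02, beta=0.1)
        state = StageState(t=5.0, x=10.0, p=2.0, v=3.0)
        end, t2 = stage2_solve(state, phys2, 500.0, 0.44)
        assert end.f == pytest.approx(10.0 * (0.02 + 0.2) / 500.0)  # 0.0044 L/h
        assert t2 == pytest.approx(100.0)
        assert end.p - state.p == pytest.approx(0.1 * 10.0 * 100.0)
        assert end.x == state.x
        assert end.mu == 0.0
        assert end.v == pytest.approx(state.v + 0.44)

    def test_zero_remaining_volume_is_identity(self, phys2):
        state = StageState(t=5.0, x=10.0, p=2.0, v=3.0)
        end, t2 = stage2_solve(state, phys2, 500.0, 0.0)
        assert t2 == 0.0
        assert (end.x, end.p, end.v, end.t) == (state.x, state.p, state.v, state.t)

    def test_zero_substrate_demand_cannot_absorb_feed(self):
        inert = StagePhysiology(y_xs=1.0, y_ps=0.5, m_s=0.0, beta=0.0)
        state = StageState(t=5.0, x=10.0, p=2.0, v=3.0)
        with pytest.raises(InfeasibleStrategyError):
            stage2_solve(state, inert, 500.0, 1.0)

    def test_product_increases_linearly_in_time(self, phys2):
        state = StageState(t=0.0, x=10.0, p=0.0, v=3.0)
        volumes = np.linspace(0.1, 1.0, 7)
        points = [stage2_solve(state, phys2, 500.0, v) for v in volumes]
        t2s = np.array([t2 for _, t2 in points])
        ps = np.array([end.p for end, _ in points])
        slopes = np.diff(ps) / np.diff(t2s)
        assert np.allclose(slopes, phys2.beta * state.x, rtol=1e-12)


class TestTimeForFeedVolume:
    def test_constant_rate(self):
        assert time_for_feed_volume(ConstantFeed(2.0), 10.0) == pytest.approx(5.0)

    @pytest.mark.parametrize("strategy_type", STRATEGY_TYPES)
    def test_zero_volume_is_zero_time(self, strategy_type, phys1, state0):
        _, _, _, strategy = random_stage_case(np.random.default_rng(1), strategy_type)
        assert time_for_feed_volume(strategy, 0.0, x0=state0.x, phys=phys1,
                                    s_f=500.0) == 0.0

    @pytest.mark.parametrize("strategy_type", STRATEGY_TYPES)
    def test_inverts_the_cumulative_feed_profile(self, strategy_type, phys1, state0):
        """Re-integrating F over [0, t] recovers the requested volume."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            _, _, s_f, strategy = random_stage_case(rng, strategy_type)
            feed_fn = strategy_feed_fn(strategy, state0, phys1, s_f)
            v_target = rng.uniform(0.05, 2.0)
            t = time_for_feed_volume(strategy, v_target, x0=state0.x,
                                     phys=phys1, s_f=s_f)
            delivered, _ = quad(feed_fn, 0.0, t, epsabs=1e-13, epsrel=1e-13)
            assert delivered == pytest.approx(v_target, rel=1e-10)

    def test_negative_ramp_that_exhausts_the_feed(self):
        # max deliverable volume is f_start^2 / (2 |ramp|) = 0.02 L
        strat = LinearFeed(f_start=0.02, ramp=-0.01)
        with pytest.raises(InfeasibleStrategyError):
            time_for_feed_volume(strat, 0.05)
        t = time_for_feed_volume(strat, 0.015)
        assert 0.0 < t < 2.0  # first crossing, while F is still positive
        assert strat.f_start + strat.ramp * t > 0

    def test_exponential_needs_context(self):
        with pytest.raises(ValueError):
            time_for_feed_volume(ExponentialFeed(0.2), 1.0)


class TestTypeInvariants:
    def test_physiology_rejects_nonpositive_yields(self):
        with pytest.raises(ValueError):
            StagePhysiology(y_xs=-1.0, y_ps=0.5)
        with pytest.raises(ValueError):
            StagePhysiology(y_xs=0.5, y_ps=0.0)
        with pytest.raises(ValueError):
            StagePhysiology(y_xs=0.5, y_ps=0.5, m_s=-0.1)

    def test_strategy_invariants(self):
        with pytest.raises(ValueError):
            ConstantFeed(rate=0.0)
        with pytest.raises(ValueError):
            LinearFeed(f_start=-0.1, ramp=0.0)
        with pytest.raises(ValueError):
            ExponentialFeed(mu_set=-0.2)

    def test_linear_feed_from_constant_biomass_rate(self, phys1):
        """dX/dt = r parameterization maps onto an (f_start, ramp) feed that
        indeed produces a straight biomass trajectory."""
        x0, s_f, r = 20.0, 500.0, 2.0
        strat = LinearFeed.from_biomass_rate(r, x0, phys1, s_f)
        state0 = StageState(t=0.0, x=x0, p=0.0, v=2.0)
        for t in [1.0, 4.0, 9.0]:
            out = stage1_linear(strat, state0, phys1, s_f, t)
            assert out.x == pytest.approx(x0 + r * t, rel=1e-10)
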
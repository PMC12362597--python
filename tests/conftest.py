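"""Shared fixtures and the independent ODE oracle used across the suite."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fedbatch import (
    ConstantFeed,
    ExponentialFeed,
    LinearFeed,
    ProcessSetup,
    StagePhysiology,
    StageState,
    feed_rate_at,
)


@pytest.fixture
def phys1():
    """Generic growth-stage physiology with all kinetic terms active."""
    return StagePhysiology(y_xs=0.5, y_ps=0.45, m_s=0.04, alpha=0.10, beta=0.02)


@pytest.fixture
def phys2():
    """Growth-arrested stage: production is purely non-growth-associated."""
    return StagePhysiology(y_xs=0.5, y_ps=0.50, m_s=0.02, alpha=0.0, beta=0.15)


@pytest.fixture
def setup():
    return ProcessSetup(v0=2.0, x0=20.0, p0=0.0, s_f=500.0, v_max=5.0,
                        f_min=0.0, f_max=1.0)


@pytest.fixture
def state0(setup):
    return StageState(t=0.0, x=setup.x0, p=setup.p0, v=setup.v0)


def ode_oracle(feed_fn, state0, phys, s_f, ts, rtol=1e-11, atol=1e-12):
    """Independent high-accuracy integration of the stage ODE system.

    Integrates dX/dt = mu X, dP/dt = (alpha mu + beta) X, dV/dt = F with mu
    from the quasi-steady-state substrate balance, plus the biomass-time
    integral as a fourth state. Returns arrays (x, p, v, int_x) at ``ts``.
    Deliberately re-states the balance instead of calling the package's
    growth-rate function.
    """
    y_eff = phys.y_xs / (1.0 + phys.alpha * phys.y_xs / phys.y_ps)
    c = phys.m_s + phys.beta / phys.y_ps

    def rhs(t, y):
        x = y[0]
        f = feed_fn(t)
        mu = y_eff * (f * s_f / x - c)
        return [mu * x, (phys.alpha * mu + phys.beta) * x, f, x]

    ts = np.atleast_1d(np.asarray(ts, dtype=float))
    sol = solve_ivp(rhs, (0.0, ts[-1]), [state0.x, state0.p, state0.v, 0.0],
                    method="DOP853", rtol=rtol, atol=atol, t_eval=ts)
    assert sol.success, sol.message
    return sol.y


def random_stage_case(rng, strategy_type):
    """One random valid (phys, state0, s_f, strategy) draw for stage 1."""
    phys = StagePhysiology(
        y_xs=rng.uniform(0.3, 0.6),
        y_ps=rng.uniform(0.2, 0.6),
        m_s=rng.uniform(0.0, 0.05),
        alpha=rng.uniform(0.0, 0.3),
        beta=rng.uniform(0.0, 0.08),
    )
    state0 = StageState(
        t=0.0,
        x=rng.uniform(2.0, 50.0),
        p=rng.uniform(0.0, 5.0),
        v=rng.uniform(0.5, 5.0),
    )
    s_f = rng.uniform(200.0, 600.0)
    if strategy_type == "constant":
        strategy = ConstantFeed(rate=rng.uniform(0.01, 0.2))
    elif strategy_type == "linear":
        strategy = LinearFeed(f_start=rng.uniform(0.005, 0.05),
                              ramp=rng.uniform(0.0, 0.02))
    else:
        strategy = ExponentialFeed(mu_set=rng.uniform(0.05, 0.4))
    return phys, state0, s_f, strategy


def strategy_feed_fn(strategy, state0, phys, s_f):
    """Feed-rate profile of a strategy as a plain callable of stage time."""
    return lambda t: feed_rate_at(strategy, t, x0=state0.x, phys=phys, s_f=s_f)
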
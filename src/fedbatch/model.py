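"""Kinetic core of the two-stage fed-batch (2SFB) model.

The model describes the feed phase of a fed-batch fermentation limited by a
single substrate. The residual substrate concentration is assumed to be ~0
throughout feeding (quasi-steady state): the substrate entering with the feed
is instantaneously partitioned between growth, product formation
(Luedeking-Piret kinetics, ``q_p = alpha*mu + beta``) and cellular
maintenance. With state tracked in absolute amounts (biomass X in g, product
P in g, volume V in L) the balance

    F * s_f = X * (mu / y_xs + (alpha * mu + beta) / y_ps + m_s)

is linear in ``mu``, which makes the stage ODEs

    dX/dt = mu * X = y_eff * (F(t) * s_f - c * X)
    dP/dt = (alpha * mu + beta) * X
    dV/dt = F(t)

linear with

    c     = m_s + beta / y_ps            (zero-growth substrate demand, g/g/h)
    y_eff = y_xs / (1 + alpha * y_xs / y_ps)   (effective biomass yield, g/g)

and therefore solvable in closed form for constant, linear and exponential
feed profiles (stage 1, growth) and for the growth-arrested production stage
(stage 2, ``mu = 0``). Product follows from integrating the Luedeking-Piret
rate: ``P(t) = P0 + alpha * (X(t) - X0) + beta * int_0^t X dtau``.

All quantities use g, L and h. Time ``t`` in the solvers is the duration
since ``state0``; feed laws are evaluated on the stage clock starting at
``state0.t`` so that solving in one step or in several chained steps gives
identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

from .errors import InfeasibleStrategyError

__all__ = [
    "StagePhysiology",
    "ProcessSetup",
    "ConstantFeed",
    "LinearFeed",
    "ExponentialFeed",
    "FeedStrategy",
    "StageState",
    "specific_growth_rate",
    "exponential_feed_start",
    "feed_rate_at",
    "stage1_constant",
    "stage1_linear",
    "stage1_exponential",
    "stage1_solve",
    "stage1_biomass_time_integral",
    "stage2_solve",
    "time_for_feed_volume",
]

# exp(mu*t) beyond this is treated as an infeasible strategy rather than
# letting the closed forms overflow to inf
_EXP_ARG_MAX = 500.0


def _require_finite(**values: float) -> None:
    for name, val in values.items():
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val!r}")


@dataclass(frozen=True)
class StagePhysiology:
    """Host physiology during one feed stage.

    Parameters
    ----------
    y_xs : float
        Biomass yield on substrate, g biomass / g substrate.
    y_ps : float
        Product yield on substrate, g product / g substrate.
    m_s : float
        Maintenance coefficient, g substrate / g biomass / h.
    alpha : float
        Growth-associated specific productivity (g product / g biomass);
        multiplies the specific growth rate.
    beta : float
        Non-growth-associated specific productivity,
        g product / g biomass / h.
    mu_max : float, optional
        Feasibility cap on the specific growth rate (1/h). ``None`` means
        uncapped.
    """

    y_xs: float
    y_ps: float
    m_s: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    mu_max: Optional[float] = None

    def __post_init__(self) -> None:
        _require_finite(y_xs=self.y_xs, y_ps=self.y_ps, m_s=self.m_s,
                        alpha=self.alpha, beta=self.beta)
        if self.y_xs <= 0:
            raise ValueError(f"y_xs must be > 0, got {self.y_xs}")
        if self.y_ps <= 0:
            raise ValueError(f"y_ps must be > 0, got {self.y_ps}")
        if self.m_s < 0:
            raise ValueError(f"m_s must be >= 0, got {self.m_s}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.mu_max is not None and not self.mu_max > 0:
            raise ValueError(f"mu_max must be > 0 if given, got {self.mu_max}")

    @property
    def c(self) -> float:
        """Zero-growth specific substrate demand m_s + beta/y_ps (g/g/h)."""
        return self.m_s + self.beta / self.y_ps

    @property
    def y_eff(self) -> float:
        """Effective biomass yield accounting for growth-coupled production."""
        return self.y_xs / (1.0 + self.alpha * self.y_xs / self.y_ps)


@dataclass(frozen=True)
class ProcessSetup:
    """Reactor and feed constants shared by all simulations.

    ``v0``, ``x0``, ``p0`` describe the broth at the end of the initial batch
    phase (= start of feeding); the batch phase itself is not modelled.
    """

    v0: float  # L, volume at feed start
    x0: float  # g, biomass at feed start
    p0: float  # g, product at feed start
    s_f: float  # g/L, substrate concentration of the feed medium
    v_max: float  # L, final reactor volume
    f_min: float = 0.0  # L/h, lower feasible feed rate
    f_max: float = math.inf  # L/h, upper feasible feed rate

    def __post_init__(self) -> None:
        _require_finite(v0=self.v0, x0=self.x0, p0=self.p0,
                        s_f=self.s_f, v_max=self.v_max, f_min=self.f_min)
        if not self.v0 > 0:
            raise ValueError(f"v0 must be > 0, got {self.v0}")
        if not self.v_max > self.v0:
            raise ValueError(f"v_max must exceed v0, got v_max={self.v_max}, v0={self.v0}")
        if not self.s_f > 0:
            raise ValueError(f"s_f must be > 0, got {self.s_f}")
        if not self.x0 > 0:
            raise ValueError(f"x0 must be > 0, got {self.x0}")
        if self.p0 < 0:
            raise ValueError(f"p0 must be >= 0, got {self.p0}")
        if self.f_min < 0 or not self.f_min < self.f_max:
            raise ValueError(
                f"need 0 <= f_min < f_max, got f_min={self.f_min}, f_max={self.f_max}")

    @property
    def v_feed(self) -> float:
        """Total feed volume delivered over the whole feed phase, L."""
        return self.v_max - self.v0


@dataclass(frozen=True)
class ConstantFeed:
    """Constant feed rate F(t) = rate (L/h)."""

    rate: float

    def __post_init__(self) -> None:
        _require_finite(rate=self.rate)
        if not self.rate > 0:
            raise ValueError(f"ConstantFeed.rate must be > 0, got {self.rate}")


@dataclass(frozen=True)
class LinearFeed:
    """Linearly ramped feed rate F(t) = f_start + ramp * t (L/h).

    ``t`` is time since the start of stage 1. The ramp may be negative as
    long as the feed rate stays positive for the whole stage; solvers raise
    :class:`InfeasibleStrategyError` otherwise.
    """

    f_start: float  # L/h
    ramp: float  # L/h^2

    def __post_init__(self) -> None:
        _require_finite(f_start=self.f_start, ramp=self.ramp)
        if self.f_start < 0:
            raise ValueError(f"LinearFeed.f_start must be >= 0, got {self.f_start}")

    @classmethod
    def from_biomass_rate(cls, r: float, x0: float, phys: "StagePhysiology",
                          s_f: float) -> "LinearFeed":
        """Linear feed giving a constant absolute biomass accumulation rate.

        Imposing ``dX/dt = r`` (g/h) on the substrate balance yields a feed
        linear in time: ``F(t) = (r / y_eff + c * (x0 + r t)) / s_f``. This is
        the "linear growth rate" parameterization; it maps onto the same
        (f_start, ramp) representation.
        """
        if not r > 0:
            raise ValueError(f"biomass accumulation rate must be > 0, got {r}")
        f_start = (r / phys.y_eff + phys.c * x0) / s_f
        ramp = phys.c * r / s_f
        return cls(f_start=f_start, ramp=ramp)

    @classmethod
    def default_f_start(cls, x0: float, phys: "StagePhysiology", s_f: float) -> float:
        """Feed rate that exactly meets the mu = 0 demand of ``x0`` g biomass."""
        return x0 * phys.c / s_f


@dataclass(frozen=True)
class ExponentialFeed:
    """Exponential feed holding the specific growth rate at ``mu_set`` (1/h).

    The initial rate follows from the substrate balance at the stage-start
    biomass; thereafter F(t) = F0 * exp(mu_set * t).
    """

    mu_set: float

    def __post_init__(self) -> None:
        _require_finite(mu_set=self.mu_set)
        if not self.mu_set > 0:
            raise ValueError(f"ExponentialFeed.mu_set must be > 0, got {self.mu_set}")


FeedStrategy = Union[ConstantFeed, LinearFeed, ExponentialFeed]


@dataclass(frozen=True)
class StageState:
    """Instantaneous state of the broth during the feed phase."""

    t: float  # h since feed start
    x: float  # g biomass
    p: float  # g product
    v: float  # L
    f: float = 0.0  # L/h, instantaneous feed rate
    mu: float = 0.0  # 1/h, instantaneous specific growth rate

    def __post_init__(self) -> None:
        _require_finite(t=self.t, x=self.x, p=self.p, v=self.v, f=self.f)
        if not self.x > 0:
            raise ValueError(f"biomass must be > 0, got {self.x}")
        if self.p < 0:
            raise ValueError(f"product must be >= 0, got {self.p}")
        if not self.v > 0:
            raise ValueError(f"volume must be > 0, got {self.v}")
        if self.f < 0:
            raise ValueError(f"feed rate must be >= 0, got {self.f}")


def specific_growth_rate(f: float, x: float, s_f: float,
                         phys: StagePhysiology) -> float:
    """Specific growth rate from the quasi-steady-state substrate balance.

    Solves ``f*s_f = x*(mu/y_xs + (alpha*mu + beta)/y_ps + m_s)`` for ``mu``:

        mu = y_eff * (f * s_f / x - c)

    The result may be negative when the feed does not even cover maintenance
    plus non-growth-associated production; the caller decides whether that is
    infeasible.
    """
    _require_finite(f=f, x=x, s_f=s_f)
    if not x > 0:
        raise ValueError(f"biomass must be > 0, got {x}")
    if f < 0:
        raise ValueError(f"feed rate must be >= 0, got {f}")
    return phys.y_eff * (f * s_f / x - phys.c)


def exponential_feed_start(mu_set: float, x: float, phys: StagePhysiology,
                           s_f: float) -> float:
    """Feed rate sustaining ``mu_set`` at biomass ``x`` (substrate balance)."""
    if not mu_set > 0:
        raise ValueError(f"mu_set must be > 0, got {mu_set}")
    return x * (mu_set / phys.y_xs
                + (phys.alpha * mu_set + phys.beta) / phys.y_ps
                + phys.m_s) / s_f


def feed_rate_at(strategy: FeedStrategy, t: float, *, x0: float = None,
                 phys: StagePhysiology = None, s_f: float = None) -> float:
    """Feed rate of ``strategy`` at stage time ``t``.

    Exponential feeds need the stage-start biomass and physiology to anchor
    F0; constant and linear feeds ignore the keyword context.
    """
    if isinstance(strategy, ConstantFeed):
        return strategy.rate
    if isinstance(strategy, LinearFeed):
        return strategy.f_start + strategy.ramp * t
    if isinstance(strategy, ExponentialFeed):
        if x0 is None or phys is None or s_f is None:
            raise ValueError("exponential feed rate requires x0, phys and s_f")
        f0 = exponential_feed_start(strategy.mu_set, x0, phys, s_f)
        return f0 * math.exp(strategy.mu_set * t)
    raise TypeError(f"unknown feed strategy {strategy!r}")


# ---------------------------------------------------------------------------
# stage-1 closed forms
# ---------------------------------------------------------------------------

def _psi123(z: float):
    """psi_n(z) = (e^{-z} - sum of its first n Taylor terms) / (-z)^n scaled.

    Concretely: psi1 = (1 - e^{-z})/z, psi2 = (e^{-z} - 1 + z)/z^2,
    psi3 = (1 - e^{-z} - z + z^2/2)/z^3, with limits 1, 1/2, 1/6 at z = 0.
    These are the phi-functions of exponential integrators; near z = 0 the
    direct expressions cancel catastrophically, so a truncated alternating
    series (error < z^5/5040) is used instead.
    """
    if z < 0.05:
        psi1 = 1.0 - z / 2.0 + z * z / 6.0 - z ** 3 / 24.0 + z ** 4 / 120.0
        psi2 = 0.5 - z / 6.0 + z * z / 24.0 - z ** 3 / 120.0 + z ** 4 / 720.0
        psi3 = (1.0 / 6.0 - z / 24.0 + z * z / 120.0 - z ** 3 / 720.0
                + z ** 4 / 5040.0)
        return psi1, psi2, psi3
    em = -math.expm1(-z)  # 1 - e^{-z}
    psi1 = em / z
    psi2 = (z - em) / (z * z)
    psi3 = (0.5 * z * z - z + em) / (z ** 3)
    return psi1, psi2, psi3


def _linear_stage_solution(a: float, r: float, state0: StageState,
                           phys: StagePhysiology, s_f: float, t: float):
    """Solve dX/dt = y_eff*(F*s_f - c*X) for F(tau) = a + r*tau on [0, t].

    Variation of constants gives

        X(t)   = X0 e^{-kt} + g (a phi1 + r phi2)
        int X  = X0 phi1    + g (a phi2 + r phi3)

    with k = y_eff*c, g = y_eff*s_f and phi_n(t) = t^n psi_n(k t) the
    exponential-integrator phi functions (phi1' = e^{-kt}, phi_{n+1}' =
    phi_n). The formulation is uniformly accurate in k*t, so the degenerate
    c = 0 case (phi_n = t^n/n!) needs no separate algebra — it falls out of
    the small-argument branch exactly.

    Returns (x, p, v, int_x) at duration t; covers constant feed as r = 0.
    ``a`` is the feed rate at the start of the step.
    """
    g = phys.y_eff * s_f
    k = phys.y_eff * phys.c
    x0, p0, v0 = state0.x, state0.p, state0.v
    psi1, psi2, psi3 = _psi123(k * t)
    phi1 = t * psi1
    phi2 = t * t * psi2
    phi3 = t ** 3 * psi3
    x = x0 * math.exp(-k * t) + g * (a * phi1 + r * phi2)
    int_x = x0 * phi1 + g * (a * phi2 + r * phi3)
    p = p0 + phys.alpha * (x - x0) + phys.beta * int_x
    v = v0 + a * t + 0.5 * r * t * t
    return x, p, v, int_x


def _stage1_solution(strategy: FeedStrategy, state0: StageState,
                     phys: StagePhysiology, s_f: float, t: float):
    """Closed-form stage-1 state after duration ``t`` plus ∫X dtau over the step.

    Returns (StageState, int_x). The feed law clock is ``state0.t`` (time
    since the start of stage 1), so chaining steps reproduces a single step.
    """
    if t < 0:
        raise ValueError(f"duration must be >= 0, got {t}")
    if isinstance(strategy, ConstantFeed):
        x, p, v, int_x = _linear_stage_solution(strategy.rate, 0.0, state0, phys, s_f, t)
        f_end = strategy.rate
    elif isinstance(strategy, LinearFeed):
        a = strategy.f_start + strategy.ramp * state0.t
        f_end = a + strategy.ramp * t
        if a < 0 or (t > 0 and f_end <= 0):
            raise InfeasibleStrategyError(
                f"linear feed rate becomes non-positive on the stage "
                f"(start {a:.4g}, end {f_end:.4g} L/h)")
        x, p, v, int_x = _linear_stage_solution(a, strategy.ramp, state0, phys, s_f, t)
    elif isinstance(strategy, ExponentialFeed):
        mu = strategy.mu_set
        if mu * t > _EXP_ARG_MAX:
            raise InfeasibleStrategyError(
                f"exponential feed overflows: mu_set*t = {mu * t:.3g}")
        f_start = exponential_feed_start(mu, state0.x, phys, s_f)
        em1 = math.expm1(mu * t)
        x = state0.x * (1.0 + em1)
        int_x = state0.x * em1 / mu
        p = state0.p + (phys.alpha * mu + phys.beta) * state0.x * em1 / mu
        v = state0.v + f_start * em1 / mu
        f_end = f_start * (1.0 + em1)
        state = StageState(t=state0.t + t, x=x, p=p, v=v, f=f_end, mu=mu)
        return state, int_x
    else:
        raise TypeError(f"unknown feed strategy {strategy!r}")
    mu_end = specific_growth_rate(f_end, x, s_f, phys)
    state = StageState(t=state0.t + t, x=x, p=p, v=v, f=f_end, mu=mu_end)
    return state, int_x


def stage1_constant(strategy: ConstantFeed, state0: StageState,
                    phys: StagePhysiology, s_f: float, t: float) -> StageState:
    """State after feeding at a constant rate for duration ``t``.

    Biomass relaxes exponentially towards the steady state X* = F*s_f/c at
    which the whole feed is consumed by maintenance and production
    (``X(t) = X* + (X0 - X*)e^{-y_eff c t}``); when c = 0 biomass grows
    linearly instead.
    """
    return _stage1_solution(strategy, state0, phys, s_f, t)[0]


def stage1_linear(strategy: LinearFeed, state0: StageState,
                  phys: StagePhysiology, s_f: float, t: float) -> StageState:
    """State after a linearly ramped feed (integrating-factor solution)."""
    return _stage1_solution(strategy, state0, phys, s_f, t)[0]


def stage1_exponential(strategy: ExponentialFeed, state0: StageState,
                       phys: StagePhysiology, s_f: float, t: float) -> StageState:
    """State after exponential feeding at constant ``mu_set``.

    ``X(t) = X0 e^{mu_set t}`` exactly; feed rate, product and volume all
    share the same ``e^{mu_set t} - 1`` time dependence.
    """
    if phys.mu_max is not None and strategy.mu_set > phys.mu_max:
        raise InfeasibleStrategyError(
            f"mu_set={strategy.mu_set} exceeds mu_max={phys.mu_max}")
    return _stage1_solution(strategy, state0, phys, s_f, t)[0]


def stage1_solve(strategy: FeedStrategy, state0: StageState,
                 phys: StagePhysiology, s_f: float, t: float) -> StageState:
    """Dispatch to the closed-form stage-1 solver for ``strategy``."""
    return _stage1_solution(strategy, state0, phys, s_f, t)[0]


def stage1_biomass_time_integral(strategy: FeedStrategy, state0: StageState,
                                 phys: StagePhysiology, s_f: float,
                                 t: float) -> float:
    """∫ X dtau (g·h) over a stage-1 step of duration ``t`` (closed form)."""
    return _stage1_solution(strategy, state0, phys, s_f, t)[1]


# ---------------------------------------------------------------------------
# stage 2: growth-arrested production
# ---------------------------------------------------------------------------

def stage2_solve(state_switch: StageState, phys2: StagePhysiology, s_f: float,
                 v_remaining: float):
    """Growth-arrested production stage absorbing ``v_remaining`` L of feed.

    With mu = 0, biomass stays at the switch value X_s and the specific
    production rate is the non-growth-associated ``beta``. The substrate
    balance fixes a constant feed rate

        F2 = X_s * (m_s + beta / y_ps) / s_f

    so the stage lasts ``t2 = v_remaining / F2`` and product accumulates
    linearly, ``P_end = P_s + beta * X_s * t2``.

    Returns ``(end_state, t2)``.
    """
    if v_remaining < 0:
        raise ValueError(f"v_remaining must be >= 0, got {v_remaining}")
    f2 = state_switch.x * phys2.c / s_f
    if v_remaining == 0.0:
        return replace(state_switch, f=f2, mu=0.0), 0.0
    if f2 <= 0.0:
        raise InfeasibleStrategyError(
            "growth-arrested stage has zero substrate demand "
            "(m_s = beta = 0) and cannot absorb the remaining feed volume")
    t2 = v_remaining / f2
    end = StageState(
        t=state_switch.t + t2,
        x=state_switch.x,
        p=state_switch.p + phys2.beta * state_switch.x * t2,
        v=state_switch.v + v_remaining,
        f=f2,
        mu=0.0,
    )
    return end, t2


# ---------------------------------------------------------------------------
# feed-volume -> time conversion
# ---------------------------------------------------------------------------

def time_for_feed_volume(strategy: FeedStrategy, v_target: float, *,
                         x0: float = None, phys: StagePhysiology = None,
                         s_f: float = None) -> float:
    """Duration needed for ``strategy`` to deliver ``v_target`` L of feed.

    Inverts ``∫_0^t F(tau) dtau = v_target`` in closed form per strategy.
    Exponential feeds need ``x0``/``phys``/``s_f`` to anchor the initial feed
    rate. Raises :class:`InfeasibleStrategyError` when no positive solution
    exists (e.g. a negative ramp exhausts the feed first).
    """
    if v_target < 0:
        raise ValueError(f"v_target must be >= 0, got {v_target}")
    if v_target == 0.0:
        return 0.0
    if isinstance(strategy, ConstantFeed):
        return v_target / strategy.rate
    if isinstance(strategy, LinearFeed):
        a, r = strategy.f_start, strategy.ramp
        if a == 0.0 and r <= 0.0:
            raise InfeasibleStrategyError("linear feed never delivers any volume")
        disc = a * a + 2.0 * r * v_target
        if disc <= 0.0:
            # the ramp drives F to zero before v_target is reached
            raise InfeasibleStrategyError(
                f"negative ramp exhausts the feed before delivering {v_target} L "
                f"(max deliverable {a * a / (-2.0 * r):.6g} L)")
        # first positive root of (r/2) t^2 + a t - v = 0, stable for r -> 0
        return 2.0 * v_target / (a + math.sqrt(disc))
    if isinstance(strategy, ExponentialFeed):
        if x0 is None or phys is None or s_f is None:
            raise ValueError("exponential feed volume inversion requires x0, phys, s_f")
        f0 = exponential_feed_start(strategy.mu_set, x0, phys, s_f)
        if f0 <= 0.0:
            raise InfeasibleStrategyError("exponential feed has zero initial rate")
        return math.log1p(strategy.mu_set * v_target / f0) / strategy.mu_set
    raise TypeError(f"unknown feed strategy {strategy!r}")
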
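# Methods

## Process model

The engine models the *feed phase* of a fed-batch fermentation in a
spatially homogeneous stirred-tank reactor limited by one substrate. The
initial batch phase is not simulated: the user supplies the broth state at
the start of feeding (biomass `x0` g, product `p0` g, volume `v0` L), which
is where design decisions about feeding begin. Volume changes from
evaporation, sampling and base addition are ignored.

### Quasi-steady-state substrate balance

The residual substrate concentration is taken as ≈ 0 throughout feeding:
substrate is consumed as fast as it arrives. The feed `F` (L/h) at
concentration `s_f` (g/L) therefore partitions instantaneously between
growth, production and maintenance,

    F s_f = X (mu / y_xs + (alpha mu + beta) / y_ps + m_s),

with Luedeking–Piret production kinetics `q_p = alpha mu + beta`. Solving
for the specific growth rate gives

    mu = y_eff (F s_f / X - c),
    c = m_s + beta / y_ps,            # specific demand at mu = 0, g/g/h
    y_eff = y_xs / (1 + alpha y_xs / y_ps).

`c` is the substrate demand per gram of biomass when growth stops; `y_eff`
is the biomass yield corrected for the substrate channelled into
growth-coupled production. `mu` may come out negative (feed below the
zero-growth demand); the kinetic layer returns it as-is and the process
layer declares such strategies infeasible — the model contains no
biomass-decay term, so sustained underfeeding is outside its validity.

### Stage 1 closed forms

Substituting `mu` into `dX/dt = mu X` yields the linear ODE
`dX/dt = y_eff (F(t) s_f - c X)`. With `k = y_eff c`, `g = y_eff s_f` and a
feed `F(t) = a + r t`, variation of constants gives

    X(t)    = X0 e^{-kt} + g (a phi1 + r phi2),
    ∫X dt   = X0 phi1    + g (a phi2 + r phi3),
    phi_n(t) = t^n psi_n(k t),

where `psi1 = (1-e^{-z})/z`, `psi2 = (e^{-z}-1+z)/z^2`,
`psi3 = (1-e^{-z}-z+z^2/2)/z^3` are the phi-functions of exponential
integrators. Product follows by integrating the production rate:
`P = P0 + alpha (X - X0) + beta ∫X dt`. The constant feed is the `r = 0`
case; its familiar form is relaxation towards the stationary biomass
`X* = F s_f / c` at which the feed exactly covers maintenance plus
production.

For the exponential feed the set-point `mu_set` is imposed instead: the
balance fixes `F(t) = F0 e^{mu_set t}` with `F0` evaluated at the
stage-start biomass, and `X = X0 e^{mu_set t}` holds exactly; `P - P0`,
`V - V0` and `∫X` all share the factor `(e^{mu_set t} - 1)/mu_set`.

Numerical choices:

- The phi-functions switch to truncated alternating series for `k t < 0.05`
  (truncation error < `(kt)^5/5040`), which removes the catastrophic
  cancellation of the naive `X* + (X0 - X*)e^{-kt}` form for small `c` and
  makes the degenerate case `c = 0` (no maintenance, no non-growth
  production — biomass linear in cumulative feed) the exact `z = 0` limit of
  the same expressions rather than a separately derived branch.
- `expm1`/`log1p` are used wherever `e^x - 1` appears (exponential stage,
  feed-volume inversion).
- `exp(mu_set t)` arguments beyond 500 are rejected as infeasible rather
  than allowed to overflow.
- Solvers interpret time as duration since the given start state while the
  feed law runs on the stage clock, so solving a stage in one step or in
  chained steps is algebraically identical (the semigroup property the test
  suite checks).

Substrate is conserved *exactly* by construction: per stage,
`s_f ΔV = ΔX/y_xs + ΔP/y_ps + m_s ∫X dt` holds algebraically, and
`substrate_audit` verifies it to machine precision on every trajectory. The
audit exists to catch implementation defects and to validate numerically
integrated stages, not because the balance could drift.

### Stage 2 (growth arrest)

With `mu = 0`, biomass is constant, the required feed is the constant
`F2 = X c2 / s_f`, the stage duration is `t2 = v_remaining / F2` and product
accumulates linearly at `beta2 X`. If the stage-2 physiology has
`m_s = beta = 0` the stage cannot absorb any feed volume and is flagged
infeasible. Stage-1 and stage-2 physiologies are independent parameter sets
and are never mixed.

## Process assembly and TRY metrics

A process is specified by the feed strategy and `frac1`, the fraction of the
total feed volume `v_feed = v_max - v0` delivered during stage 1. The switch
time follows from inverting the cumulative feed profile in closed form
(linear feeds via the numerically stable root `t = 2v/(a + sqrt(a^2+2rv))`).
Holding total feed volume — hence total substrate — fixed across all
candidate processes makes comparisons fair and forces
`yield = titer * v_end / (s_f v_feed)`: yield is a fixed multiple of titer,
so the max-titer and max-yield designs coincide.

Metrics cover the feed phase only: `titer = P_end/V_end`,
`rate = titer/(t1+t2)`, `yield = P_end/(s_f v_feed)`. An optional
`batch_time_h` adds a fixed batch duration to the rate denominator for
comparison with literature figures that count the batch phase; it never
affects titer, yield, or which grid cell is optimal at fixed batch time.
The yield denominator is feed substrate only; substrate consumed during the
batch phase is out of scope.

Feasibility is enforced at the process layer: `mu >= 0` everywhere,
`mu <= mu_max` when a cap is given, and `f_min <= F <= f_max` in both
stages. All three feed laws are monotone in time, so feed bounds are checked
at stage endpoints; `mu` is additionally checked on the sampled trajectory
(default 200 points per stage) because for ramped feeds it need not be
monotone. Infeasible processes return a reason code
(`negative_growth`, `feed_bound`, `mu_max_exceeded`, `stage2_zero_demand`,
`feed_volume_unreachable`) instead of raising, so grids stay rectangular.
Trajectory sampling is for reporting and `mu` screening only — metrics
always come from the exact endpoint formulas.

## Grid search

Axes are linearly spaced by default (log spacing available); the default
resolution is 50×50 and the fraction axis spans [0.05, 1.0] *including* the
one-stage endpoint, so "one stage beats two stages" outcomes are
representable. The optimum is the argmax of rate (or titer) over feasible
cells; exact ties break towards the lowest feed parameter, then the lowest
`frac1`, preferring gentler feeding, which is easier to run stably. The
productivity–titer trade-off is exported both as per-feed-parameter curves
and as the Pareto-nondominated subset. The engine contains no randomness;
identical inputs give identical results.

The linear strategy is parameterized by its ramp, with the start rate
defaulting to the `mu = 0` demand of the initial biomass
(`f_start = x0 c1 / s_f`) so that the ramp axis alone spans the design space
without starving the culture at `t = 0`. An alternative constructor
(`LinearFeed.from_biomass_rate`) expresses the same feed family via a
constant absolute biomass accumulation rate `dX/dt = r`, which also yields a
feed linear in time.

## Synthetic presets and what tests show

The bundled presets (`ecoli-synthetic`, `yeast-synthetic`) are illustrative
fixtures: yields, maintenance and productivities sit in the ranges tabulated
for glucose-grown *E. coli* and *S. cerevisiae* (e.g. `y_xs` ≈ 0.45–0.5 g/g,
`m_s` a few × 0.01 g/g/h), reactor volumes and pump limits are lab scale,
but no value was estimated from a specific strain's data. They exercise the
full pipeline — including mixed feasible/infeasible grids — and demonstrate
qualitative phenomena such as the one-stage/two-stage crossover as the
growth-decoupled production rate increases. Passing tests therefore
establish the internal correctness of the mathematics and bookkeeping, not
the predictive accuracy of any particular parameter set; real design
decisions require host parameters estimated from experimental data.

The synthetic-data side of testing draws random stage parameters from broad
plausible ranges (`y_xs` 0.3–0.6, `y_ps` 0.2–0.6, `m_s` 0–0.05 g/g/h,
`alpha` 0–0.3, `beta` 0–0.08 g/g/h, feed rates 0.01–0.2 L/h, `mu_set`
0.05–0.4 1/h) and compares every closed form against independent
high-accuracy ODE integration (`DOP853`, rtol 1e-11) that restates the
substrate balance rather than importing the package's growth-rate function.
What these draws do not emulate: measurement noise, parameter drift within a
stage, substrate accumulation/overflow metabolism, oxygen-transfer limits,
or biomass death — all outside the model's assumptions.

## Problem sizes

The default test suite and the acceptance script run at desk scale: 100
random draws per strategy × 5 time points for the oracle comparison, 20×20
to 50×50 grids for the landscape properties, a 14-point `beta2` sweep on a
6×96 grid for the crossover. These sizes were chosen because the measured
quantities (closed-form vs ODE error ~1e-10, conservation residuals ~1e-16)
are already far below their tolerances and do not change with more draws.

## Known limitations

- No Monod/substrate-accumulation kinetics: the quasi-steady-state
  assumption fails if feed exceeds the culture's uptake capacity; the
  `mu_max` cap is a feasibility screen, not a saturation model.
- No dynamic feed control; only constant/linear/exponential stage-1 laws
  have closed forms (arbitrary profiles via the numeric integrator).
- Two stages only; growth arrest is assumed instantaneous and complete
  (`mu = 0` exactly in stage 2).
- Parameter estimation from experimental data is out of scope; the package
  consumes already-estimated physiological parameters.
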
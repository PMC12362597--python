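# fedbatch

Design and optimization of **two-stage fed-batch (2SFB) fermentations** — a
growth stage followed by a growth-arrested production stage — for bioprocess
engineers who want to pick a feeding strategy and a switching point before
committing to bioreactor runs.

Many modern bioprocesses decouple growth from production: biomass is built up
first (stage 1), then growth is arrested (nutrient starvation, microaerobic
shift, induced inhibition) and the cells convert substrate into product at a
non-growth-associated rate (stage 2). The central design question is the
trade-off between the **TRY metrics**: **T**iter (final product
concentration, g/L), **R**ate (space-time yield: titer divided by process
time, g/L/h) and **Y**ield (product per substrate, g/g). A longer growth
stage boosts productivity; a longer production stage boosts titer and yield.

## Model

State is tracked in absolute amounts: biomass *X* (g), product *P* (g),
volume *V* (L). The limiting substrate is assumed fully consumed as it is
fed (residual concentration ≈ 0), so the feed *F* (L/h) with substrate
concentration *s*<sub>F</sub> (g/L) partitions instantaneously between
growth, production and maintenance:

```
F·s_F = X·( μ/Y_XS + q_p/Y_PS + m_s ),      q_p = α·μ + β
```

where *Y*<sub>XS</sub>, *Y*<sub>PS</sub> are the biomass and product yields
on substrate (g/g), *m*<sub>s</sub> is the maintenance coefficient (g/g/h)
and the specific production rate *q*<sub>p</sub> follows Luedeking–Piret
kinetics with a growth-associated coefficient α (g/g) and a
non-growth-associated rate β (g/g/h). Solving the balance for μ makes the
stage ODEs *dX/dt = μX*, *dP/dt = q*<sub>p</sub>*X*, *dV/dt = F* **linear**,
with closed-form solutions for

- **constant** feed *F(t) = F*,
- **linear** feed *F(t) = F*<sub>0</sub> *+ r·t*,
- **exponential** feed holding μ at a set-point (*X = X*<sub>0</sub>*e*<sup>μt</sup>).

In stage 2, μ = 0: the required feed rate is constant
(*F*<sub>2</sub> *= X·(m*<sub>s</sub> *+ β/Y*<sub>PS</sub>*)/s*<sub>F</sub>)
and product accumulates linearly at β·*X*. Host parameters may differ
between the two stages.

The grid search sweeps the stage-1 feed parameter against the **fraction of
the total feed volume delivered in stage 1**. Every simulated process spends
the same substrate and ends at the same volume, so yield is a fixed linear
function of titer and comparisons are fair; the optimum (by rate or titer)
and the productivity–titer Pareto frontier are reported. A numeric
integrator (`numeric_stage_integrate`) accepts arbitrary feed profiles —
it is the extension point for new strategies and the test oracle for the
closed forms.

## Worked example

Two synthetic presets (an *E. coli*-like and an *S. cerevisiae*-like host;
illustrative fixtures, not measured strain data) ship with the package:

```sh
$ fedbatch grid --preset ecoli-synthetic --out grid.csv --summary best.csv
feasible cells: 1650 / 2500
optimum (rate): param = 0.0557143, frac1 = 0.2633
  titer = 111.305 g/L, rate = 2.98056 g/L/h, yield = 0.371016 g/g
```

Reading: on a 50×50 grid of constant feed rates (0.01–0.08 L/h) × stage-1
feed-volume fractions, 1650 combinations satisfy the constraints (feed-rate
bounds, non-negative growth, μ ≤ μ<sub>max</sub>). The most productive
process feeds at 0.0557 L/h, switches to the growth-arrested stage after
26.3 % of the feed volume, and reaches 111.3 g/L at 2.98 g/L/h with a yield
of 0.371 g product per g substrate. `grid.csv` holds every cell (infeasible
ones keep their reason code); `best.csv` the optimum row.

A single process, with time traces:

```sh
$ fedbatch simulate --preset ecoli-synthetic --strategy exponential \
      --mu-set 0.3 --frac1 0.4 --trace trace.csv
t1 = 8.545 h, t2 = 10.83 h
titer = 92.3632 g/L
rate  = 4.76655 g/L/h
yield = 0.307877 g/g
```

The same API is available from Python (`fedbatch.simulate_process`,
`fedbatch.evaluate_grid`, `fedbatch.select_optimum`,
`fedbatch.tradeoff_frontier`); custom hosts are described in a small YAML
file (`fedbatch.load_config`, schema documented in
`fedbatch/config.py`). All units are g, L, h throughout.

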
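# Methods

## Model structure

The store is a semi-batch reactor. The continuous state is

| pool | symbol | units |
|---|---|---|
| slurry mass | $M_m$ | kg |
| degradable particulate COD | $S_p$ | g COD-S |
| volatile fatty acids | VFA | g COD-S |
| sulfate | $SO_4$ | g SO₄-S |
| dissolved sulfide | — | g S |
| total ammoniacal N | TAN | g N |
| biomass, one per group | $X_i$ | g COD-B |
| cumulative CH₄, CO₂, emitted H₂S | — | g |

plus four audit accumulators (inflow COD, respired COD, inflow S, inflow
TAN) integrated alongside the state so that COD, sulfur and nitrogen
balances can be closed after the fact without re-integrating.

Eight processes act on the state, assembled Petersen-matrix style: (1)
first-order hydrolysis/fermentation $\alpha(T) S_p$ into VFA; (2) Monod VFA
uptake by each methanogen group with yield $Y_i$, CH₄ productivity
$P_{CH_4} = (1-Y)/4$ and a lumped anaerobic CO₂ coefficient; (3) double-Monod
sulfate reduction transferring sulfur to sulfide at $f_{COD\text{-}S,sulfur}$
per g COD; (4) O₂-transfer-limited aerobic respiration of $S_p$ at the
surface; (5) H₂S volatilization proportional to area and to the unionized
aqueous concentration; (6, 7) first-order biomass decay recycled into $S_p$;
(8) inflow at $F_{in}$ with fixed influent concentrations. Monod terms use
concentrations formed as pool / current $M_m$ (g per kg slurry), recomputed
continuously — the consistent reading when slurry mass changes during a fill.

Counters for emitted gases are global; per-cycle figures are derived by
differencing, never by resetting state mid-run.

### Temperature responses

Both $\alpha$ and every $q_{max,i}$ follow CTM1, parameterised by
$(T_{min}, T_{opt}, T_{max})$ and the rate at the optimum. The raw CTM1
polynomial changes sign outside the cardinal interval; the implementation
clamps the rate to zero there, since there is no biological activity beyond
the cardinal limits. The half-saturation constant falls exponentially with
temperature, $K_S = K_{S,coef}\, k_1 e^{-k_2 T}$, shared across groups up to
the dimensionless per-group multiplier $K_{S,coef}$.

### Inhibition

Each group's uptake is multiplied by four factors in $[0,1]$: a two-sided pH
limit function (lower/upper bound form common in anaerobic-digestion models,
rescaled so it equals exactly 1 at the group's pH optimum) and
noncompetitive terms $1/(1 + C/K_I)$ for free ammonia, ammonium and
unionized H₂S. The forms are pluggable per group through
`InhibitionConstants`; the shipped constants (pH bounds 6.0–8.5 for
methanogens, 5.0–8.5 for the sulfate reducer; $K_I$ = 0.10 g NH₃-N kg⁻¹,
5.0 g NH₄-N kg⁻¹, 0.10 g H₂S-S kg⁻¹) are literature-informed placeholders,
overridable in the scenario config.

Speciation uses van 't Hoff-type pKa laws in absolute temperature: NH₄⁺
pKa $= 0.09018 + 2729.92/T_K$ (≈9.25 at 25 °C) and H₂S pKa₁
$= 2.527 + 1359.96/T_K$ (≈7.09 at 25 °C); coefficients are module constants
a config can override.

### Management

In threshold mode removal fires exactly when $M_m = M_{m,max}$, located by
the ODE solver's event root-finder (tolerance 10⁻⁶ d). Solute and substrate
pools scale by $f_{resid}$; each biomass pool by
$\mathrm{logistic}(\mathrm{logit}(f_{resid}) + a_{enrich})$. In
forced-mass-series mode an imposed slurry-mass series drives the run:
increases between series breakpoints become constant inflow over the
interval, decreases are applied as a single removal event at the start of
the interval with the retained fraction inferred from the series. With
daily-resolution series this start-of-interval convention displaces a
removal by at most one day.

The default initial state is the post-removal store,
$M_m(0) = f_{resid} M_{m,max}$, at influent composition — this makes the
default scenario periodic from the first cycle, and is overridable.

## Default parameter set

Values marked *fixed* are model constants of the default set; *placeholder*
values are the package's own literature-informed choices, all exposed in the
scenario config.

| parameter | default | status |
|---|---|---|
| $Y_i$ (methanogens) | 0.05 g COD-B/g COD-S | fixed |
| $\alpha_{opt}$; cardinal (0, 50, 60) °C | 0.02 d⁻¹ | fixed |
| $q_{max,opt}$ rule | $8\,T_{opt}/40$ | fixed |
| influent biomass | m3: 0.01, others: 0.001 g COD-B/kg | fixed |
| VS conversion | degradable fraction 0.42; 1.42 g COD/g VS | fixed |
| management | $F_{in}$ 1000 kg/d, $M_{m,max}$ 33333 kg, $f_{resid}$ 0.1 | fixed |
| cardinal temps m1…m5 | (0,18,25), (0,28,38), (10,37,45), (12.5,43.5,52), (15,50,58) °C | placeholder |
| sulfate reducer sr1 | (10,38,46) °C, $Y$ 0.077, $q_{max,opt}$ ×1.2 | placeholder |
| $k_d$ | 0.02 d⁻¹ | placeholder |
| $k_1, k_2$ | 1.0 g COD-S/kg, 0.05 °C⁻¹ | placeholder |
| transfer | area 17 m², $k_{L,O_2}$ 0.2 m/d, $0.208/k_{H,O_2}$ = 9 g O₂/m³, $k_{L,H_2S}$ 14 kg m⁻² d⁻¹ | placeholder |
| influent chemistry | $S_p$ 47.7, VFA 2.0 g COD/kg; SO₄ 0.2 g S/kg; TAN 2.0 g N/kg | placeholder |

Group temperature optima follow the species each group emulates (m1
*Methanolobus psychrophilus*, m2 *Methanosarcina soligelidi*, m3
*Methanobrevibacter*/*Methanocorpusculum*, m5 *Methanosarcina thermophila*;
m4 sits midway between m3 and m5). $C_{Sp,in}$ is 80 g VS/kg fresh cattle
slurry put through the VS→COD conversion. The sulfur transfer coefficient
defaults to $(1-Y_{sr})/2$ g S per g COD rather than the pure acetate value
of 0.5, so that sulfide (2 g COD per g S) plus sulfate-reducer biomass
exactly account for the COD consumed and the package-wide COD audit closes
in sulfate-reduction scenarios too.

CO₂ productivities derive from acetate stoichiometry: 1 mol CO₂ (anaerobic)
or 2 mol (sulfate reduction, aerobic oxidation) per 64 g COD, scaled by
$(1-Y)$. The lumped anaerobic coefficient mixes fermentation and
methanogenesis and is therefore only accurate at steady state or as a
cumulative response, not during VFA accumulation.

## Numerics

Integration uses `scipy.integrate.solve_ivp` with LSODA (stiff-capable;
growth and decay timescales span orders of magnitude across temperature),
rtol 10⁻⁸, atol 10⁻⁶, dense output, and terminal events for threshold
emptying. The output grid (default daily) is decoupled from solver steps; on
days when an emptying event coincides with a grid point the recorded state
is the pre-removal one. Respiration is transfer-limited and substrate-
independent, but is multiplied by a smooth gate $S_p/(S_p + 1\,\mathrm{g})$
so it cannot drive $S_p$ negative and introduces no solver discontinuity.
All other rates vanish naturally with their source pools; concentrations are
clamped at zero when forming rates to guard against solver overshoot.
Temperature enters $\alpha$, $q_{max}$, $K_S$ and speciation afresh at every
RHS evaluation — nothing is cached across steps. The model contains no
random number source; trajectories are bit-reproducible from the scenario.

The RHS is verified against a brute-force oracle that assembles the eight
processes pool-by-pool from the public kinetics functions, and whole
trajectories against a fixed-step explicit-Euler integration (10⁻⁴ d) across
an emptying event. The COD audit closes to ~10⁻¹⁶ relative on default runs.

## Warm-up and steady-state protocols

`run_to_periodic_steady_state` repeats the forcing cycle carrying state,
stopping when per-cycle cumulative CH₄ changes by less than a relative
tolerance (default 10⁻³, at most 5 cycles by default). Under constant
forcing the default scenario converges to within 0.5 % by the third cycle
but retains a slow multi-year oscillation of a few per cent, so
non-convergence is reported as a status flag, not an exception.
`steady_state_biomass` simulates at constant temperature in 400-day chunks
(f_resid 0.95) until cycle-averaged per-group biomass stabilises to 1 %.

## Sensitivity screen

The one-at-a-time screen scales each parameter by ±50 % and measures the
fractional change of cumulative CH₄ over one forcing cycle after two
warm-up cycles, so parameter effects are not confounded with community
establishment. By default it runs in the high-retention storage regime
(f_resid 0.95). The reason is structural: under frequent near-complete
emptying (f_resid 0.1, 30-day cadence) the community sits close to a washout
threshold, and a −50 % step in yield or $q_{max,opt}$ tips it over a cliff —
the population collapses to the influent-seeded floor and the response
saturates near −100 %, swamping the graded responses a tornado ranking is
meant to compare (this cliff is the same mechanism that makes frequent
emptying an effective mitigation measure, and is genuine model behaviour,
verified at the periodic attractor over a 12-year run). In the established-
community regime the ranking is informative: hydrolysis rate $\alpha_{opt}$
dominates among model parameters (≈∓35 % for ±50 %), temperature dominates
among inputs, Monod parameters matter little upward, and yield/uptake-rate
decreases show moderate effects.

## What the forcing generators emulate — and what they do not

`make_forcings` produces constant, sinusoidal-seasonal (optionally with
seeded Gaussian noise), step-change and piecewise-linear series at daily
resolution — idealized slurry temperature and pH histories adequate for
studying the model's dynamical repertoire. They do not emulate measured
farm data: no diurnal cycles, no correlated weather noise, no measured
slurry composition or mass series, no gaps. Tests passing on these fixtures
demonstrate the advertised dynamical mechanisms (washout, hysteresis,
spike/suppression, competition), not predictive accuracy against field
measurements, which requires site-specific influent characterisation —
above all the hydrolysis rate constant, the model's most sensitive
parameter.

Problem sizes in the test and acceptance suites — 90 to 900-day horizons,
annual cycles with two or three warm-up repetitions, 400-day steady-state
chunks — are the package's standard demonstration scales; all of its
entry points accept arbitrary durations.

## Known limitations

- Hydrogen is not an explicit substrate; hydrogenotrophic and acetoclastic
  pathways are merged into VFA consumption. No thermodynamic free-energy
  switching between pathways.
- No surface crust, CH₄ oxidation, N₂O, or nitrification; TAN is transported
  and speciated but has no sink.
- No lag-phase/acclimation mechanics: a group resumes activity the moment
  conditions allow, which likely makes rewarming responses faster than
  reality.
- Exact inhibition constants, per-group cardinal temperatures and transfer
  coefficients are placeholders (table above); conclusions that hinge on
  their precise values should re-estimate them for the system at hand.
- The lumped anaerobic CO₂ coefficient misattributes CO₂ timing during VFA
  accumulation episodes.
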
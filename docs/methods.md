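# Methods

## Scope and modelling stance

The library deliberately trades mechanism for identifiability: each model
is a single smooth ODE (or ODE pair) whose few parameters summarize the
net effect of many underlying processes. There are no phenological
stages, switches or thresholds; smoothness keeps the solution
differentiable in both time and parameters, which is what makes
derivative-based least squares and later sensitivity analysis tractable.
Biomass `M` (kg m⁻²) stands for whole-crop biomass and end-of-season
biomass is read as a proxy for yield. Time is measured in days since the
first observation of a series; the initial condition `M₀` is the biomass
on that first day. The seasonal sinusoid of the irradiance model is
likewise anchored at the series start, with the phase `φ` absorbing any
calendar offset — fitted phases are therefore comparable only within a
common sowing date.

## Parameters

| model | quantity | unit | default / typical | role |
|---|---|---|---|---|
| all | `growth_rate` (r) | day⁻¹ | ~0.1 | intrinsic relative growth rate |
| all | `carrying_capacity` (M_max) | kg m⁻² | ~1.2 | implicit biomass ceiling |
| all | `initial_biomass` (M₀) | kg m⁻² | first observation | state at t = 0 |
| irradiance | `amplitude` (A) | day⁻¹ | either sign | seasonal modulation depth |
| irradiance | `phase` (φ) | day | either sign | seasonal alignment |
| temperature | `t_low`, `t_high` | K | 292, 303 | tolerance window boundaries |
| temperature | `arrhenius_low`, `arrhenius_high` | K | 2·10⁴, 6·10⁴ | steepness of decline at each boundary |
| water | `precip_conversion` (p) | m⁻¹ | ~1 | rainfall → soil-water conversion |
| water | `infiltration_fraction` (q) | – | ~0.06 | barren-soil infiltration fraction (≤ 1) |
| water | `infiltration_constant` (K) | kg m⁻² | ~360 | biomass scale of infiltration gain |
| water | `uptake_rate` (c) | kg⁻¹ ml m⁻¹ day⁻¹ | ~0.08 | crop uptake capacity |
| water | `half_saturation` (n) | ml m⁻³ | ~1 | Michaelis–Menten half-rate |
| water | `uptake_exponent` (v) | – | ~0.5, in (0, 1] | uptake surface / maintained volume scaling |
| water | `drying_rate` (R) | day⁻¹ | ~10⁻³–10⁻¹ | leaky-bucket soil drying |
| water | `conversion_efficiency` (g) | kg ml⁻¹ m | ~1 | water → biomass conversion |
| water | `maintenance_rate` (m) | day⁻¹ | ~0.01 | respiration loss, enables biomass decline |

The temperature-response constants are held fixed (no genotypic
variation); they place the response peak between 292 and 303 K with an
asymmetric, heat-steep decline, matching the usual cardinal-temperature
picture for wheat. All water-model defaults are centred on the magnitudes
of a published single-trial wheat calibration, which also anchors the
acceptance refits.

## Environmental drivers

Adaptive ODE solvers evaluate drivers at arbitrary times, so daily
weather is smoothed into continuous functions: a cubic smoothing spline
with the penalty chosen by generalized cross-validation (explicit
penalties accepted). Constants and straight lines are in the penalty null
space and reproduced exactly. The temperature driver defaults to the
daily-mean series (min/max selectable) and converts °C → K before the
response curve; the rainfall driver is clipped at zero at evaluation
time, since an unconstrained smoother undershoots near isolated
downpours. Gaps up to 10 days are bridged by the spline; longer gaps
raise, because silently interpolating weather across weeks fabricates
data. Driver domains extend one day past the observations at each end so
a solver overshoot near the final time does not abort a run.

## Integration

`solve_ivp` with an explicit Runge–Kutta 4(5) pair, rtol 1e-8 /
atol 1e-10, output on integer days (the data cadence), with an automatic
LSODA retry if the explicit solver's step size collapses (possible for
the water model under fast drying). Over a 150-day season the logistic
solution matches its closed form to ≤ 1e-6·M_max, which is the
calibration-independent accuracy check of the engine. `M = 0` and
`W = 0` are natural boundaries of the dynamics: the right-hand sides are
evaluated in the original variables (nonlinear terms on `max(state, 0)`
to tolerate roundoff undershoot) and trajectories are floored at zero
only for reporting — flooring inside the RHS would distort Jacobians.

## Fitting

One series, one model, any free/fixed split of the model's quantities
(the water model exposes 9 structural parameters plus 2 initial
conditions). The objective is the sum of squared residuals
`r_i = f(x_i) − y_i` (model minus observation) between the integrated
trajectory and the biomass series; for the water model, soil-water
observations (when supplied) contribute a second residual block, each
block scaled by the reciprocal standard deviation of its observed series
so neither state dominates by units.

Numerical choices:

- **Biomass rescaling.** Biomass is divided by 1000 inside the objective
  (both observation and prediction), bringing typical SSRs to order one.
  Because the rescaling is applied in objective space rather than by
  reparameterization, estimates are natively in user units.
- **Transforms.** Positive quantities are optimized on a log scale,
  `uptake_exponent` and `infiltration_fraction` on a logit scale over
  (0, 1], amplitude and phase linearly. Constraints are thereby built
  into the search space with no penalty terms.
- **Optimizers.** Levenberg–Marquardt ("marq", default) on the residual
  vector with a forward-difference Jacobian at relative step 1e-4 — the
  step must sit well above the ODE integrator's relative tolerance, or
  integration noise corrupts the derivatives and the search stalls;
  Nelder–Mead on the scalar SSR; and "pseudo", a seeded Latin-hypercube
  pre-search (64 candidates within finite bounds) polished by
  Levenberg–Marquardt. Multistart adds seeded Latin-hypercube starts;
  the water-model estimator defaults to 16 starts because its
  11-quantity objective surface is rugged. Function-evaluation budgets
  are capped at 300·(k+1) per start.
- **Start values.** Defaults are data-driven: M₀ from the first
  observation, M_max from 1.05× the maximum, r from the early-season
  slope of log M; water-model defaults from the typical magnitudes above.
- **Convergence flag.** True only when the optimizer reports success and
  the gradient of the objective passes an infinity-norm test; a fit that
  exhausts its budget is returned with `converged=False`, never raised.
- **AIC.** `n·ln(SSR/n) + 2k`, the Gaussian concentrated form, computed
  from the biomass-residual SSR only (not the joint biomass+soil-water
  objective) so rankings across models fitted to the same biomass series
  compare like with like. A literal `SSR + 2k` variant is available for
  comparability with tooling that reports the sum of squared errors in
  place of the log-likelihood; it is dimensionally heuristic and not the
  default. `SSR = 0` yields −∞ with a warning. Ties rank by smaller k,
  then smaller SSR.

## Residual diagnostics

Durbin–Watson (`Σ(rᵢ−rᵢ₋₁)²/Σrᵢ²`, ≈2 under no first-order
autocorrelation) and the partial autocorrelation function at lags
1..L with the conventional ±2/√n band. PACF uses the Durbin–Levinson
recursion on biased (1/n) sample autocovariances, which keeps the implied
autoregressive system positive definite. No p-values are attached: on
noise-free simulated data residual autocorrelation reflects structural
model error, not sampling noise, so the plots are read qualitatively.

## Synthetic trial generator

The generator emulates a crop-simulation-platform export so the whole
pipeline is testable offline: seeded daily weather per location-year
(seasonal temperature sinusoid + AR(1) noise; two-state Markov rainfall
occurrence with gamma wet-day amounts), genotype panels drawn around
parameter means (mean-preserving log-normal with a common coefficient of
variation; logit-normal for (0, 1]-bounded quantities; records violating
model invariants are redrawn), and noise-free forward-simulated daily
trajectories over the full location × year × genotype factorial. Four
built-in location profiles span the semi-arid to temperate range of the
Australian wheat belt; the season length defaults to 150 days, consistent
with Australian wheat seasons. Biomass is noise-free by default — fitting
is then evaluated under the most discriminatory conditions — with
optional additive Gaussian noise for robustness experiments. One master
seed derives every per-cell seed by hashing (location, year, genotype),
so any subset regenerates identically regardless of iteration order.
Soil-water "observations" come from the same forward simulation, making
the synthetic world self-consistent by construction.

What the generator does *not* emulate: real crop physiology (phenology,
canopy development, layered soil), spatial correlation between trials,
measurement-error structure of real phenotyping platforms, or weather
beyond temperature and rainfall. Passing recovery tests on this synthetic
world therefore demonstrates the correctness and numerical health of the
estimation machinery — not that the models describe any particular field
trial.

The "bump" fixture is a constructed water-limited trial: moderate early
rain, a dry spell from day 60, and a heavy rain event near day 105, under
a fast-drying soil with a noticeable maintenance cost. Biomass stalls and
declines in the drought and re-accelerates after the rain — a trajectory
shape the logistic model cannot produce (its solutions are monotone), so
the fixture is the canonical discrimination test: the water model attains
the lowest AIC among the four.

## Problem sizes and test design

The suites run on single 151-point daily series; recovery checks use five
seeds per model with the package's default data-driven starts, and the
water model is refitted with at most three quantities free at once —
with many more the objective becomes multi-optimal (see below). The
AIC penalty-dominance check (logistic vs irradiance on logistic-generated
data) uses 20 replicates with small additive observation noise
(sd 0.005 kg m⁻²), because with strictly noise-free data the comparison
degenerates to optimizer stopping floors rather than a statistical
statement. The acceptance refits free exactly one water-model quantity at
a time from a doubled start, on one seeded 150-day rainfall series.

## Known limitations

- **Equifinality.** Over a 150-day window (well under one sinusoid
  period) the irradiance model is only weakly identifiable: `r → 0` with
  a larger compensating amplitude and shifted phase reproduces the same
  trajectory almost exactly. Fits from distant starts may land in such
  equivalent optima; (A, φ) is also exactly symmetric under
  (−A, φ ± 182.5). Interpret irradiance parameters jointly, not
  marginally.
- The 11-quantity water model fitted with many quantities free routinely
  has multiple local optima; multistart mitigates but does not guarantee
  the global solution.
- AIC across these non-nested models is a heuristic ranking of which
  crude growth pattern matches, not formal model selection.
- The sinusoid time origin (day-since-start) makes fitted phases
  incomparable across sowing dates unless the offset is handled by the
  caller.
- No evapotranspiration physics: soil drying is a single first-order
  rate, deliberately.
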
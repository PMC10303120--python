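# cropgrowth

Phenomenological ODE models of within-season crop biomass growth, with
per-series least-squares calibration, AIC model comparison, residual
diagnostics, and a seeded synthetic trial generator.

The package is for quantitative breeders and crop modellers who have
longitudinal biomass series — one per genotype-by-trial combination, as
produced by high-throughput phenotyping or by a crop simulation platform —
and want to summarize each series by a handful of interpretable dynamic
parameters. Genotypic variation is then expressed as variation in those
parameter values, and the *which-model-fits-best* question indicates which
environmental factor limited growth in a given trial.

## The model library

Four nested-in-spirit (but formally non-nested) models, each coupling the
biomass growth rate to one limitation:

**Logistic** — implicit self-limitation:

    dM/dt = r · M · (1 − M/M_max)

with the explicit solution `M(t) = M_max / (1 + (M_max/M₀ − 1)·e^{−rt})`,
used internally as an integration oracle.

**Irradiance** — day-length (seasonal) modulation of the rate:

    dM/dt = (r + A·sin(2π(t + φ)/365)) · M · (1 − M/M_max)

At `A = 0` this collapses exactly to the logistic model.

**Temperature** — the rate is scaled by an enzyme-inactivation response
with fixed Arrhenius-type constants approximating wheat's cardinal
temperatures (`T_L = 292 K`, `T_H = 303 K`, `T_AL = 2·10⁴ K`,
`T_AH = 6·10⁴ K`):

    dM/dt = r · f(T(t)) · M · (1 − M/M_max)
    f(T)  = (1 + exp(T_AL/T − T_AL/T_L) + exp(T_AH/T_H − T_AH/T))⁻¹

`T(t)` is a continuous driver built from daily weather by penalized-spline
smoothing.

**Soil water** — a leaky-bucket soil coupled to the crop through a
saturating (Michaelis–Menten) uptake term:

    dW/dt = p·((M + K·q)/(M + K))·P(t) − c·(W/(W+n))·M^v − R·W
    dM/dt = g·c·(W/(W+n))·M^v − m·M

with smoothed precipitation `P(t)`. This is the only model in the library
that can lose biomass mid-season (maintenance `m·M` exceeding uptake), so
it is the one that reproduces drought-then-rain growth "bumps".

Fits are ranked per series by `AIC = n·ln(SSR/n) + 2k` (Gaussian
concentrated log-likelihood; `k` = number of estimated quantities), read
heuristically since the models are non-nested. Residual structure is
inspected with the partial autocorrelation function and the Durbin–Watson
statistic.

## Worked example

Simulate a logistic trial, add a little observation noise, and refit with
the scikit-learn-style estimator:

```python
import numpy as np
import cropgrowth as cg

params = cg.LogisticParams(growth_rate=0.09, carrying_capacity=1.2,
                           initial_biomass=0.004)
traj = cg.integrate_model("logistic", params, cg.day_grid(150))
rng = np.random.default_rng(0)
y = np.maximum(traj.biomass + rng.normal(0, 0.005, len(traj.biomass)), 0.0)

est = cg.LogisticGrowth().fit(traj.t[:, None], y)
print(est.result_.summary())

report = cg.diagnose(est.result_.residuals["biomass"].residuals, max_lag=5)
print(f"durbin_watson = {report.dw:.3f}")
```

prints

```
model      : logistic
method     : marq
converged  : True
n_obs      : 151
k (free)   : 3
SSR        : 3.40066e-09
AIC        : -3696.0030
  growth_rate = 0.0897922
  carrying_capacity = 1.20014
  initial_biomass = 0.00406887
durbin_watson = 1.898
```

All three generating values come back well within the noise level (r =
0.0898 vs 0.09, M_max = 1.200 vs 1.2, M₀ = 0.00407 vs 0.004); the SSR is
the sum of squared biomass residuals after the default ÷1000 rescaling,
and a Durbin–Watson statistic near 2 says the remaining residuals carry
no first-order serial structure — the noise is white, the model captured
the signal.

The same workflow is available from a shell:

```sh
cropgrowth simulate --model logistic --r 0.09 --mmax 1.2 --m0 0.004 \
    --days 150 --out traj.csv
cropgrowth fit --model logistic --data traj.csv --out-dir fit/
cropgrowth compare --data traj.csv --model logistic --model irradiance
```

`cropgrowth synth` generates whole location-by-year-by-genotype trial
grids (seeded weather, genotype parameter panels drawn around panel
means, forward-simulated daily trajectories) for offline experimentation.

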
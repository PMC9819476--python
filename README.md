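# vegelag

Climate→vegetation time-lag analysis for monthly forest ecosystem records.

Forest greenness (the Enhanced Vegetation Index, EVI) responds to climate
with a delay: a warm or humid month shows up in canopy growth one to
several months later, and the strength of that response is not fixed — it
shifts with slow ecosystem change and with extreme events such as typhoons.
`vegelag` implements the full analysis chain for quantifying these lag
effects at the site level:

1. **EVI reconstruction** — maximum-value compositing (MVC) of sub-monthly
   satellite composites, Savitzky–Golay (SG) local-polynomial smoothing,
   and HANTS harmonic reconstruction with low-side outlier rejection.
2. **Panel preparation** — Min-Max scaling of the five-variable monthly
   panel (EVI; air temperature TEM, °C; relative humidity RHU, %;
   precipitation PRE, mm; photosynthetically active radiation PAR, mol/m²),
   augmented Dickey–Fuller stationarity screening, and AIC/SC lag-order
   selection.
3. **Models** — a constant-parameter VAR (equation-wise OLS, Cholesky
   identification) and the core model, a Bayesian **time-varying-parameter
   VAR with stochastic volatility**:

       y_t = X_t β_t + A_t⁻¹ Σ_t ε_t,            ε_t ~ N(0, I)
       β_{t+1} = β_t + ν_β,   a_{t+1} = a_t + ν_a,   h_{t+1} = h_t + ν_h

   with A_t unit lower triangular, Σ_t = diag(exp(h_t/2)), and diagonal
   innovation covariances Σ_β, Σ_a, Σ_h, estimated by a Gibbs sampler
   (forward-filtering backward-sampling for β and a; a Kim–Shephard–Chib
   mixture sampler for h).
4. **Lag analysis** — time-point impulse responses, per-period lag effects,
   lag accumulation (their running sum), lag duration (months until the
   effect falls below a threshold), growing-season-stage comparisons, and
   out-of-sample VAR vs TVP-VAR forecast comparison by RMSE.

A first-class synthetic-data module generates station-like panels with
known ground-truth dynamics (constant, drifting, or breaking coefficients;
seasonal harmonics in published per-station ranges; cloud-noisy composites;
single-month shock events) so that every stage is testable offline.

## Worked example

```python
import numpy as np
import vegelag as vg
from vegelag.tvp import McmcConfig, TvpPriorConfig

# a bivariate panel whose cross-coefficient breaks 0.6 -> -0.6 mid-sample
dyn = vg.DynamicsSpec(
    p=1,
    coeffs=np.array([[0.3, 0.6], [0.0, 0.5]]),
    coeffs_end=np.array([[0.3, -0.6], [0.0, 0.5]]),
    break_month=60,
    log_vol=np.log(0.01) * np.ones(2),
)
specs = {"y0": vg.SeasonalSpec(0, 0, noise_sd=1.0),
         "y1": vg.SeasonalSpec(0, 0, noise_sd=1.0)}
panel = vg.generate_panel(specs, dyn, T=121, seed=31).panel

priors = TvpPriorConfig(beta_shape=8.0, beta_scale=4e-3)  # allow visible drift
draws = vg.fit_tvp_var(panel, p=1, priors=priors, mcmc=McmcConfig(500, 150, seed=2))
path = draws.beta[:, :, 2].mean(axis=0)   # posterior mean of the y0<-y1 coefficient
print(f"first quarter {path[:30].mean():+.2f}, last quarter {path[-30:].mean():+.2f}")
```

prints

```
first quarter +0.70, last quarter -0.61
```

— the posterior coefficient path tracks the planted break from +0.6 to
−0.6. The same fit yields time-point impulse responses
(`vg.tvp_irf(draws, times=[10, 110], H=6)`) whose EVI row, summed over lag
periods, is the lag accumulation, and `vg.compare_models(...)` scores both
models' 24-month EVI forecasts by RMSE and reports the improvement
percentage `(RMSE_VAR − RMSE_TVP)/RMSE_VAR × 100`.

## Analysis scripts

`analysis/01…06_*.py` run the study end to end on synthetic station-like
panels: simulate six sites (01), reconstruct EVI from cloud-noisy
composites (02), screen stationarity and select lag orders (03), fit both
models with convergence diagnostics (04), derive the lag-effect table and
growing-season comparison (05), and compare out-of-sample forecasts (06).
Each writes its tables under `results/`. A `vegelag` CLI (subcommands
`simulate`, `preprocess`, `diagnose`, `fit-var`, `fit-tvpvar`, `irf`,
`lags`, `forecast`, `compare`, `run-all`) exposes the same stages for
one-off use.

## Module map

| module | contents |
| --- | --- |
| `vegelag.synthetic` | `SeasonalSpec`, `DynamicsSpec`, `generate_panel`, `inject_shock`, `generate_composites` |
| `vegelag.preprocess` | `mvc_monthly`, `sg_filter`, `hants_reconstruct`, `sg_hants` |
| `vegelag.panel` | `minmax_normalize`, `adf_test`, `select_lag_order` |
| `vegelag.var` | `fit_var`, `var_irf`, `var_forecast` |
| `vegelag.tvp` | `fit_tvp_var`, `tvp_irf`, `tvp_forecast` |
| `vegelag.lags` | `lag_effects`, `lag_accumulation`, `lag_duration`, `growing_season_irf`, `rmse`, `improvement_pct`, `compare_models` |
| `vegelag.pipeline` / `vegelag.cli` | config, panel CSV IO, `run_pipeline`, CLI |
| `vegelag.published` | published station tables used as inputs |

See `docs/methods.md` for the model assumptions, priors, numerical choices,
and known limitations.
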
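# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations of `vegelag`.

## The scientific problem

Monthly forest greenness (EVI) responds to climate — air temperature (TEM,
°C), relative humidity (RHU, %), precipitation (PRE, mm/month), and
photosynthetically active radiation (PAR, mol/m²) — with lags of one to
several months, and the strength and even sign of the response changes over
time (slow ecosystem change, disturbance events). A constant-parameter VAR
captures the average lag structure; a time-varying-parameter VAR (TVP-VAR)
lets the lag structure itself evolve, so the same shock can have different
effects in different months or years, and forecasts adapt to recent
conditions.

## EVI reconstruction

Sub-monthly vegetation-index composites are contaminated by clouds and
rain, which bias values *downward*. The chain is:

- **MVC** — the per-month maximum suppresses low-biased noise (it can only
  remove low outliers, never high ones).
- **SG filter** — local least-squares polynomial smoothing. Defaults:
  half-width m = 2 (5-month window), order 2 — the shortest window that
  smooths monthly noise without flattening the annual cycle. At series
  boundaries the window shrinks asymmetrically and the same-order
  polynomial is fit on the available points; this avoids padding artifacts
  on short records. The filter is exact on polynomials up to the fit order
  and linear in its input.
- **HANTS** — least-squares fit of `A0 + Σ_j A_j sin(2πji/n + θ_j)` over
  all years jointly, with base period n = 12 months so frequency 1 is
  annual and frequency 2 semi-annual (2 frequencies by default). Points
  lying *below* the curve by more than the fit-error tolerance (FET) are
  removed one per iteration, worst first, and the curve refit; iteration
  stops when no residual exceeds FET or only DOD points remain (DOD = 8 by
  default, never below the 2·frequencies+1 fitted parameters). FET
  defaults to 0.05 EVI — the customary 500 raw counts on the integer
  (×10⁻⁴) scale vegetation-index products ship; both the raw number and
  the scale factor are configurable. Only low-side outliers are removable
  by default, consistent with the cloud-noise mechanism; high-side removal
  is a flag.

In the end-to-end pipeline the reconstruction is applied as *gap
filling*: the SG-smoothed observations are kept everywhere and the
harmonic value substitutes only the months HANTS flagged as
cloud-depressed, so interannual variation survives into the modelling
stage (a strictly periodic column would be degenerate for the unit-root
screen and the VAR).

**Limitation**: HANTS assumes a strictly periodic seasonal signal. On a
series with a secular level trend the harmonic basis cannot follow the
trend, residuals inflate, and the low-side rejection flags legitimate
early-sample points. Reconstruction quality should be judged against
(quasi-)stationary seasonal series; for trending series, reconstruct
first and model the trend in the VAR stage (where the time-varying
intercept absorbs it).

## Panel preparation

Min-Max scaling `X' = (X − Xmin)/(Xmax − Xmin)` puts all five variables on
[0, 1]; the stored parameters invert the map exactly. The ADF test is the
t-ratio on the lagged level in the augmented regression (constant-only
deterministic term by default, since normalized seasonal series are
non-trending); the augmentation lag is chosen by AIC up to Schwert's cap,
and p-values/critical values are MacKinnon's response surfaces.
Non-stationary verdicts are warnings, not errors — the pipeline proceeds
with level data. Lag order is selected on a common effective sample with
`AIC = ln|Σ̂| + 2k/T` and `SC = ln|Σ̂| + k·ln(T)/T` (k = freely estimated
mean parameters); when the criteria disagree the more parsimonious SC
choice is used, and both are reported.

## Constant-parameter VAR

Equation-by-equation OLS with intercept (a flag), residual covariance with
degrees-of-freedom correction. Impulse responses are Cholesky-identified:
the covariance is permuted into the identification ordering, factored, and
permuted back; `shock="sd"` applies one-standard-deviation orthogonalized
shocks, `shock="unit"` rescales each column so the shocked variable moves
by one normalized unit on impact. The default ordering places the climate
block first and EVI last — (TEM, RHU, PRE, PAR, EVI) — so climate shocks
affect EVI contemporaneously but not vice versa; the ordering is an
explicit field recorded in every export. Forecasts iterate the conditional
mean with innovations at zero.

## TVP-VAR

Measurement: `y_t = X_t β_t + A_t⁻¹ D_t^{1/2} ε_t` with
`X_t = I_k ⊗ [1, y_{t-1}', …, y_{t-p}']`, A_t unit lower triangular (free
elements a_t), `D_t = diag(exp(h_t))`. States β_t (intercept + lag
coefficients), a_t, and h_t follow independent random walks with diagonal
innovation covariances Σ_β, Σ_a, Σ_h. The time-varying intercept is
included by default (normalized data need a level term) and can be
disabled.

Gibbs sampler blocks, all driven by one seeded generator:

1. **β path** — Carter–Kohn forward-filtering backward-sampling on the
   linear Gaussian state space, exploiting the Kronecker structure of X_t.
2. **a path** — per equation i, the orthogonalized residual regression
   `ŷ_{it} = −Σ_{j<i} a_{ij,t} ŷ_{jt} + e_{it}` is again linear Gaussian;
   FFBS per equation (Σ_a diagonal makes the blocks independent).
3. **h paths** — log χ²(1) measurement error approximated by the
   Kim–Shephard–Chib 7-component normal mixture; component indicators
   sampled per time point, then scalar FFBS. A single-move Metropolis
   fallback targeting the exact measurement density is provided for
   verification; the two agree on long-run path means in tests.
4. **Hyperparameters** — each diagonal variance from its inverse-gamma
   conditional `IG(shape + (T−1)/2, scale + ½Σ(Δstate)²)`.

The numerically heavy kernels are numba-compiled; all random variates are
pre-drawn from the seeded generator outside the kernels, so identical
configurations reproduce identical draws bit for bit.

**Priors** (configurable; defaults on the normalized scale):
(Σ_β)ᵢᵢ ~ IG(20, 10⁻³) — prior-mean monthly coefficient drift s.d. ≈ 0.007,
concentrating on slow evolution; (Σ_a)ᵢᵢ, (Σ_h)ᵢᵢ ~ IG(4, 10⁻²) — looser,
as contemporaneous relations and volatilities are less constrained a
priori. Initial states β₀, a₀, h₀ ~ N(0, 10·I). MCMC default: 2000
iterations with the first 500 discarded, no thinning. Convergence is
summarized by Geweke z-scores and Parzen-window inefficiency factors on
the hyperparameter chains.

**Time-point impulse responses** hold the parameters prevailing at the
evaluation time fixed over the response horizon (no state projection) —
the standard time-point IRF for this model class. The impact matrix per
draw is `A_t⁻¹ diag(s)` with s the draw's *time-averaged* innovation
standard deviation `exp(h/2)` per equation; averaging responses across
draws then yields the posterior mean under a time-averaged
one-standard-deviation shock. The per-unit convention rescales by the
impact diagonal. **Forecasts** iterate the conditional mean from the
final-period states (β_T, A_T) per draw; cross-draw mean and quantiles are
returned. An optional stationarity constraint
(`stationary_only=True`) excludes draws whose final-period companion
matrix is explosive (spectral radius ≥ 1) — a guard for ensembles whose
mean would otherwise be dominated by a few diverging paths. It is off by
default: fitted seasonal systems sit near the unit circle, and filtering
there biases the ensemble toward damped annual cycles.

## Lag analysis

Lag period k maps to horizon k by default (period 1 = one month after the
shock); the mapping is a config switch (`period_to_horizon=-1` makes
period 1 the impact month) and is recorded in every export. Lag
accumulation is the running sum of per-period effects; its value at the
last period is the "stable" accumulation. Lag duration is the largest
period whose absolute effect is ≥ ε, with ε = 0.005 — half the rounding
unit of two-decimal reports, so effects printed as 0.00 count as vanished.
Growing-season stages default to early (Mar–Apr), peak (May–Oct), dormant
(Nov–Feb); the group mean averages posterior-mean time-point IRFs over all
in-sample months in the group. Forecast comparison trains both models on
the pre-split span, forecasts the full test span, and scores the EVI
column's RMSE on the normalized scale (the denormalized RMSE is also
exported); the improvement percentage is
`(RMSE_VAR − RMSE_TVP)/RMSE_VAR × 100`. Station-table averages report the
mean of per-site improvements; year-table averages report the improvement
of mean RMSEs — both conventions appear in published tables, so both are
computed and labeled.

## Synthetic study conditions

The generator emulates 11–13 years of monthly station records: one annual
harmonic per variable (the dominant cycle in monthly data, matching the
2-frequency HANTS setting), means and amplitudes placed inside the
published per-station ranges, values clamped to those ranges after noise.
The unitless anomaly process follows the structural VAR with coefficient
paths that are constant, drift linearly, or break at a stated month; the
true time-point IRFs are stored with the panel. EVI's anomaly scale
defaults to 0.03 native units — typical interannual monthly EVI
variability — and the default site dynamics drift the EVI-equation
intercept by ≈0.05 native EVI over the sample, a decade-scale greening
magnitude, alongside mild drift in the lag matrices. Cloud noise on
composites is strictly negative (depression = magnitude × U(0.5, 1.5) with
the stated probability), matching the mechanism MVC targets; within-month
jitter is configurable since its real magnitude is product-dependent.
Shock injection is additive, single-month, clamped to the variable range;
multi-month decay profiles are out of scope.

What passing tests on these panels do **not** show about real data: real
EVI series have asymmetric seasonal shapes (fast green-up, slow
senescence), autocorrelated cloud contamination, spatially varying scale
factors, and trend components; the synthetic harmonic-plus-VAR structure
is the cleanest testbed for the estimators, not a phenological model.

## Numerical choices

- State covariances are symmetrized every filter step; Cholesky factors
  get a 10⁻¹² jitter.
- `log(e² + 10⁻¹⁰)` guards the volatility measurement against zero
  residuals.
- The SG edge policy (shrinking windows) keeps the filter linear; the
  HANTS iteration removes one outlier per pass (worst first), which makes
  the flag set deterministic.
- Ties between AIC and SC resolve to SC (parsimony).
- Degenerate inputs error early with the offending variable or month
  named: constant columns in normalization, empty months in MVC, exact
  collinearity in OLS, zero-residual ADF regressions, non-stationary
  average dynamics in the generator (the spectral radius is reported).

## Known limitations

- **Seasonally oscillating coefficients are not recoverable.** The
  random-walk state prior is a low-pass filter on coefficient paths; a
  coefficient that cycles with a 12-month period (e.g., a response active
  only in spring) is smoothed to its annual mean at any plausible drift
  variance, and forcing a loose prior makes the coefficient paths absorb
  residual noise and collapses the volatility estimates instead.
  Growing-season-stage differences in the time-point IRFs therefore
  reflect slowly varying parameter differences between calendar months
  across years, not within-year parameter cycling.
- A drifting *lag coefficient* alone produces little out-of-sample
  forecast advantage for the time-varying model: multi-step conditional
  means of mean-reverting anomalies are dominated by unpredictable
  innovations. The advantage appears when the forecastable component
  shifts — a drifting intercept (level) or a persistent break.
- Single chain by default; the Geweke and inefficiency diagnostics flag
  non-convergence, and short demonstration runs (≤1000 sweeps) routinely
  show inflated hyperparameter inefficiencies — the 2000/500 default is
  the minimum for stable posterior summaries at study scale.
- No structural identification beyond the recursive ordering; no marginal
  likelihood or model comparison beyond forecast RMSE.
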
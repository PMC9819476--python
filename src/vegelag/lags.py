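"""Lag-effect summaries and forecast evaluation.

Turns impulse responses into the quantities ecologists report: per-period
lag effects of each climate factor on the EVI, their running sum (lag
accumulation, whose limit summarizes the total eventual impact of a shock),
lag duration (months until the per-period effect falls below a threshold),
growing-season-stage comparisons of time-point responses, and the
VAR-vs-TVP-VAR out-of-sample RMSE comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tvp import McmcConfig, PosteriorDraws, TvpPriorConfig, fit_tvp_var, tvp_forecast, tvp_irf
from .var import ImpulseResponseArray, fit_var, var_forecast

__all__ = [
    "DEFAULT_SEASON_GROUPS",
    "ForecastEvaluation",
    "lag_effects",
    "lag_accumulation",
    "lag_duration",
    "lag_effect_table",
    "growing_season_irf",
    "rmse",
    "improvement_pct",
    "compare_models",
]

#: Calendar-month groups for the growing-season stages of the study region.
DEFAULT_SEASON_GROUPS: dict[str, tuple[int, ...]] = {
    "early": (3, 4),
    "peak": (5, 6, 7, 8, 9, 10),
    "dormant": (11, 12, 1, 2),
}


def _irf_values(irf) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(irf, ImpulseResponseArray):
        return irf.values, irf.variables
    raise TypeError("expected an ImpulseResponseArray")


def lag_effects(
    irf: ImpulseResponseArray,
    shock: str,
    response: str = "EVI",
    periods: int = 6,
    period_to_horizon: int = 0,
) -> np.ndarray:
    """Per-period lag effects: the ``response`` row of the IRF for ``shock``.

    Lag period k maps to horizon k + ``period_to_horizon`` (0 by default, so
    period 1 is the response one month after the shock; set -1 to make
    period 1 the impact month). The mapping is recorded in every export.
    """
    values, variables = _irf_values(irf)
    if shock not in variables:
        raise ValueError(f"shock variable {shock!r} not in panel {variables}")
    if response not in variables:
        raise ValueError(f"response variable {response!r} not in panel {variables}")
    i, j = variables.index(response), variables.index(shock)
    horizons = np.arange(1, periods + 1) + period_to_horizon
    if horizons.max() >= values.shape[2] or horizons.min() < 0:
        raise ValueError("IRF horizon too short for the requested lag periods")
    return values[i, j, horizons]


def lag_accumulation(effects: np.ndarray) -> tuple[np.ndarray, float]:
    """Running sums of per-period effects and the stable (total) value."""
    effects = np.asarray(effects, dtype=float)
    if effects.size == 0:
        raise ValueError("empty effect vector")
    running = np.cumsum(effects)
    return running, float(running[-1])


def lag_duration(effects: np.ndarray, eps: float = 0.005) -> int:
    """Largest period k (1-based) with |effect_k| >= eps; 0 if none.

    The default eps = 0.005 is half the rounding unit of two-decimal
    reports, so effects printed as 0.00 count as vanished.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    effects = np.asarray(effects, dtype=float)
    alive = np.flatnonzero(np.abs(effects) >= eps)
    return int(alive[-1] + 1) if alive.size else 0


def lag_effect_table(
    irf_by_station: dict[str, ImpulseResponseArray],
    factors: tuple[str, ...] = ("PAR", "PRE", "RHU", "TEM"),
    response: str = "EVI",
    periods: int = 6,
    eps: float = 0.005,
    period_to_horizon: int = 0,
) -> pd.DataFrame:
    """Per-(factor, station) lag effects, accumulation, and duration."""
    rows = []
    for factor in factors:
        for station, irf in irf_by_station.items():
            eff = lag_effects(irf, factor, response, periods, period_to_horizon)
            _, stable = lag_accumulation(eff)
            rows.append(
                {"factor": factor, "station": station,
                 **{f"lag{i + 1}": eff[i] for i in range(periods)},
                 "accumulation": stable, "duration": lag_duration(eff, eps)}
            )
    table = pd.DataFrame(rows)
    table.attrs["period_to_horizon"] = period_to_horizon
    table.attrs["eps"] = eps
    return table


def growing_season_irf(
    draws: PosteriorDraws,
    month_groups: dict[str, tuple[int, ...]] | None = None,
    H: int = 6,
    shock: str = "sd",
) -> dict[str, np.ndarray]:
    """Mean posterior-mean IRF per growing-season stage.

    Evaluates the time-point IRF at every in-sample month whose calendar
    month belongs to each group and averages the posterior means within the
    group. Requires the fit to carry a date index.
    """
    if draws.dates is None:
        raise ValueError("posterior draws carry no date index")
    groups = month_groups or DEFAULT_SEASON_GROUPS
    months = np.asarray(draws.dates.month)
    out: dict[str, np.ndarray] = {}
    for name, member_months in groups.items():
        times = [int(t) for t in np.flatnonzero(np.isin(months, member_months))]
        if not times:
            raise ValueError(f"month group {name!r} matches no in-sample months")
        irf = tvp_irf(draws, times, H=H, shock=shock)
        out[name] = irf.mean.mean(axis=0)
    return out


def rmse(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Root mean squared deviation between two equal-length series."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {actual.shape}")
    if predicted.size == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


def improvement_pct(rmse_var: float, rmse_tvp: float) -> float:
    """Accuracy improvement (%) of the TVP model over the constant baseline."""
    if rmse_var <= 0:
        raise ValueError("baseline RMSE must be positive")
    return (rmse_var - rmse_tvp) / rmse_var * 100.0


@dataclass
class ForecastEvaluation:
    """Out-of-sample comparison of the constant and time-varying VAR."""

    rmse_var: float
    rmse_tvp: float
    improvement: float
    predicted_var: pd.Series
    predicted_tvp: pd.Series
    actual: pd.Series
    per_year: pd.DataFrame | None = None
    target: str = "EVI"

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"unit": "all", "rmse_var": self.rmse_var, "rmse_tvp": self.rmse_tvp,
              "improvement_pct": self.improvement}]
        )


def compare_models(
    panel: pd.DataFrame,
    split: str | pd.Timestamp,
    p: int,
    target: str = "EVI",
    ordering: tuple[str, ...] | None = None,
    priors: TvpPriorConfig = TvpPriorConfig(),
    mcmc: McmcConfig = McmcConfig(),
    per_year: bool = True,
) -> ForecastEvaluation:
    """Train both models before ``split``, forecast the rest, score the target.

    The constant VAR and the TVP-VAR are fit on the training span; each
    forecasts the full test span by conditional-mean recursion, and the
    RMSE of the ``target`` column (on the scale of the supplied panel,
    normally the normalized [0, 1] scale) is compared. Calendar-year
    sub-evaluations are included when the test span covers several years.
    """
    split = pd.Timestamp(split)
    train = panel[panel.index < split]
    test = panel[panel.index >= split]
    if len(test) == 0:
        raise ValueError(f"empty test span at split {split.date()}")
    h = len(test)
    variables = tuple(ordering) if ordering else tuple(panel.columns)

    var_model = fit_var(train[list(variables)], p=p)
    var_pred = var_forecast(var_model, train[list(variables)], h)
    draws = fit_tvp_var(train, p=p, priors=priors, mcmc=mcmc, ordering=variables)
    tvp_pred = tvp_forecast(draws, None, h)

    j = variables.index(target)
    pred_var = pd.Series(var_pred[:, j], index=test.index, name="var")
    pred_tvp = pd.Series(tvp_pred.mean[:, j], index=test.index, name="tvp")
    actual = test[target]
    r_var = rmse(pred_var.to_numpy(), actual.to_numpy())
    r_tvp = rmse(pred_tvp.to_numpy(), actual.to_numpy())

    per_year_frame = None
    if per_year:
        rows = []
        for year, chunk in actual.groupby(actual.index.year):
            rv = rmse(pred_var[chunk.index].to_numpy(), chunk.to_numpy())
            rt = rmse(pred_tvp[chunk.index].to_numpy(), chunk.to_numpy())
            rows.append({"unit": int(year), "rmse_var": rv, "rmse_tvp": rt,
                         "improvement_pct": improvement_pct(rv, rt)})
        per_year_frame = pd.DataFrame(rows)

    return ForecastEvaluation(
        rmse_var=r_var, rmse_tvp=r_tvp,
        improvement=improvement_pct(r_var, r_tvp),
        predicted_var=pred_var, predicted_tvp=pred_tvp, actual=actual,
        per_year=per_year_frame, target=target,
    )
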
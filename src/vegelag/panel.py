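"""Panel assembly and pre-model screening.

Min-Max scaling puts the five variables (EVI, TEM, RHU, PRE, PAR) on a
common [0, 1] scale; an augmented Dickey-Fuller regression screens each
series for a unit root; and Akaike / Schwarz information criteria computed
on a common effective sample choose the VAR lag order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.adfvalues import mackinnoncrit, mackinnonp

from .var import fit_var

__all__ = [
    "NormalizationParams",
    "AdfResult",
    "LagSelection",
    "minmax_normalize",
    "adf_test",
    "select_lag_order",
    "check_monthly_panel",
]


def check_monthly_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a month-indexed panel: consecutive months, no missing cells."""
    idx = pd.DatetimeIndex(panel.index)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique()
        raise ValueError(f"duplicate months: {[str(d.date()) for d in dups]}")
    expected = pd.date_range(idx[0], idx[-1], freq="MS")
    missing = expected.difference(idx)
    if len(missing):
        raise ValueError(f"missing months: {[f'{d:%Y-%m}' for d in missing]}")
    if panel.isna().any().any():
        bad = panel.index[panel.isna().any(axis=1)]
        raise ValueError(f"missing cells in months: {[f'{d:%Y-%m}' for d in bad]}")
    return panel


@dataclass
class NormalizationParams:
    """Per-variable min/max of the original data, for inverse mapping."""

    x_min: pd.Series
    x_max: pd.Series

    def transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        return (panel - self.x_min) / (self.x_max - self.x_min)

    def inverse(self, normalized: pd.DataFrame | pd.Series):
        return normalized * (self.x_max - self.x_min) + self.x_min

    def inverse_column(self, values: np.ndarray, name: str) -> np.ndarray:
        lo, hi = self.x_min[name], self.x_max[name]
        return values * (hi - lo) + lo


def minmax_normalize(panel: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationParams]:
    """Min-Max scale every column to [0, 1]: X' = (X - Xmin)/(Xmax - Xmin)."""
    x_min = panel.min()
    x_max = panel.max()
    constant = x_max <= x_min
    if constant.any():
        names = list(panel.columns[constant])
        raise ValueError(f"constant column(s) cannot be normalized: {names}")
    params = NormalizationParams(x_min=x_min, x_max=x_max)
    normalized = params.transform(panel)
    normalized.attrs = dict(panel.attrs)
    return normalized, params


@dataclass
class AdfResult:
    statistic: float
    lag_used: int
    deterministic: str  # "none" | "constant" | "constant+trend"
    pvalue: float
    critical_values: dict[str, float]
    stationary: bool  # rejection of the unit root at 5%


_DET_TO_REG = {"none": "n", "constant": "c", "constant+trend": "ct"}


def _adf_regression(y: np.ndarray, lag: int, deterministic: str) -> tuple[float, float]:
    """t-ratio on the lagged level in the augmented regression, plus its RSS-based AIC."""
    dy = np.diff(y)
    n = len(dy) - lag
    rows = [y[lag:-1]]
    for i in range(1, lag + 1):
        rows.append(dy[lag - i : len(dy) - i])
    X = np.column_stack(rows)
    if deterministic in ("constant", "constant+trend"):
        X = np.column_stack([X, np.ones(n)])
    if deterministic == "constant+trend":
        X = np.column_stack([X, np.arange(n, dtype=float)])
    target = dy[lag:]
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    resid = target - X @ coef
    dof = n - X.shape[1]
    if dof <= 0:
        raise ValueError("series too short for the requested ADF lag")
    rss = resid @ resid
    if not np.isfinite(rss) or rss <= 1e-12 * max(1.0, target @ target):
        raise ValueError("degenerate ADF regression (zero residual variance)")
    s2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * xtx_inv[0, 0])
    tstat = coef[0] / se
    aic = n * np.log(resid @ resid / n) + 2 * X.shape[1]
    return float(tstat), float(aic)


def adf_test(
    series: pd.Series | np.ndarray,
    max_lag: int | None = None,
    deterministic: str = "constant",
    alpha: float = 0.05,
) -> AdfResult:
    """Augmented Dickey-Fuller unit-root test.

    The statistic is the t-ratio on the lagged level in
    ``dy_t = [det terms] + rho*y_{t-1} + sum_i phi_i dy_{t-i} + e_t``; the
    augmentation lag is chosen by AIC over 0..max_lag (Schwert's rule caps
    the default). p-values and critical values are MacKinnon's response
    surfaces for the chosen deterministic specification.
    """
    if deterministic not in _DET_TO_REG:
        raise ValueError(f"deterministic must be one of {list(_DET_TO_REG)}")
    y = np.asarray(series, dtype=float)
    n = len(y)
    if max_lag is None:
        max_lag = min(int(np.ceil(12.0 * (n / 100.0) ** 0.25)), n // 2 - 2)
    if n <= max_lag + 10:
        raise ValueError(f"series length {n} too short for max_lag {max_lag}")
    best = None
    for lag in range(max_lag + 1):
        stat, aic = _adf_regression(y, lag, deterministic)
        if best is None or aic < best[2]:
            best = (stat, lag, aic)
    stat, lag_used, _ = best
    reg = _DET_TO_REG[deterministic]
    pvalue = float(mackinnonp(stat, regression=reg, N=1))
    crit = mackinnoncrit(N=1, regression=reg, nobs=n - lag_used - 1)
    critical_values = {"1%": float(crit[0]), "5%": float(crit[1]), "10%": float(crit[2])}
    return AdfResult(
        statistic=stat,
        lag_used=lag_used,
        deterministic=deterministic,
        pvalue=pvalue,
        critical_values=critical_values,
        stationary=bool(stat < critical_values[f"{int(alpha * 100)}%"]),
    )


def adf_screen(panel: pd.DataFrame, deterministic: str = "constant") -> pd.DataFrame:
    """ADF table for every column; non-stationary verdicts warn, not abort."""
    rows = {}
    for name in panel.columns:
        res = adf_test(panel[name], deterministic=deterministic)
        rows[name] = {
            "statistic": res.statistic,
            "lag": res.lag_used,
            "pvalue": res.pvalue,
            "stationary_5pct": res.stationary,
        }
        if not res.stationary:
            warnings.warn(f"{name}: unit root not rejected at 5% (ADF {res.statistic:.3f})")
    return pd.DataFrame(rows).T


@dataclass
class LagSelection:
    table: pd.DataFrame  # index p, columns aic / sc
    aic_order: int
    sc_order: int
    chosen: int
    agree: bool


def select_lag_order(panel: pd.DataFrame, p_max: int) -> LagSelection:
    """AIC / SC lag-order choice on a common effective sample.

    For each p in 1..p_max the VAR is fit on observations p_max+1..T so all
    candidates share the sample; AIC = ln|Sigma_mle| + 2k/T_eff and
    SC = ln|Sigma_mle| + k ln(T_eff)/T_eff with k the count of freely
    estimated mean parameters. Ties between criteria resolve to the SC
    (parsimonious) choice.
    """
    data = panel.to_numpy(dtype=float) if isinstance(panel, pd.DataFrame) else np.asarray(panel, float)
    T, k = data.shape
    t_eff = T - p_max
    if p_max < 1 or t_eff < k * p_max + 10:
        raise ValueError(f"p_max {p_max} too large for sample length {T}")
    records = {}
    for p in range(1, p_max + 1):
        # common sample: drop p_max initial obs regardless of p
        sub = data[p_max - p :]
        model = fit_var(sub, p=p, intercept=True)
        sigma_mle = model.loglike_sigma_mle()
        sign, logdet = np.linalg.slogdet(sigma_mle)
        if sign <= 0:
            raise np.linalg.LinAlgError(f"singular residual covariance at p={p}")
        n_mean_params = k * (k * p + 1)
        records[p] = {
            "aic": logdet + 2.0 * n_mean_params / t_eff,
            "sc": logdet + n_mean_params * np.log(t_eff) / t_eff,
        }
    table = pd.DataFrame(records).T
    aic_order = int(table["aic"].idxmin())
    sc_order = int(table["sc"].idxmin())
    return LagSelection(
        table=table,
        aic_order=aic_order,
        sc_order=sc_order,
        chosen=sc_order,
        agree=aic_order == sc_order,
    )
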
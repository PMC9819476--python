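"""Synthetic climate/EVI panels with known ground truth.

A site's monthly record is modelled as a deterministic annual harmonic per
variable plus a multivariate anomaly process that follows a (possibly
time-varying) structural VAR:

    x_t = c + sum_l B_{l,t} x_{t-l} + A_t^{-1} D_t^{1/2} eps_t,   eps_t ~ N(0, I)

with A_t unit lower triangular and D_t = diag(exp(h_t)). The anomaly is
unitless; each observed variable is ``mean + amplitude*sin(2*pi*t/12 + phase)
+ noise_sd * x_t`` clamped to its declared physical range. Coefficient paths
may be constant, drift linearly, or break at a stated month, so parameter
recovery and break-tracking of the time-varying estimators can be tested
against stored truth. True time-point impulse responses (from B_t and the
impact matrix A_t^{-1} D_t^{1/2}) are kept alongside the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CompositeSeries

__all__ = [
    "SeasonalSpec",
    "DynamicsSpec",
    "SyntheticTruth",
    "generate_panel",
    "inject_shock",
    "generate_composites",
    "station_seasonal_specs",
]


@dataclass(frozen=True)
class SeasonalSpec:
    """Annual-harmonic description of one variable, in native units."""

    mean: float
    amplitude: float
    phase: float = 0.0
    noise_sd: float = 0.0
    vmin: float = -np.inf
    vmax: float = np.inf

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not self.vmin < self.vmax:
            raise ValueError("range min must be below range max")


@dataclass
class DynamicsSpec:
    """Time paths of the anomaly VAR parameters.

    ``coeffs`` is (p, k, k); if ``coeffs_end`` is given the per-lag matrices
    move from ``coeffs`` to ``coeffs_end`` either linearly over the sample
    (``break_month is None``) or as a step at ``break_month`` (0-based month
    index). ``contemp`` holds the unit-lower-triangular contemporaneous
    matrix (constant (k, k) or path (T, k, k)); ``log_vol`` the log innovation
    variances (constant (k,) or path (T, k)).
    """

    p: int
    coeffs: np.ndarray
    coeffs_end: np.ndarray | None = None
    break_month: int | None = None
    contemp: np.ndarray | None = None
    log_vol: np.ndarray | None = None
    intercept: np.ndarray | None = None
    intercept_end: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim == 2:
            self.coeffs = self.coeffs[None, :, :]
        if self.p < 1 or self.coeffs.shape[0] != self.p:
            raise ValueError("coeffs must stack p square lag matrices")
        k = self.coeffs.shape[1]
        if self.coeffs.shape[1:] != (k, k):
            raise ValueError("lag matrices must be square")
        if self.coeffs_end is not None:
            self.coeffs_end = np.asarray(self.coeffs_end, dtype=float).reshape(self.p, k, k)

    @property
    def k(self) -> int:
        return self.coeffs.shape[1]

    def coeff_path(self, T: int) -> np.ndarray:
        """(T, p, k, k) coefficient path."""
        if self.coeffs_end is None:
            return np.broadcast_to(self.coeffs, (T, self.p, self.k, self.k)).copy()
        if self.break_month is not None:
            path = np.broadcast_to(self.coeffs, (T, self.p, self.k, self.k)).copy()
            path[self.break_month:] = self.coeffs_end
            return path
        w = np.linspace(0.0, 1.0, T)[:, None, None, None]
        return (1 - w) * self.coeffs + w * self.coeffs_end

    def contemp_path(self, T: int) -> np.ndarray:
        if self.contemp is None:
            a = np.broadcast_to(np.eye(self.k), (T, self.k, self.k)).copy()
        else:
            a = np.asarray(self.contemp, dtype=float)
            if a.ndim == 2:
                a = np.broadcast_to(a, (T, self.k, self.k)).copy()
        for t in (0, T - 1):
            if not (np.allclose(np.diag(a[t]), 1.0) and np.allclose(np.triu(a[t], 1), 0.0)):
                raise ValueError("contemporaneous matrix must be unit lower triangular")
        return a

    def intercept_path(self, T: int) -> np.ndarray:
        """(T, k) intercept path; drifts like the coefficients if an end is given."""
        c0 = np.zeros(self.k) if self.intercept is None else np.asarray(self.intercept, float)
        if self.intercept_end is None:
            return np.broadcast_to(c0, (T, self.k)).copy()
        c1 = np.asarray(self.intercept_end, dtype=float)
        if self.break_month is not None:
            path = np.broadcast_to(c0, (T, self.k)).copy()
            path[self.break_month:] = c1
            return path
        w = np.linspace(0.0, 1.0, T)[:, None]
        return (1 - w) * c0 + w * c1

    def log_vol_path(self, T: int) -> np.ndarray:
        if self.log_vol is None:
            return np.zeros((T, self.k))
        h = np.asarray(self.log_vol, dtype=float)
        if h.ndim == 1:
            h = np.broadcast_to(h, (T, self.k)).copy()
        return h

    def average_spectral_radius(self, T: int) -> float:
        from .var import companion_matrix

        mean_b = self.coeff_path(T).mean(axis=0)
        return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(mean_b)))))


@dataclass
class SyntheticTruth:
    """Generated panel together with everything needed to score estimators."""

    panel: pd.DataFrame
    dynamics: DynamicsSpec
    seasonal: dict[str, SeasonalSpec]
    anomalies: pd.DataFrame
    true_irf: np.ndarray  # (T, k, k, H+1): [time, response, shock, horizon]
    irf_horizon: int
    variables: tuple[str, ...]
    shocks: list[dict] = field(default_factory=list)


def _true_irf_path(dynamics: DynamicsSpec, T: int, horizon: int) -> np.ndarray:
    from .var import impulse_responses

    coeff = dynamics.coeff_path(T)
    contemp = dynamics.contemp_path(T)
    log_vol = dynamics.log_vol_path(T)
    k = dynamics.k
    out = np.empty((T, k, k, horizon + 1))
    for t in range(T):
        impact = np.linalg.solve(contemp[t], np.diag(np.exp(log_vol[t] / 2.0)))
        out[t] = impulse_responses(coeff[t], impact, horizon)
    return out


def generate_panel(
    seasonal: dict[str, SeasonalSpec],
    dynamics: DynamicsSpec,
    T: int = 156,
    seed: int | None = None,
    start: str = "2007-01",
    irf_horizon: int = 6,
    site: str = "SYN",
) -> SyntheticTruth:
    """Simulate a monthly panel of ``T`` months with known dynamics.

    Variable order is the order of the ``seasonal`` dict and indexes the
    rows/columns of the dynamics matrices. Identical ``(seed, specs)`` give
    bit-identical output.
    """
    if T < 24:
        raise ValueError("T must be >= 24 months (two annual cycles)")
    names = tuple(seasonal)
    k = len(names)
    if dynamics.k != k:
        raise ValueError(f"dynamics dimension {dynamics.k} != number of variables {k}")
    rho = dynamics.average_spectral_radius(T)
    if rho >= 1.0:
        raise ValueError(
            f"time-average dynamics are non-stationary: companion spectral radius {rho:.4f} >= 1"
        )
    if seed is None:
        seed = dynamics.seed if dynamics.seed is not None else 0
    rng = np.random.default_rng(seed)

    coeff = dynamics.coeff_path(T)
    contemp = dynamics.contemp_path(T)
    log_vol = dynamics.log_vol_path(T)
    intercept = dynamics.intercept_path(T)

    p = dynamics.p
    x = np.zeros((T + p, k))
    eps = rng.standard_normal((T, k))
    for t in range(T):
        mean = intercept[t].copy()
        for lag in range(p):
            mean += coeff[t, lag] @ x[t + p - 1 - lag]
        shock = np.linalg.solve(contemp[t], np.exp(log_vol[t] / 2.0) * eps[t])
        x[t + p] = mean + shock
    anom = x[p:]

    dates = pd.date_range(start, periods=T, freq="MS")
    t_idx = np.arange(T)
    data = {}
    for j, name in enumerate(names):
        spec = seasonal[name]
        harmonic = spec.mean + spec.amplitude * np.sin(2 * np.pi * t_idx / 12.0 + spec.phase)
        series = harmonic + spec.noise_sd * anom[:, j]
        data[name] = np.clip(series, spec.vmin, spec.vmax)
    panel = pd.DataFrame(data, index=dates)
    panel.index.name = "date"
    panel.attrs["site"] = site
    return SyntheticTruth(
        panel=panel,
        dynamics=dynamics,
        seasonal=dict(seasonal),
        anomalies=pd.DataFrame(anom, index=dates, columns=list(names)),
        true_irf=_true_irf_path(dynamics, T, irf_horizon),
        irf_horizon=irf_horizon,
        variables=names,
    )


def inject_shock(
    panel: pd.DataFrame,
    month: str | pd.Timestamp,
    deltas: dict[str, float],
    ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Add per-variable offsets to a single month (typhoon-style event).

    Only the stated month changes, by exactly the stated offsets (then
    clamped to the variable range if one is supplied); every other cell is
    bit-identical to the input.
    """
    ts = pd.Timestamp(month)
    if ts not in panel.index:
        raise ValueError(f"shock month {ts.date()} outside panel span")
    out = panel.copy()
    for name, delta in deltas.items():
        if name not in out.columns:
            raise ValueError(f"unknown variable {name!r}")
        value = out.at[ts, name] + delta
        if ranges and name in ranges:
            lo, hi = ranges[name]
            value = min(max(value, lo), hi)
        out.at[ts, name] = value
    out.attrs = dict(panel.attrs)
    return out


def generate_composites(
    monthly_evi: pd.Series,
    per_month: int = 2,
    cloud_noise: tuple[float, float] = (0.3, 0.15),
    jitter_sd: float = 0.01,
    seed: int | None = None,
) -> CompositeSeries:
    """Sub-monthly composites around a monthly EVI truth, with cloud noise.

    Each month yields ``per_month`` observations equal to the monthly truth
    plus Gaussian jitter; each is independently depressed -- never raised --
    with probability ``cloud_noise[0]`` by a strictly positive amount drawn
    as ``magnitude * U(0.5, 1.5)``, emulating the low-biased contamination
    that maximum-value compositing targets.
    """
    prob, magnitude = cloud_noise
    if per_month < 2:
        raise ValueError("per_month must be >= 2")
    if not 0.0 <= prob <= 1.0:
        raise ValueError("cloud probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dates, values = [], []
    day_step = 28 // per_month
    for ts, truth in monthly_evi.items():
        for i in range(per_month):
            obs = truth + (jitter_sd and rng.normal(0.0, jitter_sd))
            if rng.random() < prob:
                obs -= magnitude * rng.uniform(0.5, 1.5)
            dates.append(pd.Timestamp(ts) + pd.Timedelta(days=i * day_step))
            values.append(np.clip(obs, -1.0, 1.0))
    return CompositeSeries(pd.DatetimeIndex(dates), np.asarray(values))


def station_seasonal_specs(station: str = "DHF", evi_noise_sd: float = 0.03) -> dict[str, SeasonalSpec]:
    """Seasonal specs emulating one station's published variable ranges.

    Means/amplitudes are placed so the annual harmonic spans roughly the
    middle 80% of the published climate-range of the station, with modest
    anomaly noise; EVI ranges are not published, so a canopy-typical
    0.2-0.6 annual sweep is used. Order: EVI first, then TEM, RHU, PRE, PAR
    (matching the panel CSV column convention).
    """
    from .published import STATION_RANGES

    ranges = STATION_RANGES[station]
    specs: dict[str, SeasonalSpec] = {
        "EVI": SeasonalSpec(
            mean=0.40, amplitude=0.18, phase=-np.pi / 2, noise_sd=evi_noise_sd,
            vmin=-1.0, vmax=1.0,
        )
    }
    for name in ("TEM", "RHU", "PRE", "PAR"):
        lo, hi = ranges[name]
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        specs[name] = SeasonalSpec(
            mean=mid, amplitude=0.8 * half, phase=-np.pi / 2,
            noise_sd=0.08 * half, vmin=lo, vmax=hi,
        )
    return specs
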
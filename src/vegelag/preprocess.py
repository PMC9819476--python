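"""Monthly EVI reconstruction from noisy sub-monthly composites.

The chain mirrors standard vegetation-index practice: per-month maximum
value compositing (MVC) suppresses the cloud-induced low-biased noise,
a Savitzky-Golay (SG) local-polynomial smoother removes residual
high-frequency noise, and HANTS (Harmonic ANalysis of Time Series) fits a
truncated Fourier basis by iterated least squares with low-side outlier
rejection, yielding a gap-free harmonic reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompositeSeries",
    "SgParams",
    "HantsParams",
    "ReconstructionResult",
    "mvc_monthly",
    "sg_filter",
    "hants_reconstruct",
    "sg_hants",
]


@dataclass(frozen=True)
class CompositeSeries:
    """Ordered sub-monthly EVI observations, >=1 per calendar month."""

    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.dates) != len(values):
            raise ValueError("dates and values must have equal length")
        if len(self.dates) == 0:
            raise ValueError("empty composite series")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("composite dates must be strictly increasing")
        if np.any(values < -1.0) or np.any(values > 1.0):
            raise ValueError("EVI composites must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "value": self.values})


@dataclass(frozen=True)
class SgParams:
    """Savitzky-Golay window half-width (months) and polynomial order."""

    half_width: int = 2
    order: int = 2

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be a positive integer")
        if self.order < 0:
            raise ValueError("polynomial order must be non-negative")
        if 2 * self.half_width + 1 <= self.order:
            raise ValueError("window length 2m+1 must exceed polynomial order")


@dataclass(frozen=True)
class HantsParams:
    """HANTS configuration.

    ``fet`` is the fit-error tolerance in EVI units. Vegetation-index
    products ship integer-scaled values (scale factor 1e-4), where the
    customary tolerance of 500 raw counts corresponds to 0.05 EVI; pass
    ``fet_raw``/``fet_scale`` to configure on the raw scale instead.
    ``dod`` is the minimum number of retained points ("degree of
    over-determinedness" floor). ``base_period`` is the fundamental period
    in samples; 12 makes frequency 1 annual and frequency 2 semi-annual on
    monthly data, with the fit spanning all years jointly.
    """

    frequencies: int = 2
    fet: float | None = None
    dod: int = 8
    base_period: int = 12
    fet_raw: float = 500.0
    fet_scale: float = 1e-4
    low_side_only: bool = True

    def __post_init__(self) -> None:
        if self.frequencies < 1:
            raise ValueError("frequencies must be a positive integer")
        if self.fet is None:
            object.__setattr__(self, "fet", self.fet_raw * self.fet_scale)
        if self.fet <= 0:
            raise ValueError("FET must be positive")
        if self.dod < self.n_params:
            raise ValueError(
                f"DOD ({self.dod}) must be >= number of fitted parameters ({self.n_params})"
            )

    @property
    def n_params(self) -> int:
        return 2 * self.frequencies + 1


@dataclass
class ReconstructionResult:
    """Harmonic reconstruction with fit metadata."""

    reconstruction: np.ndarray
    a0: float
    amplitudes: np.ndarray
    phases: np.ndarray
    outlier_indices: list[int] = field(default_factory=list)
    residuals: np.ndarray | None = None


def mvc_monthly(composites: CompositeSeries) -> pd.Series:
    """Monthly maximum-value composite.

    Returns a calendar-complete monthly series (month-start index) where
    each month's value is the maximum of that month's composites. Raises if
    any month inside the span has no observation.
    """
    frame = composites.to_frame()
    periods = frame["date"].dt.to_period("M")
    monthly = frame.groupby(periods)["value"].max()
    full = pd.period_range(periods.iloc[0], periods.iloc[-1], freq="M")
    missing = full.difference(monthly.index)
    if len(missing):
        raise ValueError(f"months without composites: {[str(m) for m in missing]}")
    out = monthly.reindex(full)
    out.index = out.index.to_timestamp(how="start")
    out.name = "EVI"
    return out


def sg_filter(series: np.ndarray | pd.Series, params: SgParams = SgParams()) -> np.ndarray | pd.Series:
    """Savitzky-Golay smoothing by local least-squares polynomial fits.

    Interior point j is the center value of the best-fit polynomial of the
    configured order over the symmetric window of 2m+1 points. At the
    boundaries the window shrinks asymmetrically to the available points
    (same polynomial order), avoiding padding artifacts on short series.
    The map is linear in the input.
    """
    values = np.asarray(series, dtype=float)
    if values.ndim != 1:
        raise ValueError("sg_filter expects a 1-D series")
    if np.any(~np.isfinite(values)):
        raise ValueError("sg_filter requires a complete (no-missing) series")
    n = len(values)
    m = params.half_width
    if n < 2 * m + 1:
        raise ValueError(f"series length {n} shorter than SG window {2 * m + 1}")
    out = np.empty(n)
    for j in range(n):
        lo, hi = max(0, j - m), min(n, j + m + 1)
        x = np.arange(lo, hi) - j
        order = min(params.order, hi - lo - 1)
        # Vandermonde least squares evaluated at the window center (x=0):
        # the fitted value is the constant coefficient.
        coeffs = np.polynomial.polynomial.polyfit(x, values[lo:hi], order)
        out[j] = coeffs[0]
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out


def _hants_design(n_points: int, params: HantsParams) -> np.ndarray:
    i = np.arange(n_points, dtype=float)
    cols = [np.ones(n_points)]
    for j in range(1, params.frequencies + 1):
        w = 2.0 * np.pi * j / params.base_period
        cols.append(np.sin(w * i))
        cols.append(np.cos(w * i))
    return np.column_stack(cols)


def hants_reconstruct(
    series: np.ndarray | pd.Series, params: HantsParams = HantsParams()
) -> ReconstructionResult:
    """Iterative harmonic fit with low-side outlier rejection.

    Fits ``y_i = A0 + sum_j A_j sin(w_j i + theta_j)``, ``w_j = 2 pi j / n``
    (n the base period), by least squares over the retained points. On each
    pass the worst point lying *below* the fitted curve by more than the FET
    tolerance is dropped and the curve refit; iteration stops when no
    residual exceeds the tolerance or only ``dod`` points remain. Cloud and
    rain contamination depresses vegetation indices, hence only low-side
    outliers are removable by default (``low_side_only``).
    """
    values = np.asarray(series, dtype=float)
    if values.ndim != 1:
        raise ValueError("hants_reconstruct expects a 1-D series")
    n = len(values)
    if n < params.dod:
        raise ValueError(f"series length {n} shorter than DOD {params.dod}")
    design = _hants_design(n, params)
    retained = np.ones(n, dtype=bool)
    outliers: list[int] = []
    while True:
        coef, *_ = np.linalg.lstsq(design[retained], values[retained], rcond=None)
        fitted = design @ coef
        resid = values - fitted
        if retained.sum() <= params.dod:
            break
        # candidate outliers: below the curve by more than FET (and, if
        # enabled, above it) among retained points
        exceed = (-resid > params.fet) & retained
        if not params.low_side_only:
            exceed |= (np.abs(resid) > params.fet) & retained
        if not exceed.any():
            break
        # drop the single worst offender, then refit (deterministic order)
        candidates = np.flatnonzero(exceed)
        worst = candidates[np.argmax(np.abs(resid[candidates]))]
        retained[worst] = False
        outliers.append(int(worst))
    a0 = float(coef[0])
    sin_c = coef[1::2]
    cos_c = coef[2::2]
    amplitudes = np.hypot(sin_c, cos_c)
    # A sin(wt + theta) = A cos(theta) sin(wt) + A sin(theta) cos(wt)
    phases = np.arctan2(cos_c, sin_c)
    return ReconstructionResult(
        reconstruction=fitted,
        a0=a0,
        amplitudes=amplitudes,
        phases=phases,
        outlier_indices=sorted(outliers),
        residuals=resid,
    )


def sg_hants(
    series: np.ndarray | pd.Series,
    sg_params: SgParams = SgParams(),
    hants_params: HantsParams = HantsParams(),
) -> ReconstructionResult:
    """SG smoothing followed by HANTS reconstruction of the smoothed series."""
    smoothed = sg_filter(series, sg_params)
    return hants_reconstruct(np.asarray(smoothed, dtype=float), hants_params)
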
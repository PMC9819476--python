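"""Constant-parameter VAR: equation-by-equation OLS, Cholesky-identified
impulse responses, and recursive conditional-mean forecasts.

This is both the comparison baseline for the time-varying model and the
closed-form oracle for its constant-parameter limit. Estimation is plain
OLS per equation (identical regressors), with a degrees-of-freedom
corrected residual covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarModel",
    "ImpulseResponseArray",
    "fit_var",
    "var_irf",
    "var_forecast",
    "companion_matrix",
    "impulse_responses",
    "spectral_radius",
]


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of stacked (p, k, k) lag matrices: (kp, kp)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    p, k, _ = coeffs.shape
    comp = np.zeros((k * p, k * p))
    comp[:k] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    return comp


def spectral_radius(coeffs: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))


def impulse_responses(coeffs: np.ndarray, impact: np.ndarray, horizon: int) -> np.ndarray:
    """Responses (k, k, horizon+1) of a VAR with given lag matrices.

    ``r[i, j, h]`` is the response of variable i at horizon h to the shock
    whose impact-period effect is column j of ``impact``; r[:, :, 0] =
    impact, r[:, :, h] = Psi_h @ impact with Psi_h the MA matrices obtained
    from powers of the companion matrix.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    k = coeffs.shape[1]
    comp = companion_matrix(coeffs)
    out = np.empty((k, k, horizon + 1))
    out[:, :, 0] = impact
    power = np.eye(comp.shape[0])
    for h in range(1, horizon + 1):
        power = comp @ power
        out[:, :, h] = power[:k, :k] @ impact
    return out


@dataclass
class VarModel:
    """OLS-estimated constant-parameter VAR."""

    p: int
    intercept: np.ndarray  # (k,); zeros when fitted without intercept
    coeffs: np.ndarray  # (p, k, k)
    sigma_u: np.ndarray  # (k, k) dof-corrected innovation covariance
    variables: tuple[str, ...]
    t_eff: int
    has_intercept: bool = True

    @property
    def k(self) -> int:
        return len(self.variables)

    def stable(self) -> bool:
        return spectral_radius(self.coeffs) < 1.0

    def loglike_sigma_mle(self) -> np.ndarray:
        """Residual covariance without dof correction (for criteria)."""
        k_per_eq = self.k * self.p + int(self.has_intercept)
        return self.sigma_u * (self.t_eff - k_per_eq) / self.t_eff


@dataclass
class ImpulseResponseArray:
    """Responses indexed by (response variable, shock variable, horizon)."""

    values: np.ndarray  # (k, k, H+1)
    variables: tuple[str, ...]
    ordering: tuple[str, ...]
    shock: str  # "sd" (one standard deviation) or "unit"

    @property
    def horizon(self) -> int:
        return self.values.shape[2] - 1

    def response(self, response: str, shock: str) -> np.ndarray:
        i = self.variables.index(response)
        j = self.variables.index(shock)
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, resp in enumerate(self.variables):
            for j, shk in enumerate(self.variables):
                for h in range(self.values.shape[2]):
                    rows.append((resp, shk, h, self.values[i, j, h]))
        frame = pd.DataFrame(rows, columns=["response", "shock", "horizon", "value"])
        frame.attrs["ordering"] = ",".join(self.ordering)
        frame.attrs["shock_convention"] = self.shock
        return frame


def _design(data: np.ndarray, p: int, intercept: bool) -> tuple[np.ndarray, np.ndarray]:
    T, k = data.shape
    y = data[p:]
    blocks = [data[p - lag - 1 : T - lag - 1] for lag in range(p)]
    X = np.concatenate(blocks, axis=1)
    if intercept:
        X = np.column_stack([np.ones(T - p), X])
    return y, X


def fit_var(panel: pd.DataFrame | np.ndarray, p: int, intercept: bool = True) -> VarModel:
    """Equation-by-equation OLS fit of a VAR(p)."""
    if isinstance(panel, pd.DataFrame):
        variables = tuple(panel.columns)
        data = panel.to_numpy(dtype=float)
    else:
        data = np.asarray(panel, dtype=float)
        variables = tuple(f"y{i}" for i in range(data.shape[1]))
    T, k = data.shape
    if p < 1:
        raise ValueError("lag order must be >= 1")
    n_params = k * p + int(intercept)
    t_eff = T - p
    if t_eff < n_params + 2:
        raise ValueError(f"effective sample {t_eff} too short for {n_params} parameters per equation")
    y, X = _design(data, p, intercept)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient regressor matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)  # (n_params, k)
    resid = y - X @ beta
    sigma = resid.T @ resid / (t_eff - n_params)
    if intercept:
        c = beta[0].copy()
        lagged = beta[1:]
    else:
        c = np.zeros(k)
        lagged = beta
    coeffs = np.stack([lagged[lag * k : (lag + 1) * k].T for lag in range(p)])
    return VarModel(
        p=p, intercept=c, coeffs=coeffs, sigma_u=sigma,
        variables=variables, t_eff=t_eff, has_intercept=intercept,
    )


def _ordered_cholesky(sigma: np.ndarray, variables: tuple[str, ...], ordering: tuple[str, ...]) -> np.ndarray:
    """Lower-triangular impact matrix under ``ordering``, in panel order.

    The covariance is permuted into the identification ordering, factored,
    and the factor permuted back, so the returned matrix is triangular with
    respect to the ordering (not necessarily the storage order).
    """
    perm = [variables.index(v) for v in ordering]
    sig = np.asarray(sigma, dtype=float)[np.ix_(perm, perm)]
    eigmin = float(np.min(np.linalg.eigvalsh((sig + sig.T) / 2)))
    if eigmin < -1e-10:
        raise np.linalg.LinAlgError(f"innovation covariance not PSD (min eigenvalue {eigmin:.3e})")
    chol = np.linalg.cholesky(sig + 1e-14 * np.eye(len(perm)))
    out = np.zeros_like(chol)
    for a, i in enumerate(perm):
        for b, j in enumerate(perm):
            out[i, j] = chol[a, b]
    return out


def var_irf(
    model: VarModel,
    horizon: int = 6,
    ordering: tuple[str, ...] | None = None,
    shock: str = "sd",
) -> ImpulseResponseArray:
    """Cholesky-identified impulse responses to horizon ``horizon``.

    ``shock="sd"`` applies one-standard-deviation orthogonalized shocks
    (impact matrix = permuted Cholesky factor of the innovation covariance);
    ``shock="unit"`` rescales each shock column so the shocked variable
    moves by one normalized unit on impact.
    """
    ordering = tuple(ordering) if ordering else model.variables
    if set(ordering) != set(model.variables):
        raise ValueError("ordering must be a permutation of the model variables")
    impact = _ordered_cholesky(model.sigma_u, model.variables, ordering)
    if shock == "unit":
        impact = impact / np.diag(impact)[None, :]
    elif shock != "sd":
        raise ValueError("shock must be 'sd' or 'unit'")
    values = impulse_responses(model.coeffs, impact, horizon)
    return ImpulseResponseArray(values=values, variables=model.variables, ordering=ordering, shock=shock)


def var_forecast(model: VarModel, panel: pd.DataFrame | np.ndarray, h_steps: int) -> np.ndarray:
    """Recursive conditional-mean forecast (innovations at zero), (h, k)."""
    data = panel.to_numpy(dtype=float) if isinstance(panel, pd.DataFrame) else np.asarray(panel, float)
    if data.ndim != 2 or data.shape[0] < model.p:
        raise ValueError(f"need at least p={model.p} final observations to forecast")
    history = list(data[-model.p:])
    out = np.empty((h_steps, model.k))
    for step in range(h_steps):
        mean = model.intercept.copy()
        for lag in range(model.p):
            mean += model.coeffs[lag] @ history[-1 - lag]
        out[step] = mean
        history.append(mean)
    return out
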
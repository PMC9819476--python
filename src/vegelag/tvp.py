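"""Bayesian time-varying-parameter VAR with stochastic volatility.

Model (for a k-variable monthly panel y_t, t = 1..T):

    y_t = X_t beta_t + A_t^{-1} D_t^{1/2} eps_t,     eps_t ~ N(0, I_k)

with X_t = I_k (x) [1, y_{t-1}', ..., y_{t-p}'], A_t unit lower triangular
(free elements a_t, stacked row-wise), and D_t = diag(exp(h_t)). The
time-varying intercept and lag coefficients beta_t, the contemporaneous
relations a_t, and the log volatilities h_t all follow independent random
walks with diagonal innovation covariances Sigma_beta, Sigma_a, Sigma_h.

Estimation is a Gibbs sampler cycling four blocks:

1. beta path  -- forward-filtering backward-sampling (FFBS) on the linear
   Gaussian state space conditional on (a, h);
2. a path     -- per-equation FFBS on the regression of each orthogonalized
   residual on the preceding residuals, conditional on (beta, h);
3. h paths    -- per-series FFBS after a 7-component mixture-of-normals
   (Kim-Shephard-Chib) approximation of the log chi^2(1) measurement error;
   a single-move Metropolis fallback is available for verification;
4. hyperparameters -- each diagonal innovation variance from its
   inverse-gamma conditional.

Everything is driven by one seeded generator, so identical configurations
reproduce identical draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

from .var import impulse_responses

__all__ = [
    "TvpPriorConfig",
    "McmcConfig",
    "PosteriorDraws",
    "TimeVaryingIrf",
    "ForecastDistribution",
    "fit_tvp_var",
    "tvp_irf",
    "tvp_forecast",
]

# Kim-Shephard-Chib (1998) 7-component normal mixture approximating the
# distribution of log(chi^2_1): probabilities, means, variances.
_KSC_PROB = np.array([0.00730, 0.10556, 0.00002, 0.04395, 0.34001, 0.24566, 0.25750])
_KSC_MEAN = np.array([-10.12999, -3.97281, -8.56686, 2.77786, 0.61942, -1.79518, -5.33566])
_KSC_VAR = np.array([5.79596, 2.61369, 5.17950, 0.16735, 0.64009, 0.34023, 1.26261])


@dataclass(frozen=True)
class TvpPriorConfig:
    """Weakly-informative defaults on the normalized [0, 1] data scale.

    Each diagonal element of Sigma_beta / Sigma_a / Sigma_h has an
    inverse-gamma prior IG(shape, scale) (density ~ x^{-shape-1} e^{-scale/x});
    the beta prior concentrates on small month-to-month coefficient drift,
    the a and h priors are looser. Initial states are N(mean, var * I).
    """

    beta_shape: float = 20.0
    beta_scale: float = 1e-3
    a_shape: float = 4.0
    a_scale: float = 1e-2
    h_shape: float = 4.0
    h_scale: float = 1e-2
    state0_mean: float = 0.0
    state0_var: float = 10.0

    def __post_init__(self) -> None:
        for name in ("beta_shape", "beta_scale", "a_shape", "a_scale", "h_shape", "h_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.state0_var <= 0:
            raise ValueError("initial-state variance must be positive")


@dataclass(frozen=True)
class McmcConfig:
    iterations: int = 2000
    burn_in: int = 500
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thin < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


def _tril_indices(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(1, k) for j in range(i)]


@numba.njit(cache=False)
def _ffbs_mv_core(y, Z, R, q, m0, prior_mean, prior_var, normals):  # pragma: no cover - numba
    """Carter-Kohn draw of the stacked coefficient path (numba kernel).

    ``normals`` supplies the (T, nb) standard-normal variates so the kernel
    is a pure function of its inputs and the caller's seeded generator.
    """
    T, k = y.shape
    nb = prior_mean.shape[0]
    ms = np.empty((T, nb))
    Ps = np.empty((T, nb, nb))
    m = prior_mean.copy()
    P = np.diag(prior_var)
    Q = np.diag(q)
    jit = 1e-12 * np.eye(nb)
    for t in range(T):
        if t > 0:
            P = P + Q
        z = Z[t]
        # Z_t = I_k (x) z', so Z_t P has k rows z' P[block_i, :]
        ZP = np.zeros((k, nb))
        for i in range(k):
            for a in range(m0):
                za = z[a]
                row = i * m0 + a
                for c in range(nb):
                    ZP[i, c] += za * P[row, c]
        S = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                acc = 0.0
                for a in range(m0):
                    acc += ZP[i, j * m0 + a] * z[a]
                S[i, j] = acc + R[t, i, j]
        S = (S + S.T) / 2.0
        v = np.empty(k)
        for i in range(k):
            acc = 0.0
            for a in range(m0):
                acc += m[i * m0 + a] * z[a]
            v[i] = y[t, i] - acc
        K = np.linalg.solve(S, ZP).T
        m = m + K @ v
        P = P - K @ ZP
        P = (P + P.T) / 2.0
        ms[t] = m
        Ps[t] = P
    draws = np.empty((T, nb))
    L = np.linalg.cholesky(Ps[T - 1] + jit)
    draws[T - 1] = ms[T - 1] + L @ normals[T - 1]
    for t in range(T - 2, -1, -1):
        P = Ps[t]
        G = np.linalg.solve(P + Q + jit, P).T  # P (P+Q)^{-1}
        mean = ms[t] + G @ (draws[t + 1] - ms[t])
        cov = P - G @ P
        cov = (cov + cov.T) / 2.0
        L = np.linalg.cholesky(cov + jit)
        draws[t] = mean + L @ normals[t]
    return draws


def _ffbs_multivariate(y, Z_rows, R, q, prior_mean, prior_var, rng):
    """Seeded wrapper around the multivariate FFBS kernel, (T, nb)."""
    T = y.shape[0]
    nb = prior_mean.shape[0]
    normals = rng.standard_normal((T, nb))
    return _ffbs_mv_core(y, Z_rows, R, q, Z_rows.shape[1], prior_mean, prior_var, normals)


@numba.njit(cache=False)
def _ffbs_scalar_core(y, X, obs_var, q, prior_mean, prior_var, normals):  # pragma: no cover - numba
    """FFBS for a d-dim random-walk state under scalar observations."""
    T, d = X.shape
    ms = np.empty((T, d))
    Ps = np.empty((T, d, d))
    m = prior_mean.copy()
    P = np.diag(prior_var)
    Q = np.diag(q)
    jit = 1e-12 * np.eye(d)
    for t in range(T):
        if t > 0:
            P = P + Q
        x = X[t]
        Px = P @ x
        s = np.dot(x, Px) + obs_var[t]
        K = Px / s
        m = m + K * (y[t] - np.dot(x, m))
        P = P - np.outer(K, Px)
        P = (P + P.T) / 2.0
        ms[t] = m
        Ps[t] = P
    draws = np.empty((T, d))
    L = np.linalg.cholesky(Ps[T - 1] + jit)
    draws[T - 1] = ms[T - 1] + L @ normals[T - 1]
    for t in range(T - 2, -1, -1):
        P = Ps[t]
        G = np.linalg.solve(P + Q + jit, P).T
        mean = ms[t] + G @ (draws[t + 1] - ms[t])
        cov = P - G @ P
        cov = (cov + cov.T) / 2.0
        L = np.linalg.cholesky(cov + jit)
        draws[t] = mean + L @ normals[t]
    return draws


def _ffbs_scalar_obs(y, X, obs_var, q, prior_mean, prior_var, rng):
    """Seeded wrapper around the scalar-observation FFBS kernel, (T, d)."""
    normals = rng.standard_normal(X.shape)
    return _ffbs_scalar_core(y, X, obs_var, q, prior_mean, prior_var, normals)


@numba.njit(cache=False)
def _h_ffbs_core(y, obs_var, q, prior_mean, prior_var, normals):  # pragma: no cover - numba
    """Scalar-state FFBS for one log-volatility path."""
    T = y.shape[0]
    ms = np.empty(T)
    Ps = np.empty(T)
    m = prior_mean
    P = prior_var
    for t in range(T):
        if t > 0:
            P = P + q
        s = P + obs_var[t]
        K = P / s
        m = m + K * (y[t] - m)
        P = P * (1.0 - K)
        ms[t] = m
        Ps[t] = P
    out = np.empty(T)
    out[T - 1] = ms[T - 1] + np.sqrt(max(Ps[T - 1], 0.0)) * normals[T - 1]
    for t in range(T - 2, -1, -1):
        G = Ps[t] / (Ps[t] + q)
        mean = ms[t] + G * (out[t + 1] - ms[t])
        var = Ps[t] * (1.0 - G)
        out[t] = mean + np.sqrt(max(var, 0.0)) * normals[t]
    return out


def _sample_h_mixture(
    log_e2: np.ndarray,  # (T,) log squared orthogonalized residuals
    h: np.ndarray,  # (T,) current path
    q: float,
    prior_mean: float,
    prior_var: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mixture-of-normals FFBS update of one log-volatility path."""
    T = len(log_e2)
    # component indicators given current h
    dev = log_e2[:, None] - h[:, None] - _KSC_MEAN[None, :]
    logp = np.log(_KSC_PROB)[None, :] - 0.5 * dev**2 / _KSC_VAR[None, :] - 0.5 * np.log(_KSC_VAR)[None, :]
    logp -= logp.max(axis=1, keepdims=True)
    prob = np.exp(logp)
    prob /= prob.sum(axis=1, keepdims=True)
    u = rng.random(T)
    comp = (prob.cumsum(axis=1) < u[:, None]).sum(axis=1)
    y = log_e2 - _KSC_MEAN[comp]
    obs_var = _KSC_VAR[comp]
    normals = rng.standard_normal(T)
    return _h_ffbs_core(y, obs_var, q, prior_mean, prior_var, normals)


def _sample_h_single_move(
    e: np.ndarray,  # (T,) orthogonalized residuals
    h: np.ndarray,
    q: float,
    prior_mean: float,
    prior_var: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-move Metropolis update of one log-volatility path (fallback).

    Proposes from the random-walk prior conditional of h_t given its
    neighbours and accepts with the measurement-likelihood ratio
    exp(-(h+ e^2 e^{-h})/2); slower mixing than the mixture sampler but an
    exact-target cross-check.
    """
    T = len(e)
    out = h.copy()
    e2 = e**2
    for t in range(T):
        if t == 0:
            if T > 1:
                var = 1.0 / (1.0 / prior_var + 1.0 / q)
                mean = var * (prior_mean / prior_var + out[1] / q)
            else:
                mean, var = prior_mean, prior_var
        elif t == T - 1:
            mean, var = out[t - 1], q
        else:
            mean, var = (out[t - 1] + out[t + 1]) / 2.0, q / 2.0
        prop = mean + np.sqrt(var) * rng.standard_normal()
        log_acc = -0.5 * (prop + e2[t] * np.exp(-prop)) + 0.5 * (out[t] + e2[t] * np.exp(-out[t]))
        if np.log(rng.random()) < log_acc:
            out[t] = prop
    return out


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of the time-varying parameter paths."""

    beta: np.ndarray  # (n_draws, T_eff, nb)
    a: np.ndarray  # (n_draws, T_eff, na)
    h: np.ndarray  # (n_draws, T_eff, k)
    sig_beta: np.ndarray  # (n_draws, nb)
    sig_a: np.ndarray  # (n_draws, na)
    sig_h: np.ndarray  # (n_draws, k)
    variables: tuple[str, ...]
    p: int
    has_intercept: bool
    dates: pd.DatetimeIndex | None = None
    history: np.ndarray | None = None  # (p, k) final observations, fit ordering
    prior: TvpPriorConfig | None = None
    mcmc: McmcConfig | None = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def t_eff(self) -> int:
        return self.beta.shape[1]

    @property
    def k(self) -> int:
        return len(self.variables)

    @property
    def m0(self) -> int:
        return self.k * self.p + int(self.has_intercept)

    def coeff_matrices(self, draw: int, t: int) -> tuple[np.ndarray, np.ndarray]:
        """(intercept (k,), lag matrices (p, k, k)) implied by one draw at time t."""
        k, p = self.k, self.p
        rows = self.beta[draw, t].reshape(k, self.m0)
        if self.has_intercept:
            c = rows[:, 0].copy()
            lagged = rows[:, 1:]
        else:
            c = np.zeros(k)
            lagged = rows
        coeffs = np.stack([lagged[:, lag * k : (lag + 1) * k] for lag in range(p)])
        return c, coeffs

    def contemp_matrix(self, draw: int, t: int) -> np.ndarray:
        A = np.eye(self.k)
        for idx, (i, j) in enumerate(_tril_indices(self.k)):
            A[i, j] = self.a[draw, t, idx]
        return A

    def convergence(self) -> pd.DataFrame:
        """Geweke z-scores and inefficiency factors of the hyperparameters."""
        rows = {}
        chains = {
            **{f"sig_beta[{i}]": self.sig_beta[:, i] for i in range(self.sig_beta.shape[1])},
            **{f"sig_a[{i}]": self.sig_a[:, i] for i in range(self.sig_a.shape[1])},
            **{f"sig_h[{i}]": self.sig_h[:, i] for i in range(self.sig_h.shape[1])},
        }
        for name, chain in chains.items():
            rows[name] = {
                "mean": float(chain.mean()),
                "geweke_z": _geweke_z(chain),
                "inefficiency": _inefficiency_factor(chain),
            }
        return pd.DataFrame(rows).T


def _geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    n = len(chain)
    a = chain[: max(int(n * first), 2)]
    b = chain[-max(int(n * last), 2) :]
    var = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
    if var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(var))


def _inefficiency_factor(chain: np.ndarray, max_lag: int | None = None) -> float:
    """1 + 2 * sum of autocorrelations under a Parzen window."""
    n = len(chain)
    if max_lag is None:
        max_lag = min(n // 2, 100)
    x = chain - chain.mean()
    denom = float(x @ x)
    if denom == 0:
        return 1.0
    total = 1.0
    for lag in range(1, max_lag):
        z = lag / max_lag
        w = 1 - 6 * z**2 + 6 * z**3 if z <= 0.5 else 2 * (1 - z) ** 3
        rho = float(x[:-lag] @ x[lag:]) / denom
        total += 2.0 * w * rho
    return float(max(total, 1.0))


def fit_tvp_var(
    panel: pd.DataFrame | np.ndarray,
    p: int,
    priors: TvpPriorConfig = TvpPriorConfig(),
    mcmc: McmcConfig = McmcConfig(),
    ordering: tuple[str, ...] | None = None,
    intercept: bool = True,
    sv_method: str = "mixture",
) -> PosteriorDraws:
    """Gibbs-sample the TVP-VAR posterior.

    ``ordering`` fixes the recursive identification: the panel columns are
    re-ordered accordingly before fitting, so earlier variables do not react
    contemporaneously to later ones. All outputs are expressed in that
    ordering (recorded in ``PosteriorDraws.variables``).
    """
    if isinstance(panel, pd.DataFrame):
        if ordering is not None:
            missing = set(ordering) - set(panel.columns)
            if missing:
                raise ValueError(f"ordering names unknown variables: {sorted(missing)}")
            panel = panel[list(ordering)]
        variables = tuple(panel.columns)
        data = panel.to_numpy(dtype=float)
        dates = pd.DatetimeIndex(panel.index) if isinstance(panel.index, pd.DatetimeIndex) else None
    else:
        data = np.asarray(panel, dtype=float)
        if ordering is not None:
            raise ValueError("ordering by name requires a DataFrame panel")
        variables = tuple(f"y{i}" for i in range(data.shape[1]))
        dates = None
    if sv_method not in ("mixture", "single_move"):
        raise ValueError("sv_method must be 'mixture' or 'single_move'")
    T, k = data.shape
    if p < 1:
        raise ValueError("lag order must be >= 1")
    t_eff = T - p
    if t_eff < 30:
        raise ValueError(f"effective sample T - p = {t_eff} < 30")
    rng = np.random.default_rng(mcmc.seed)

    y = data[p:]
    z_cols = [np.ones((t_eff, 1))] if intercept else []
    z_cols += [data[p - lag - 1 : T - lag - 1] for lag in range(p)]
    Z_rows = np.concatenate(z_cols, axis=1)  # (T_eff, m0)
    m0 = Z_rows.shape[1]
    nb = k * m0
    tril = _tril_indices(k)
    na = len(tril)

    # initial parameter state
    beta = np.zeros((t_eff, nb))
    a_path = np.zeros((t_eff, na))
    resid0 = y - y.mean(axis=0)
    h_path = np.tile(np.log(resid0.var(axis=0) + 1e-8), (t_eff, 1))
    sig_beta = np.full(nb, priors.beta_scale / (priors.beta_shape + 1))
    sig_a = np.full(na, priors.a_scale / (priors.a_shape + 1))
    sig_h = np.full(k, priors.h_scale / (priors.h_shape + 1))

    n_ret = mcmc.n_retained
    out_beta = np.empty((n_ret, t_eff, nb))
    out_a = np.empty((n_ret, t_eff, na))
    out_h = np.empty((n_ret, t_eff, k))
    out_sb = np.empty((n_ret, nb))
    out_sa = np.empty((n_ret, na))
    out_sh = np.empty((n_ret, k))

    prior_mean_b = np.full(nb, priors.state0_mean)
    prior_var_b = np.full(nb, priors.state0_var)

    tril_rows = np.array([i for i, _ in tril], dtype=int)
    tril_cols = np.array([j for _, j in tril], dtype=int)

    def assemble_A(path: np.ndarray) -> np.ndarray:
        A_all = np.broadcast_to(np.eye(k), (t_eff, k, k)).copy()
        if na:
            A_all[:, tril_rows, tril_cols] = path
        return A_all

    kept = 0
    for sweep in range(mcmc.iterations):
        # --- observation covariances R_t = A^{-1} D A^{-T} (batched)
        A_all = assemble_A(a_path)
        Ainv = np.linalg.inv(A_all)
        R = np.einsum("tij,tj,tkj->tik", Ainv, np.exp(h_path), Ainv)
        # --- 1. beta path
        beta = _ffbs_multivariate(y, Z_rows, R, sig_beta, prior_mean_b, prior_var_b, rng)
        yhat_resid = y - np.einsum("tm,tkm->tk", Z_rows, beta.reshape(t_eff, k, m0))
        # --- 2. a path, equation by equation
        offset = 0
        for i in range(1, k):
            d = i
            X = -yhat_resid[:, :i]
            obs_var = np.exp(h_path[:, i])
            block = _ffbs_scalar_obs(
                yhat_resid[:, i], X, obs_var,
                sig_a[offset : offset + d],
                np.full(d, priors.state0_mean), np.full(d, priors.state0_var),
                rng,
            )
            a_path[:, offset : offset + d] = block
            offset += d
        # --- orthogonalized residuals e_t = A_t yhat_t
        e = np.einsum("tij,tj->ti", assemble_A(a_path), yhat_resid)
        # --- 3. h paths
        for i in range(k):
            if sv_method == "mixture":
                log_e2 = np.log(e[:, i] ** 2 + 1e-10)
                h_path[:, i] = _sample_h_mixture(
                    log_e2, h_path[:, i], sig_h[i], priors.state0_mean, priors.state0_var, rng
                )
            else:
                h_path[:, i] = _sample_h_single_move(
                    e[:, i], h_path[:, i], sig_h[i], priors.state0_mean, priors.state0_var, rng
                )
        # --- 4. hyperparameters (vectorized inverse-gamma conditionals)
        post_shape = (t_eff - 1) / 2.0
        db = np.diff(beta, axis=0)
        sig_beta = (priors.beta_scale + 0.5 * np.sum(db * db, axis=0)) / rng.gamma(
            priors.beta_shape + post_shape, 1.0, size=nb
        )
        if na:
            da = np.diff(a_path, axis=0)
            sig_a = (priors.a_scale + 0.5 * np.sum(da * da, axis=0)) / rng.gamma(
                priors.a_shape + post_shape, 1.0, size=na
            )
        dh = np.diff(h_path, axis=0)
        sig_h = (priors.h_scale + 0.5 * np.sum(dh * dh, axis=0)) / rng.gamma(
            priors.h_shape + post_shape, 1.0, size=k
        )
        # --- retain
        if sweep >= mcmc.burn_in and (sweep - mcmc.burn_in) % mcmc.thin == 0:
            out_beta[kept] = beta
            out_a[kept] = a_path
            out_h[kept] = h_path
            out_sb[kept] = sig_beta
            out_sa[kept] = sig_a
            out_sh[kept] = sig_h
            kept += 1

    return PosteriorDraws(
        beta=out_beta[:kept], a=out_a[:kept], h=out_h[:kept],
        sig_beta=out_sb[:kept], sig_a=out_sa[:kept], sig_h=out_sh[:kept],
        variables=variables, p=p, has_intercept=intercept,
        dates=dates[p:] if dates is not None else None,
        history=data[-p:].copy(), prior=priors, mcmc=mcmc,
    )


@dataclass
class TimeVaryingIrf:
    """Posterior summary of time-point impulse responses.

    Arrays are (n_times, k_response, k_shock, H+1); the parameters
    prevailing at each evaluation time are held fixed over the horizon.
    """

    times: list[int]
    mean: np.ndarray
    q_lower: np.ndarray
    q_upper: np.ndarray
    variables: tuple[str, ...]
    shock: str
    quantiles: tuple[float, float] = (0.05, 0.95)
    dates: list | None = None

    def response(self, response: str, shock: str, time_index: int = 0) -> np.ndarray:
        i = self.variables.index(response)
        j = self.variables.index(shock)
        return self.mean[time_index, i, j]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ti, t in enumerate(self.times):
            for i, resp in enumerate(self.variables):
                for j, shk in enumerate(self.variables):
                    for hh in range(self.mean.shape[3]):
                        rows.append(
                            (resp, shk, hh, t, self.mean[ti, i, j, hh],
                             self.q_lower[ti, i, j, hh], self.q_upper[ti, i, j, hh])
                        )
        frame = pd.DataFrame(rows, columns=["response", "shock", "horizon", "time", "mean", "q05", "q95"])
        frame.attrs["shock_convention"] = self.shock
        return frame


def _draw_irf(draws: PosteriorDraws, d: int, t: int, H: int, shock: str) -> np.ndarray:
    _, coeffs = draws.coeff_matrices(d, t)
    A = draws.contemp_matrix(d, t)
    sd = np.exp(draws.h[d].mean(axis=0) / 2.0)  # per-draw time-averaged shock sd
    impact = np.linalg.solve(A, np.diag(sd))
    if shock == "unit":
        impact = impact / np.diag(impact)[None, :]
    return impulse_responses(coeffs, impact, H)


def tvp_irf(
    draws: PosteriorDraws,
    times: int | list[int],
    H: int = 6,
    shock: str = "sd",
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> TimeVaryingIrf:
    """Time-point impulse responses summarized over the posterior draws.

    For each retained draw, the VAR matrices at evaluation time t and the
    impact matrix implied by A_t and the shock convention generate responses
    to horizon H with time-t parameters frozen; the cross-draw mean and the
    requested quantiles are returned. ``shock="sd"`` scales shock j by that
    draw's time-averaged innovation standard deviation exp(h_j/2);
    ``shock="unit"`` makes the impact of shock j on variable j equal one.
    """
    if shock not in ("sd", "unit"):
        raise ValueError("shock must be 'sd' or 'unit'")
    if H < 1:
        raise ValueError("horizon must be >= 1")
    time_list = [times] if isinstance(times, (int, np.integer)) else list(times)
    for t in time_list:
        if not 0 <= t < draws.t_eff:
            raise ValueError(f"evaluation time {t} outside sample [0, {draws.t_eff})")
    k = draws.k
    all_resp = np.empty((draws.n_draws, len(time_list), k, k, H + 1))
    for d in range(draws.n_draws):
        for ti, t in enumerate(time_list):
            all_resp[d, ti] = _draw_irf(draws, d, int(t), H, shock)
    lo, hi = quantiles
    return TimeVaryingIrf(
        times=[int(t) for t in time_list],
        mean=all_resp.mean(axis=0),
        q_lower=np.quantile(all_resp, lo, axis=0),
        q_upper=np.quantile(all_resp, hi, axis=0),
        variables=draws.variables,
        shock=shock,
        quantiles=quantiles,
        dates=[draws.dates[t] for t in time_list] if draws.dates is not None else None,
    )


@dataclass
class ForecastDistribution:
    mean: np.ndarray  # (h, k)
    quantiles: dict[float, np.ndarray]
    variables: tuple[str, ...]

    def column(self, name: str, which: str | float = "mean") -> np.ndarray:
        j = self.variables.index(name)
        if which == "mean":
            return self.mean[:, j]
        return self.quantiles[float(which)][:, j]


def tvp_forecast(
    draws: PosteriorDraws,
    panel: pd.DataFrame | np.ndarray | None,
    h_steps: int,
    quantiles: tuple[float, ...] = (0.05, 0.5, 0.95),
    stationary_only: bool = False,
) -> ForecastDistribution:
    """Posterior conditional-mean forecast from the final-period states.

    Per retained draw, the intercept and lag matrices at the last in-sample
    time are held fixed and the mean recursion is iterated ``h_steps`` ahead
    with innovations at zero; cross-draw mean and quantiles are returned.
    ``panel`` supplies the final p observations (defaults to the training
    data the sampler saw).

    ``stationary_only`` optionally imposes a stationarity constraint:
    draws whose final-period companion matrix has spectral radius >= 1 are
    excluded, a guard for ensembles dominated by explosive draws (iterating
    them amplifies without bound). It is off by default because fitted
    seasonal systems sit near the unit circle, where the constraint biases
    the ensemble toward damped cycles. If every draw is explosive the
    constraint is dropped.
    """
    from .var import companion_matrix
    if panel is None:
        history = draws.history
    elif isinstance(panel, pd.DataFrame):
        history = panel[list(draws.variables)].to_numpy(dtype=float)
    else:
        history = np.asarray(panel, dtype=float)
    if history is None or history.shape[0] < draws.p:
        raise ValueError(f"need at least p={draws.p} final observations to forecast")
    tail = history[-draws.p :]
    k = draws.k
    t_last = draws.t_eff - 1
    keep = []
    if stationary_only:
        for d in range(draws.n_draws):
            _, coeffs = draws.coeff_matrices(d, t_last)
            comp = companion_matrix(coeffs)
            if np.max(np.abs(np.linalg.eigvals(comp))) < 1.0:
                keep.append(d)
    if not keep:
        keep = list(range(draws.n_draws))
    paths = np.empty((len(keep), h_steps, k))
    for out_i, d in enumerate(keep):
        c, coeffs = draws.coeff_matrices(d, t_last)
        hist = list(tail)
        for step in range(h_steps):
            mean = c.copy()
            for lag in range(draws.p):
                mean += coeffs[lag] @ hist[-1 - lag]
            paths[out_i, step] = mean
            hist.append(mean)
    return ForecastDistribution(
        mean=paths.mean(axis=0),
        quantiles={float(q): np.quantile(paths, q, axis=0) for q in quantiles},
        variables=draws.variables,
    )
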
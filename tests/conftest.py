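"""Shared fixtures: small seeded synthetic panels and one reusable TVP fit.

The expensive MCMC fits are session-scoped so the whole suite pays for the
sampler (and its JIT compilation) once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import vegelag as vg
from vegelag.tvp import McmcConfig, TvpPriorConfig

#: Hyperpriors concentrating the random-walk innovation variances near zero,
#: the constant-parameter limit of the time-varying model.
TIGHT_PRIORS = TvpPriorConfig(
    beta_shape=100.0, beta_scale=1e-4,
    a_shape=100.0, a_scale=1e-4,
    h_shape=100.0, h_scale=1e-3,
)

UNIT_ANOMALY_SPECS = {
    "y0": vg.SeasonalSpec(mean=0.0, amplitude=0.0, noise_sd=1.0),
    "y1": vg.SeasonalSpec(mean=0.0, amplitude=0.0, noise_sd=1.0),
}

CONST_B = np.array([[0.5, 0.2], [0.1, 0.4]])
CONST_CONTEMP = np.array([[1.0, 0.0], [-0.5, 1.0]])


def constant_dynamics() -> vg.DynamicsSpec:
    """Bivariate constant VAR(1) with a real contemporaneous relation."""
    return vg.DynamicsSpec(
        p=1, coeffs=CONST_B.copy(), contemp=CONST_CONTEMP.copy(),
        log_vol=np.log(0.01) * np.ones(2),
    )


def bivariate_panel(dynamics: vg.DynamicsSpec, T: int, seed: int) -> pd.DataFrame:
    truth = vg.generate_panel(UNIT_ANOMALY_SPECS, dynamics, T=T, seed=seed)
    return truth.panel


@pytest.fixture(scope="session")
def const_panel() -> pd.DataFrame:
    return bivariate_panel(constant_dynamics(), T=131, seed=42)


@pytest.fixture(scope="session")
def const_ols(const_panel):
    return vg.fit_var(const_panel, p=1)


@pytest.fixture(scope="session")
def const_draws(const_panel):
    """TVP fit of the constant DGP under near-constant hyperpriors."""
    return vg.fit_tvp_var(
        const_panel, p=1, priors=TIGHT_PRIORS,
        mcmc=McmcConfig(iterations=800, burn_in=300, seed=7),
    )


def mc_se(chains: np.ndarray) -> np.ndarray:
    """Monte-Carlo standard error of the posterior mean along axis 0,
    inflated by each chain's inefficiency factor."""
    from vegelag.tvp import _inefficiency_factor

    flat = chains.reshape(chains.shape[0], -1)
    n = flat.shape[0]
    se = np.empty(flat.shape[1])
    for j in range(flat.shape[1]):
        se[j] = flat[:, j].std(ddof=1) * np.sqrt(_inefficiency_factor(flat[:, j]) / n)
    return se.reshape(chains.shape[1:])
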
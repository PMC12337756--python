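"""Simulation-based residual diagnostics for fitted mixed models.

Randomized quantile residuals in the style of the DHARMa workflow:
``n_sim`` response vectors are simulated unconditionally from the
fitted model (random intercepts redrawn), each observation's residual
is its randomized rank among its simulated counterparts — exactly
Uniform(0, 1) when the model is correct — and two checks follow:

* *uniformity*: a Kolmogorov-Smirnov test of the residuals against
  Uniform(0, 1);
* *dispersion*: the variance of observed raw residuals compared with
  the Monte-Carlo distribution of the same quantity over simulations,
  as a two-sided empirical p-value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .glmm import MovementGLMMResults

MIN_N_SIM = 250


class DiagnosticFlag(str, enum.Enum):
    OK = "ok"
    DEVIATION_SIGNIFICANT = "deviation_significant"


@dataclass(frozen=True)
class DiagnosticsReport:
    ks_uniformity_p: float
    dispersion_p: float
    dispersion_ratio: float  # observed / mean simulated residual variance
    n_sim: int
    flag: DiagnosticFlag

    def __post_init__(self):
        if self.n_sim < MIN_N_SIM:
            raise ValueError(f"n_sim must be >= {MIN_N_SIM}")


def quantile_residuals(
    observed: np.ndarray, simulated: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Randomized PIT residuals: (#sims below observed + U)/ (n_sim+1),
    with ties broken uniformly. Exactly U(0,1) under the model."""
    n_sim, n = simulated.shape
    below = (simulated < observed[None, :]).sum(axis=0)
    ties = (simulated == observed[None, :]).sum(axis=0)
    u = rng.uniform(size=n)
    return (below + u * (ties + 1.0)) / (n_sim + 1.0)


def residual_diagnostics(
    fit: MovementGLMMResults,
    n_sim: int = MIN_N_SIM,
    seed: int | np.random.Generator | None = 0,
    alpha: float = 0.05,
) -> DiagnosticsReport:
    """Uniformity and dispersion checks of a fitted model's residuals."""
    if n_sim < MIN_N_SIM:
        raise ValueError(f"n_sim must be >= {MIN_N_SIM}, got {n_sim}")
    rng = np.random.default_rng(seed)
    y = fit.model.endog
    sims = fit.simulate(n_sim, rng)

    resid = quantile_residuals(y, sims, rng)
    ks_p = float(sps.kstest(resid, "uniform").pvalue)

    center = sims.mean(axis=0)
    obs_var = float(np.var(y - center))
    sim_vars = np.var(sims - center[None, :], axis=1)
    n_le = int((sim_vars <= obs_var).sum())
    n_ge = int((sim_vars >= obs_var).sum())
    disp_p = float(min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (n_sim + 1)))

    flag = (DiagnosticFlag.OK if (ks_p > alpha and disp_p > alpha)
            else DiagnosticFlag.DEVIATION_SIGNIFICANT)
    return DiagnosticsReport(
        ks_uniformity_p=ks_p,
        dispersion_p=disp_p,
        dispersion_ratio=obs_var / max(float(sim_vars.mean()), 1e-300),
        n_sim=n_sim,
        flag=flag,
    )
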
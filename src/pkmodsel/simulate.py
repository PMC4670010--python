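"""Simulation of individual and population concentration data.

The data-generating truth is the power-of-time disposition curve
``y(t) = 1/t`` (an infinite sum of exponentials), so that any finite sum of
exponentials underfits it — the situation faced with real pharmacokinetic
data.  Populations carry a single lognormal random effect on the curve:

* additive-inside (default):  ``y_i(t_j) = (exp(eta_i) + eps_ij) / t_j``
* proportional variant:       ``y_i(t_j) = exp(eta_i) * (1 + eps_ij) / t_j``

with ``eta_i ~ N(0, omega2)`` i.i.d. across individuals and
``eps_ij ~ N(0, sigma2)`` i.i.d. across all observations.  Weighting
residuals by ``w(t_j) = 1/t_j`` makes them homoscedastic under the default
variant.  Note the proportional variant can yield non-positive
concentrations at large ``sigma2``; values are never clipped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TimeGrid

__all__ = ["ErrorModel", "PopulationData", "simulate_population", "true_curve"]


class ErrorModel(enum.Enum):
    """Residual-error placement in the generative model."""

    #: ``y = (exp(eta) + eps) / t`` — noise added inside the scaled curve.
    ADDITIVE_INSIDE = "additive"
    #: ``y = exp(eta) * (1 + eps) / t`` — noise proportional to the
    #: individual curve.
    PROPORTIONAL = "proportional"


@dataclass(frozen=True)
class PopulationData:
    """Simulated concentrations for ``N`` individuals on a shared grid.

    ``values[i, j]`` is the concentration of individual ``i`` at time
    ``grid.times[j]`` (arbitrary concentration units); ``weights[j] = 1/t_j``
    are the homoscedasticizing regression weights.  The realized random
    effects ``eta_true`` and the generating variances are retained so tests
    can condition on them.
    """

    grid: TimeGrid
    values: np.ndarray
    eta_true: np.ndarray
    sigma2_true: float
    omega2_true: float
    weights: np.ndarray
    seed: int
    error_model: ErrorModel = ErrorModel.ADDITIVE_INSIDE

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.grid.M

    @property
    def n_obs(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        """Tidy long layout: one row per observation.

        Columns ``individual`` (1-based), ``time``, ``concentration``,
        ``weight`` — the layout a population-PK tool expects.
        """
        N, M = self.values.shape
        return pd.DataFrame(
            {
                "individual": np.repeat(np.arange(1, N + 1), M),
                "time": np.tile(self.grid.times, N),
                "concentration": self.values.ravel(),
                "weight": np.tile(self.weights, N),
            }
        )


def true_curve(grid: TimeGrid) -> np.ndarray:
    """The generating disposition curve ``y(t_j) = 1/t_j``."""
    return 1.0 / grid.times


def simulate_population(
    grid: TimeGrid,
    N: int,
    sigma2: float,
    omega2: float,
    error_model: ErrorModel = ErrorModel.ADDITIVE_INSIDE,
    seed: int = 0,
) -> PopulationData:
    """Draw one population data set.

    Identical arguments give bit-identical output; validation sets are
    obtained with a different ``seed``.  Negative variances are rejected.
    With ``omega2 = 0`` the realized ``eta_true`` are exactly zero (the same
    underlying normal stream is consumed, so the residual draws do not
    depend on whether ``omega2`` is zero).
    """
    if N < 1:
        raise ValueError("N: must be a positive integer")
    if sigma2 < 0:
        raise ValueError("sigma2: variance must be non-negative")
    if omega2 < 0:
        raise ValueError("omega2: variance must be non-negative")
    error_model = ErrorModel(error_model)
    rng = np.random.default_rng(seed)
    eta = np.sqrt(omega2) * rng.standard_normal(N)
    eps = np.sqrt(sigma2) * rng.standard_normal((N, grid.M))
    inv_t = 1.0 / grid.times
    if error_model is ErrorModel.ADDITIVE_INSIDE:
        values = (np.exp(eta)[:, None] + eps) * inv_t[None, :]
    else:
        values = np.exp(eta)[:, None] * (1.0 + eps) * inv_t[None, :]
    return PopulationData(
        grid=grid,
        values=values,
        eta_true=eta,
        sigma2_true=float(sigma2),
        omega2_true=float(omega2),
        weights=inv_t,
        seed=int(seed),
        error_model=error_model,
    )
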
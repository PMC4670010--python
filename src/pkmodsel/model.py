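"""Sum-of-exponentials models for population concentration data.

Two estimators share one model class:

* weighted linear least squares (WLS) for data without interindividual
  variability: minimize ``sum_ij ((y_ij - yhat(t_j)) / w_j)**2`` with
  ``w_j = 1/t_j``; the residual variance is the maximum-likelihood mean of
  squared weighted residuals.

* maximum marginal likelihood for the single-random-effect nonlinear
  mixed-effects model ``yhat_i(t_j) = exp(eta_i) * sum_m alpha_m
  exp(-lambda_m t_j)``, ``eta_i ~ N(0, omega2)``, residual s.d.
  proportional to ``w_j``.  The per-individual integral over ``eta`` is
  computed by adaptive Gauss-Hermite quadrature centred at the conditional
  mode (one node reproduces the Laplace approximation).

All objective function values (OFV = -2 log likelihood) include the
``log(2*pi)`` constants, and variance parameters are counted as ordinary
parameters, so D = K + 1 for WLS fits and D = K + 2 for mixed fits.
Coefficients ``alpha`` are unconstrained in sign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import criteria
from .design import LambdaGrid, ModelSpec, TimeGrid, make_lambda_grid, make_time_grid
from .simulate import PopulationData

__all__ = [
    "FitSettings",
    "SumOfExponentials",
    "SumOfExponentialsResults",
    "FitResult",
    "design_matrix",
    "wls_fit",
    "nlme_fit",
    "marginal_ofv",
]

_LOG2PI = float(np.log(2.0 * np.pi))

#: omega2 estimates below this are reported as exactly zero.
OMEGA2_ZERO_TOL = 1e-10


@dataclass(frozen=True)
class FitSettings:
    """Tuning knobs of the mixed-effects estimator.

    n_quad
        Gauss-Hermite nodes for the marginal integral (1 = Laplace).
    omega2_start
        Starting value for the random-effect variance.
    max_restarts
        Perturbed restarts attempted before declaring non-convergence.
    maxiter
        Iteration cap of the outer quasi-Newton optimizer.
    """

    n_quad: int = 21
    omega2_start: float = 0.1
    max_restarts: int = 2
    maxiter: int = 500


def design_matrix(grid: TimeGrid, lambdas: LambdaGrid, model: ModelSpec) -> np.ndarray:
    """M x K matrix with column k equal to ``exp(-lambda_{m(k)} * t_j)``."""
    if model.M != grid.M or lambdas.rates.shape != (grid.M,):
        raise ValueError("model/lambda dimensions incompatible with grid")
    act = model.active
    if act.size == 0:
        raise ValueError("model: empty model has no design matrix")
    return np.exp(-np.outer(grid.times, lambdas.rates[act]))


class SumOfExponentials:
    """Model object binding one candidate model to one population data set.

    Parameters
    ----------
    data : PopulationData
        Observations of N individuals on a shared time grid.
    spec : ModelSpec
        The candidate model (active exponential terms).

    ``fit()`` dispatches to WLS or mixed-effects estimation and returns a
    :class:`SumOfExponentialsResults`.
    """

    def __init__(self, data: PopulationData, spec: ModelSpec):
        if spec.M != data.grid.M:
            raise ValueError("spec: mask length must equal the grid size M")
        self.data = data
        self.spec = spec
        self.grid = data.grid
        self.lambdas = make_lambda_grid(self.grid)
        self.exog = design_matrix(self.grid, self.lambdas, spec)
        t = self.grid.times
        # weighted design and weighted data: dividing by w = 1/t multiplies by t
        self._Xw = self.exog * t[:, None]
        self._u = data.values * t[None, :]
        # sum_j log w_j  (zero on the symmetric grid, kept general)
        self._sum_log_w = float(np.sum(np.log(data.weights)))

    @classmethod
    def from_dataframe(cls, df, spec: ModelSpec, t_max: float | None = None):
        """Build from a tidy frame with columns individual/time/concentration.

        The unique times must form a log-symmetric grid (they are checked
        against the grid formula for ``M`` times and the inferred or given
        ``t_max``).
        """
        times = np.sort(df["time"].unique())
        M = times.size
        t_max = float(times[-1]) if t_max is None else float(t_max)
        grid = make_time_grid(M, t_max)
        if not np.allclose(grid.times, times, rtol=1e-8):
            raise ValueError("time: values do not lie on a log-symmetric grid")
        wide = df.pivot_table(index="individual", columns="time",
                              values="concentration", sort=True)
        values = wide.to_numpy(dtype=float)
        if values.shape[1] != M or np.isnan(values).any():
            raise ValueError("concentration: incomplete individual profiles")
        data = PopulationData(
            grid=grid, values=values, eta_true=np.zeros(values.shape[0]),
            sigma2_true=float("nan"), omega2_true=float("nan"),
            weights=1.0 / grid.times, seed=-1,
        )
        return cls(data, spec)

    # ------------------------------------------------------------------ fit

    def fit(self, method: str = "auto", settings: FitSettings | None = None):
        """Estimate the model.

        ``method`` is ``"wls"``, ``"mixed"``, or ``"auto"`` (mixed exactly
        when the data were simulated with ``omega2 > 0`` — the study's own
        rule; explicit methods are for everything else).
        """
        settings = settings or FitSettings()
        if method == "auto":
            method = "mixed" if self.data.omega2_true > 0 else "wls"
        if method == "wls":
            return self._fit_wls()
        if method == "mixed":
            return self._fit_mixed(settings)
        raise ValueError(f"method: unknown method {method!r}")

    def _fit_wls(self):
        N, M = self.data.values.shape
        n = N * M
        ubar = self._u.mean(axis=0)
        coef, _, rank, _ = np.linalg.lstsq(self._Xw, ubar, rcond=None)
        converged = bool(rank == self.spec.K)
        g = self._Xw @ coef
        rss = float(np.sum((self._u - g[None, :]) ** 2))
        sigma2 = max(rss / n, 0.0)
        with np.errstate(divide="ignore"):
            ofv = n * (_LOG2PI + np.log(sigma2)) + 2 * N * self._sum_log_w + n
        alpha = np.zeros(M)
        alpha[self.spec.active] = coef
        cov = None
        if converged and sigma2 > 0:
            xtx = N * (self._Xw.T @ self._Xw)
            cov = sigma2 * np.linalg.inv(xtx)
        return SumOfExponentialsResults(
            model=self, spec=self.spec, alpha=alpha, sigma2=float(sigma2),
            omega2=None, ofv=float(ofv), converged=converged, method="wls",
            n_quad=None, cov_alpha=cov,
        )

    def _fit_mixed(self, settings: FitSettings):
        K = self.spec.K
        wls = self._fit_wls()
        # Optimize the mean coefficients in the orthonormal basis of the
        # weighted design (alpha = R^-1 beta, g = Q beta): the exponential
        # columns are nearly collinear at large K and the raw alpha space
        # is too ill-conditioned for a quasi-Newton optimizer.
        Q, R = np.linalg.qr(self._Xw)
        x0 = np.concatenate([
            R @ wls.alpha[self.spec.active],
            [np.log(max(wls.sigma2, 1e-8)), np.log(settings.omega2_start)],
        ])
        C_i = np.sum(self._u * self._u, axis=1)

        def neg2ll(theta):
            g = Q @ theta[:K]
            s2 = np.exp(theta[K])
            w2 = np.exp(theta[K + 1])
            return _mixed_neg2ll(self._u, C_i, g, s2, w2,
                                 self._sum_log_w, settings.n_quad)

        bounds = [(None, None)] * K + [(-30.0, 10.0), (-30.0, 10.0)]
        best = None
        rng = np.random.default_rng(20140528)  # deterministic restart stream
        for attempt in range(settings.max_restarts + 1):
            start = x0 if attempt == 0 else x0 + np.concatenate([
                0.1 * np.abs(x0[:K]) * rng.standard_normal(K)
                + 0.01 * rng.standard_normal(K),
                0.5 * rng.standard_normal(2),
            ])
            res = minimize(neg2ll, start, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": settings.maxiter,
                                    "maxfun": 20 * settings.maxiter})
            ok = res.success and np.isfinite(res.fun)
            if best is None or (np.isfinite(res.fun) and res.fun < best[0].fun - 1e-9):
                best = (res, ok)
            if ok and attempt == 0:
                break
        res, converged = best
        theta = res.x
        alpha = np.zeros(self.grid.M)
        alpha[self.spec.active] = np.linalg.solve(R, theta[:K])
        sigma2 = float(np.exp(theta[K]))
        omega2 = float(np.exp(theta[K + 1]))
        if omega2 < OMEGA2_ZERO_TOL:
            omega2 = 0.0
        converged = bool(converged and np.isfinite(res.fun) and sigma2 > 0)
        return SumOfExponentialsResults(
            model=self, spec=self.spec, alpha=alpha, sigma2=sigma2,
            omega2=omega2, ofv=float(res.fun), converged=converged,
            method="mixed", n_quad=settings.n_quad,
        )


class SumOfExponentialsResults:
    """Estimates, fit diagnostics, and predictive criteria for one fit.

    Attributes mirror a flat fit record: ``alpha`` (length M, exactly zero
    at inactive positions), ``sigma2``, ``omega2`` (None for WLS fits),
    ``ofv`` (full -2 log likelihood at the optimum), ``D`` (parameter count
    including variances), ``n_obs``, ``converged``.
    """

    def __init__(self, model, spec, alpha, sigma2, omega2, ofv, converged,
                 method, n_quad, cov_alpha=None):
        self.model = model
        self.spec = spec
        self.alpha = np.asarray(alpha, dtype=float)
        self.sigma2 = sigma2
        self.omega2 = omega2
        self.ofv = ofv
        self.converged = converged
        self.method = method
        self.n_quad = n_quad
        self.cov_alpha = cov_alpha

    @property
    def K(self) -> int:
        return self.spec.K

    @property
    def D(self) -> int:
        """Parameters counted for information criteria (alphas + variances)."""
        return self.K + (1 if self.omega2 is None else 2)

    @property
    def n_obs(self) -> int:
        return self.model.data.n_obs

    @property
    def aic(self) -> float:
        return criteria.aic(self.ofv, self.D)

    @property
    def aicc(self) -> float:
        return criteria.aicc(self.ofv, self.D, self.n_obs)

    def predict(self, times=None) -> np.ndarray:
        """Population prediction (random effect at zero) on the model grid
        or at arbitrary times."""
        if times is None:
            return self.model.exog @ self.alpha[self.spec.active]
        times = np.asarray(times, dtype=float)
        X = np.exp(-np.outer(times, self.model.lambdas.rates[self.spec.active]))
        return X @ self.alpha[self.spec.active]

    def ofv_v(self, validation: PopulationData) -> float:
        """OFV of validation data at the fitted parameters (the study's
        predictive-performance criterion)."""
        return criteria.ofv_v(self, validation)

    def prediction_error(self, validation: PopulationData,
                         weighting=criteria.Weighting.TRUE_WEIGHTS,
                         ref_prediction=None) -> float:
        return criteria.prediction_error(self, validation, weighting,
                                         ref_prediction=ref_prediction)

    def bse_alpha(self):
        """WLS standard errors of the active coefficients (None for mixed)."""
        if self.cov_alpha is None:
            return None
        return np.sqrt(np.diag(self.cov_alpha))

    def summary(self) -> str:
        spec = self.spec
        lines = [
            "Sum-of-exponentials fit",
            "=" * 47,
            f"model mask      : {spec.to_string()}   (K = {spec.K})",
            f"estimator       : {'weighted LS' if self.method == 'wls' else 'mixed effects (adaptive GH, %d nodes)' % self.n_quad}",
            f"individuals N   : {self.model.data.values.shape[0]}",
            f"observations    : {self.n_obs}",
            f"converged       : {self.converged}",
            f"OFV (-2 log L)  : {self.ofv:.6g}",
            f"D (parameters)  : {self.D}",
            f"AIC / AICc      : {self.aic:.6g} / {self.aicc:.6g}",
            "-" * 47,
            f"sigma2 (resid.) : {self.sigma2:.6g}",
        ]
        if self.omega2 is not None:
            lines.append(f"omega2 (IIV)    : {self.omega2:.6g}")
        bse = self.bse_alpha()
        lines.append("-" * 47)
        lines.append(" term   lambda        alpha" + ("        s.e." if bse is not None else ""))
        for k, m in enumerate(spec.active):
            row = (f"  {m + 1:3d}  {self.model.lambdas.rates[m]:9.4g}  "
                   f"{self.alpha[m]:11.5g}")
            if bse is not None:
                row += f"  {bse[k]:10.4g}"
            lines.append(row)
        return "\n".join(lines)

    def to_record(self) -> dict:
        """Flat record (one CSV row) of the fit."""
        return {
            "model": self.spec.to_string(),
            "K": self.K,
            "D": self.D,
            "method": self.method,
            "converged": self.converged,
            "ofv": self.ofv,
            "sigma2_hat": self.sigma2,
            "omega2_hat": self.omega2 if self.omega2 is not None else np.nan,
        }


#: Spec-level alias: a fit result is the results object itself.
FitResult = SumOfExponentialsResults


def wls_fit(pop: PopulationData, model: ModelSpec) -> SumOfExponentialsResults:
    """Weighted least squares fit of one candidate model (D = K + 1)."""
    return SumOfExponentials(pop, model).fit(method="wls")


def nlme_fit(pop: PopulationData, model: ModelSpec,
             settings: FitSettings | None = None) -> SumOfExponentialsResults:
    """Maximum marginal likelihood fit of the mixed model (D = K + 2)."""
    if pop.N < 2:
        raise ValueError("N: mixed-effects estimation needs at least 2 individuals")
    return SumOfExponentials(pop, model).fit(method="mixed", settings=settings)


# ---------------------------------------------------------------- likelihood


def _fixed_neg2ll(u: np.ndarray, g: np.ndarray, sigma2: float,
                  sum_log_w: float) -> float:
    N, M = u.shape
    n = N * M
    rss = float(np.sum((u - g[None, :]) ** 2))
    return n * (_LOG2PI + np.log(sigma2)) + 2 * N * sum_log_w + rss / sigma2


def _conditional_modes(A, C, B, sigma2, omega2):
    """Vectorized Newton search for the per-individual mode of the joint
    log density h(eta); returns (eta_hat, hpp at the mode).

    h(eta) = const - eta^2/(2 omega2) - S(eta)/(2 sigma2) with
    S(eta) = C - 2 e^eta A + e^{2 eta} B, so both derivatives are closed
    form.  Steps are damped to +-1; non-concave stragglers fall back to a
    grid search.
    """
    inv_w2 = 1.0 / omega2
    eta = np.zeros_like(A)
    for _ in range(200):
        s = np.exp(eta)
        hp = -eta * inv_w2 + (s * A - s * s * B) / sigma2
        hpp = -inv_w2 + (s * A - 2.0 * s * s * B) / sigma2
        denom = np.where(hpp < -1e-300, -hpp, inv_w2)
        step = np.clip(hp / denom, -1.0, 1.0)
        eta = np.clip(eta + step, -60.0, 60.0)
        if np.max(np.abs(step)) < 1e-12:
            break
    s = np.exp(eta)
    hp = -eta * inv_w2 + (s * A - s * s * B) / sigma2
    hpp = -inv_w2 + (s * A - 2.0 * s * s * B) / sigma2
    bad = (hpp >= -1e-300) | (np.abs(hp) > 1e-6 * (1.0 + inv_w2))
    if np.any(bad):
        span = 6.0 * np.sqrt(omega2) + 6.0
        grid = np.linspace(-span, span, 4001)
        sg = np.exp(grid)
        for i in np.flatnonzero(bad):
            hg = (-grid * grid * (0.5 * inv_w2)
                  - (C[i] - 2.0 * sg * A[i] + sg * sg * B) / (2.0 * sigma2))
            eta[i] = grid[np.argmax(hg)]
        s = np.exp(eta)
        hpp = -inv_w2 + (s * A - 2.0 * s * s * B) / sigma2
        hpp = np.minimum(hpp, -inv_w2 * 1e-8)  # curvature floor, degenerate cases
    return eta, hpp


def _mixed_neg2ll(u, C_i, g, sigma2, omega2, sum_log_w, n_quad):
    """-2 log marginal likelihood with adaptive Gauss-Hermite quadrature."""
    N, M = u.shape
    if omega2 == 0.0:
        return _fixed_neg2ll(u, g, sigma2, sum_log_w)
    A = u @ g
    B = float(g @ g)
    eta_hat, hpp = _conditional_modes(A, C_i, B, sigma2, omega2)
    tau = 1.0 / np.sqrt(-hpp)
    x, wq = _gh_nodes(n_quad)
    etaq = eta_hat[:, None] + np.sqrt(2.0) * tau[:, None] * x[None, :]
    c0 = (-0.5 * (_LOG2PI + np.log(omega2))
          - 0.5 * M * (_LOG2PI + np.log(sigma2)) - sum_log_w)
    with np.errstate(over="ignore"):
        s = np.exp(etaq)
        hq = (c0 - etaq * etaq / (2.0 * omega2)
              - (C_i[:, None] - 2.0 * s * A[:, None] + s * s * B)
              / (2.0 * sigma2))
    logL = (0.5 * np.log(2.0) + np.log(tau)
            + logsumexp(np.log(wq)[None, :] + (x * x)[None, :] + hq, axis=1))
    return float(-2.0 * np.sum(logL))


_GH_CACHE: dict = {}


def _gh_nodes(n_quad: int):
    if n_quad not in _GH_CACHE:
        _GH_CACHE[n_quad] = hermgauss(n_quad)
    return _GH_CACHE[n_quad]


def marginal_ofv(pop: PopulationData, alpha, sigma2: float, omega2: float,
                 n_quad: int = 21) -> float:
    """-2 log (marginal) likelihood of ``pop`` at given parameter values.

    ``alpha`` is the full length-M coefficient vector (zeros for inactive
    terms).  With ``omega2 = 0`` this reduces exactly to the fixed-effects
    Gaussian -2 log likelihood with per-observation variance
    ``sigma2 * w_j**2``; with ``omega2 > 0`` the one-dimensional integral
    over the random effect is computed per individual by adaptive
    Gauss-Hermite quadrature centred at the conditional mode.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2: must be positive")
    if omega2 < 0:
        raise ValueError("omega2: must be non-negative")
    if n_quad < 1:
        raise ValueError("n_quad: must be at least 1")
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (pop.grid.M,):
        raise ValueError("alpha: must have length M")
    t = pop.grid.times
    lam = 1.0 / t
    f = np.exp(-np.outer(t, lam)) @ alpha
    g = t * f
    u = pop.values * t[None, :]
    sum_log_w = float(np.sum(np.log(pop.weights)))
    if omega2 == 0.0:
        val = _fixed_neg2ll(u, g, float(sigma2), sum_log_w)
    else:
        C_i = np.sum(u * u, axis=1)
        val = _mixed_neg2ll(u, C_i, g, float(sigma2), float(omega2),
                            sum_log_w, int(n_quad))
    return float(val)
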
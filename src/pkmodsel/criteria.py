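"""Model-selection and predictive-performance criteria.

Selection criteria on the training fit:

* ``AIC  = OFV + 2 D``
* ``AICc = OFV + 2 D (1 + (D + 1) / (n - D - 1))`` with ``n = N * M``
  total observations,

both with D counting the variance parameters as ordinary parameters.
Predictive performance on an independent validation population:

* ``OFV_v`` — the (marginal) -2 log likelihood of the validation data at
  the fitted parameters, which on average approximates AIC;
* ``nu2`` — the mean squared weighted prediction error of the population
  prediction (random effects at zero), in three weighting conventions:
  the true weights ``w_j = 1/t_j``, the fitted model output, or the model
  output of a common reference (largest) model.

Criteria are routinely normalized by the number of observations; that is a
positive scaling and never changes which model attains the minimum.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .simulate import PopulationData

__all__ = [
    "Weighting",
    "CriteriaRecord",
    "EffectiveSampleSize",
    "aic",
    "aicc",
    "lrt_threshold",
    "prediction_error",
    "ofv_v",
    "bic_effective_n",
    "normalize",
]


class Weighting(enum.Enum):
    """Weight convention for the mean squared prediction error."""

    TRUE_WEIGHTS = "true"        # w_j = 1/t_j, the generative weights
    MODEL_OUTPUT = "model"       # weights equal the fitted model output
    LARGEST_MODEL = "largest"    # weights from a common reference model


def aic(ofv: float, D: int) -> float:
    """Akaike's criterion: adding a parameter must buy 2 points of OFV."""
    return ofv + 2.0 * D


def aicc(ofv: float, D: int, n: int) -> float:
    """Small-sample corrected AIC; undefined unless ``n > D + 1``."""
    if n <= D + 1:
        raise ValueError("n: AICc requires n > D + 1 observations")
    return ofv + 2.0 * D * (1.0 + (D + 1.0) / (n - D - 1.0))


def lrt_threshold(alpha: float = 0.05, df: int = 1) -> float:
    """Chi-square OFV drop required by a likelihood-ratio test at level
    ``alpha`` (3.84 for one parameter at 5%) — the stricter yardstick that
    hypothesis-test selection would apply instead of AIC's 2."""
    return float(stats.chi2.ppf(1.0 - alpha, df))


def _predictions(fit_or_curve, validation: PopulationData) -> np.ndarray:
    if hasattr(fit_or_curve, "predict"):
        return np.asarray(fit_or_curve.predict(validation.grid.times), dtype=float)
    pred = np.asarray(fit_or_curve, dtype=float)
    if pred.shape != (validation.grid.M,):
        raise ValueError("predictions: need one value per grid time")
    return pred


def prediction_error(fit_or_curve, validation: PopulationData,
                     weighting: Weighting = Weighting.TRUE_WEIGHTS,
                     ref_prediction=None) -> float:
    """Mean squared weighted prediction error nu2 against validation data.

    ``fit_or_curve`` is a fit results object (population prediction is used,
    i.e. random effects at zero) or a length-M curve.  With
    ``MODEL_OUTPUT`` weighting the fitted curve itself provides the weights
    and any zero model output is rejected (division hazard); with
    ``LARGEST_MODEL`` a common reference curve must be supplied so errors
    stay comparable across candidate models.
    """
    weighting = Weighting(weighting)
    yhat = _predictions(fit_or_curve, validation)
    z = validation.values
    if weighting is Weighting.TRUE_WEIGHTS:
        w = validation.weights
    elif weighting is Weighting.MODEL_OUTPUT:
        if np.any(yhat == 0.0):
            raise ValueError(
                "weighting: fitted model output is zero at some time; "
                "model-output weighting is undefined there")
        w = yhat
    else:
        if ref_prediction is None:
            raise ValueError("ref_prediction: required for LARGEST_MODEL weighting")
        w = np.asarray(ref_prediction, dtype=float)
        if w.shape != (validation.grid.M,):
            raise ValueError("ref_prediction: need one value per grid time")
        if np.any(w == 0.0):
            raise ValueError("ref_prediction: zero reference output at some time")
    r = (z - yhat[None, :]) / w[None, :]
    return float(np.mean(r * r))


def ofv_v(fit, validation: PopulationData) -> float:
    """Validation OFV: the -2 log (marginal) likelihood of the validation
    data at the fitted parameters.  WLS fits are evaluated with
    ``omega2 = 0``."""
    from .model import marginal_ofv  # deferred: criteria is imported by model

    omega2 = 0.0 if fit.omega2 is None else fit.omega2
    n_quad = fit.n_quad if fit.n_quad else 21
    return marginal_ofv(validation, fit.alpha, fit.sigma2, omega2, n_quad)


@dataclass(frozen=True)
class EffectiveSampleSize:
    """Effective sample size N' entering BIC's log(N') penalty.

    For this model family (one random effect, D parameters of which two are
    variances) ``n_prime = (D - 2) N M + 2 N``.  ``threshold`` is exp(2):
    when N' is near 7.4, log(N') equals AIC's factor 2 and BIC and AIC
    would penalize alike.
    """

    n_prime: float
    threshold: float = float(np.exp(2.0))


def bic_effective_n(D: int, N: int, M: int) -> EffectiveSampleSize:
    if D < 2:
        raise ValueError("D: effective sample size needs D >= 2")
    return EffectiveSampleSize(n_prime=float((D - 2) * N * M + 2 * N))


@dataclass(frozen=True)
class CriteriaRecord:
    """Criteria of one fitted candidate model in one run (one CSV row)."""

    model: str
    K: int
    D: int
    ofv: float
    aic: float
    aicc: float
    ofv_v: float
    nu2: float
    converged: bool
    normalized: bool = False

    def as_dict(self) -> dict:
        return {
            "model": self.model, "K": self.K, "D": self.D, "ofv": self.ofv,
            "aic": self.aic, "aicc": self.aicc, "ofv_v": self.ofv_v,
            "nu2": self.nu2, "converged": self.converged,
            "normalized": self.normalized,
        }


def normalize(record: CriteriaRecord, n_obs: int) -> CriteriaRecord:
    """Divide the likelihood-based criteria by the number of observations.

    ``nu2`` is already a per-observation mean and is left unchanged; the
    scaling is positive so the argmin over models is preserved.
    """
    if n_obs <= 0:
        raise ValueError("n_obs: must be positive")
    return replace(
        record,
        ofv=record.ofv / n_obs,
        aic=record.aic / n_obs,
        aicc=record.aicc / n_obs,
        ofv_v=record.ofv_v / n_obs,
        normalized=True,
    )
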
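"""Sampling-time grid, fixed rate-constant grid, and candidate model sets.

The study design places ``M`` sampling times log-symmetrically around t = 1
on ``[1/t_max, t_max]``,

    t_j = (j / (M + 1 - j))**gamma,   gamma = log(t_max) / log(M),

so that ``t_j * t_{M+1-j} = 1`` for every j.  One candidate rate constant is
attached to each sampling time, ``lambda_m = 1 / t_m``, and a candidate model
is a subset of those rates whose coefficients are estimated (the rest are
fixed to zero).  Two candidate sets are supported: the full enumeration of
all non-empty subsets, and the "evenly spaced" one-model-per-K subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "TimeGrid",
    "LambdaGrid",
    "ModelSpec",
    "make_time_grid",
    "make_lambda_grid",
    "evenly_spaced_model",
    "enumerate_models",
    "ENUMERATION_CAP",
]

#: Guard against combinatorial explosion in :func:`enumerate_models`.
ENUMERATION_CAP = 16


@dataclass(frozen=True)
class TimeGrid:
    """A log-symmetric grid of sampling times centred around t = 1.

    Attributes
    ----------
    M : int
        Number of sampling times.
    t_max : float
        Largest time; the smallest is ``1/t_max``.  Arbitrary time units.
    times : numpy.ndarray
        Strictly increasing times ``t_1 < ... < t_M`` with
        ``t_j * t_{M+1-j} = 1``.
    gamma : float
        Exponent of the grid formula, ``log(t_max)/log(M)``.
    """

    M: int
    t_max: float
    times: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.shape != (self.M,):
            raise ValueError("times: length must equal M")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times: must be strictly increasing")
        sym = times * times[::-1]
        if not np.allclose(sym, 1.0, rtol=1e-9, atol=0.0):
            raise ValueError("times: grid must satisfy t_j * t_{M+1-j} = 1")


@dataclass(frozen=True)
class LambdaGrid:
    """Fixed candidate rate constants, ``rates[m] = 1 / t_m`` (decreasing)."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if not np.all(np.diff(rates) < 0):
            raise ValueError("rates: must be strictly decreasing")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which of the M exponential terms are free.

    ``mask[m-1]`` is True when the coefficient of ``exp(-lambda_m t)`` is an
    estimated parameter; the model order K is the number of True entries.
    """

    mask: tuple

    def __post_init__(self) -> None:
        mask = tuple(bool(b) for b in self.mask)
        object.__setattr__(self, "mask", mask)
        if len(mask) < 1 or not any(mask):
            raise ValueError("mask: a model needs at least one active term")

    @property
    def M(self) -> int:
        return len(self.mask)

    @property
    def K(self) -> int:
        return sum(self.mask)

    @property
    def active(self) -> np.ndarray:
        """Zero-based indices of the active terms."""
        return np.flatnonzero(self.mask)

    @property
    def indices(self) -> tuple:
        """One-based indices of the active terms (tabular convention)."""
        return tuple(int(i) + 1 for i in self.active)

    def to_string(self) -> str:
        """'0'/'1' string, leftmost character is term m = 1."""
        return "".join("1" if b else "0" for b in self.mask)

    @classmethod
    def from_string(cls, s: str) -> "ModelSpec":
        if set(s) - {"0", "1"}:
            raise ValueError("mask string: characters must be '0' or '1'")
        return cls(tuple(c == "1" for c in s))

    @classmethod
    def from_indices(cls, M: int, indices) -> "ModelSpec":
        """Build from one-based active indices."""
        mask = [False] * M
        for i in indices:
            if not 1 <= i <= M:
                raise ValueError(f"index {i} outside 1..{M}")
            mask[i - 1] = True
        return cls(tuple(mask))


def make_time_grid(M: int, t_max: float) -> TimeGrid:
    """Construct the log-symmetric sampling grid.

    Parameters
    ----------
    M : int
        Number of sampling times, at least 2.
    t_max : float
        Largest sampling time, greater than 1.
    """
    if not isinstance(M, (int, np.integer)) or isinstance(M, bool):
        raise TypeError("M: must be an integer")
    if M < 2:
        raise ValueError("M: must be at least 2")
    t_max = float(t_max)
    if not np.isfinite(t_max) or t_max <= 1.0:
        raise ValueError("t_max: must be a finite real greater than 1")
    gamma = np.log(t_max) / np.log(M)
    j = np.arange(1, M + 1, dtype=float)
    times = (j / (M + 1 - j)) ** gamma
    return TimeGrid(M=int(M), t_max=t_max, times=times, gamma=float(gamma))


def make_lambda_grid(grid: TimeGrid) -> LambdaGrid:
    """Rate constants paired to the sampling times, ``lambda_m = 1/t_m``."""
    return LambdaGrid(rates=1.0 / grid.times)


def evenly_spaced_model(M: int, K: int) -> ModelSpec:
    """The evenly spaced K-of-M candidate model.

    For K >= 2 the active (one-based) indices are
    ``round(1 + (k-1)(M-1)/(K-1))`` for k = 1..K, with round-half-to-even
    tie-breaking; K = 1 takes the single middle index ``round((M+1)/2)``.
    Rounding is done in exact rational arithmetic.
    """
    if not 1 <= K <= M:
        raise ValueError(f"K: must be in 1..{M}, got {K}")
    if K == 1:
        idx = [round(Fraction(M + 1, 2))]
    else:
        idx = [round(Fraction(1) + Fraction((k - 1) * (M - 1), K - 1))
               for k in range(1, K + 1)]
    spec = ModelSpec.from_indices(M, idx)
    assert spec.K == K
    return spec


def enumerate_models(M: int, cap: int = ENUMERATION_CAP) -> list:
    """All 2**M - 1 non-empty candidate models, in binary-counting order.

    The model with code ``c`` (1 <= c < 2**M) activates term m exactly when
    bit ``m-1`` of ``c`` is set, so the ordering is deterministic and
    documented.  ``M`` above ``cap`` is rejected to guard against
    combinatorial explosion.
    """
    if M > cap:
        raise ValueError(f"M: enumeration of 2^{M}-1 models exceeds cap {cap}")
    if M < 1:
        raise ValueError("M: must be at least 1")
    out = []
    for code in range(1, 2 ** M):
        out.append(ModelSpec(tuple(bool(code >> m & 1) for m in range(M))))
    return out
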
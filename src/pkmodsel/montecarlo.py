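"""Monte Carlo orchestration of the model-selection study.

Each run simulates one training and one validation population, fits every
candidate model (WLS when ``omega2 = 0``, mixed-effects marginal maximum
likelihood otherwise), and records OFV, AIC, AICc, the validation OFV_v and
the prediction error nu2.  Across runs the experiment reports per-model
means with normal-approximation 95% confidence intervals (criteria
normalized by the number of observations), and the frequency with which
each model attains the minimal AICc.

Seed discipline: one master seed per experiment; run ``r`` derives its
training seed from spawn key ``(r, 0)`` and its validation seed from
``(r, 1)`` of ``numpy.random.SeedSequence(master_seed)``, so any single run
can be re-created in isolation and reruns are byte-identical.

Exclusions: a failed fit drops that (run, model) pair from the per-model
averages; a run with any failed fit is dropped from the selection-frequency
tally, which needs a complete comparison set.  The experiment aborts when
more than a configurable fraction of runs is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .design import (ModelSpec, TimeGrid, enumerate_models,
                     evenly_spaced_model, make_time_grid)
from .model import FitSettings, SumOfExponentials, _LOG2PI
from .simulate import ErrorModel, PopulationData, simulate_population
from . import criteria

__all__ = [
    "ExperimentConfig",
    "MCSummary",
    "ConfigError",
    "ExperimentError",
    "run_experiment",
    "selection_frequencies",
    "child_seed",
]


class ConfigError(ValueError):
    """Invalid experiment configuration (names the offending key)."""


class ExperimentError(RuntimeError):
    """Estimation failure cascade (exclusion guard tripped)."""


def child_seed(master_seed: int, run: int, stream: int) -> int:
    """Derived seed for (run, stream); stream 0 = training, 1 = validation."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(run, stream))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ExperimentConfig:
    """Resolved configuration of one Monte Carlo experiment.

    The defaults are the study conditions: M = 11 times on [0.01, 100],
    N = 5 individuals, residual variance 0.5, evenly spaced candidate set
    starting at K = 4, 1000 runs.
    """

    M: int = 11
    N: int = 5
    t_max: float = 100.0
    sigma2: float = 0.5
    omega2: float = 0.0
    n_runs: int = 1000
    master_seed: int = 0
    model_set: str = "table1"         # "table1" | "full"
    K_min: int = 4
    K_max: int | None = None          # None -> M
    error_model: str = "additive"     # "additive" | "proportional"
    n_quad: int = 21
    omega2_start: float = 0.1
    max_restarts: int = 2
    max_exclusion_fraction: float = 0.5
    n_jobs: int = 1

    def __post_init__(self):
        if self.K_max is None:
            self.K_max = self.M
        if self.n_runs < 1:
            raise ConfigError("n_runs: must be at least 1")
        if not 1 <= self.K_min <= self.K_max <= self.M:
            raise ConfigError("K_min/K_max: need 1 <= K_min <= K_max <= M")
        if self.model_set not in ("table1", "full"):
            raise ConfigError("model_set: must be 'table1' or 'full'")
        if self.error_model not in ("additive", "proportional"):
            raise ConfigError("error_model: must be 'additive' or 'proportional'")
        if self.sigma2 < 0 or self.omega2 < 0:
            raise ConfigError("sigma2/omega2: variances must be non-negative")
        if not 0 < self.max_exclusion_fraction <= 1:
            raise ConfigError("max_exclusion_fraction: must be in (0, 1]")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ExperimentConfig":
        known = {f.name: f for f in fields(cls)}
        clean = {}
        for key, value in mapping.items():
            if key not in known:
                raise ConfigError(f"unknown configuration key: {key!r}")
            clean[key] = value
        try:
            return cls(**clean)
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        if not isinstance(mapping, dict):
            raise ConfigError("config file: expected a flat key: value mapping")
        return cls.from_mapping(mapping)

    def grid(self) -> TimeGrid:
        return make_time_grid(self.M, self.t_max)

    def models(self) -> list:
        if self.model_set == "full":
            return [m for m in enumerate_models(self.M)
                    if self.K_min <= m.K <= self.K_max]
        return [evenly_spaced_model(self.M, K)
                for K in range(self.K_min, self.K_max + 1)]

    def fit_settings(self) -> FitSettings:
        return FitSettings(n_quad=self.n_quad, omega2_start=self.omega2_start,
                           max_restarts=self.max_restarts)

    def resolved(self) -> dict:
        return asdict(self)


@dataclass
class MCSummary:
    """Aggregated experiment output.

    ``summary`` has one row per candidate model (means, 95% CIs, selection
    frequency); ``runs`` has one row per (run, model) with the raw
    criteria.  Likelihood criteria in ``summary`` are normalized by N * M.
    """

    summary: pd.DataFrame
    runs: pd.DataFrame
    n_excluded_fits: int
    n_excluded_runs: int
    config: ExperimentConfig

    def argmin_K(self, column: str) -> int:
        """K of the model minimizing the mean of ``column`` (ties -> smaller K)."""
        s = self.summary.sort_values(["K", "model"], kind="stable")
        return int(s.loc[s[f"mean_{column}"].idxmin(), "K"])


# ------------------------------------------------------------------ fitting


class _BatchWLS:
    """Shared-design WLS solver for many models on many runs.

    All individuals share the design, so the stacked normal equations are
    ``N G a = Xw' usum`` with the per-mask Gram ``G`` precomputed and
    Cholesky-factored once; each run then costs one small solve per model.
    """

    def __init__(self, grid: TimeGrid, models, N: int):
        t = grid.times
        self.Xw_full = np.exp(-np.outer(t, 1.0 / t)) * t[:, None]
        self.N = N
        self.n = N * grid.M
        self.sum_log_w = float(-np.sum(np.log(t)))
        self.models = models
        self._factors = []
        for spec in models:
            Xw = self.Xw_full[:, spec.active]
            gram = self.N * (Xw.T @ Xw)
            try:
                self._factors.append((Xw, cho_factor(gram)))
            except np.linalg.LinAlgError:
                self._factors.append((Xw, None))

    def run(self, train: PopulationData, valid: PopulationData):
        t = train.grid.times
        u = train.values * t[None, :]
        v = valid.values * t[None, :]
        usum = u.sum(axis=0)
        vsum = v.sum(axis=0)
        Cu = float(np.sum(u * u))
        Cv = float(np.sum(v * v))
        n, N = self.n, self.N
        const = n * _LOG2PI + 2 * N * self.sum_log_w
        out = []
        for spec, (Xw, factor) in zip(self.models, self._factors):
            if factor is None:
                out.append(criteria.CriteriaRecord(
                    model=spec.to_string(), K=spec.K, D=spec.K + 1,
                    ofv=np.nan, aic=np.nan, aicc=np.nan, ofv_v=np.nan,
                    nu2=np.nan, converged=False))
                continue
            b = Xw.T @ usum
            a = cho_solve(factor, b)
            rss = max(Cu - float(a @ b), 0.0)
            sigma2 = rss / n
            g = Xw @ a
            rss_v = max(Cv - 2.0 * float(g @ vsum) + N * float(g @ g), 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ofv = const + n * np.log(sigma2) + n
                ofv_v = const + n * np.log(sigma2) + rss_v / sigma2
            D = spec.K + 1
            out.append(criteria.CriteriaRecord(
                model=spec.to_string(), K=spec.K, D=D, ofv=float(ofv),
                aic=criteria.aic(ofv, D), aicc=criteria.aicc(ofv, D, n),
                ofv_v=float(ofv_v), nu2=rss_v / n,
                converged=bool(np.isfinite(ofv))))
        return out


def _mixed_run(train, valid, models, settings):
    out = []
    for spec in models:
        fit = SumOfExponentials(train, spec).fit("mixed", settings)
        if fit.converged:
            ofvv = fit.ofv_v(valid)
            nu2 = fit.prediction_error(valid)
            ok = np.isfinite(fit.ofv) and np.isfinite(ofvv)
        else:
            ofvv, nu2, ok = np.nan, np.nan, False
        out.append(criteria.CriteriaRecord(
            model=spec.to_string(), K=spec.K, D=fit.D,
            ofv=fit.ofv if ok else np.nan,
            aic=fit.aic if ok else np.nan,
            aicc=fit.aicc if ok else np.nan,
            ofv_v=ofvv, nu2=nu2, converged=bool(ok)))
    return out


def _one_run(r, config, grid, models, batch, settings, error_model):
    train = simulate_population(grid, config.N, config.sigma2, config.omega2,
                                error_model, seed=child_seed(config.master_seed, r, 0))
    valid = simulate_population(grid, config.N, config.sigma2, config.omega2,
                                error_model, seed=child_seed(config.master_seed, r, 1))
    if batch is not None:
        return batch.run(train, valid)
    return _mixed_run(train, valid, models, settings)


# ---------------------------------------------------------------- experiment


def run_experiment(config: ExperimentConfig) -> MCSummary:
    """Run the full Monte Carlo experiment described by ``config``.

    Fully reproducible from the configuration (results are invariant to
    execution order; the reduction is ordered by run index).
    """
    grid = config.grid()
    models = config.models()
    error_model = ErrorModel(config.error_model)
    settings = config.fit_settings()
    batch = _BatchWLS(grid, models, config.N) if config.omega2 == 0 else None

    args = (config, grid, models, batch, settings, error_model)
    if config.n_jobs != 1:
        from joblib import Parallel, delayed

        per_run = Parallel(n_jobs=config.n_jobs)(
            delayed(_one_run)(r, *args) for r in range(config.n_runs))
    else:
        per_run = [_one_run(r, *args) for r in range(config.n_runs)]

    rows = []
    for r, recs in enumerate(per_run):
        for rec in recs:
            rows.append({"run": r, **rec.as_dict()})
    runs = pd.DataFrame(rows).drop(columns=["normalized"])

    n_excluded_fits = int((~runs["converged"]).sum())
    complete = runs.groupby("run")["converged"].all()
    n_excluded_runs = int((~complete).sum())
    if n_excluded_runs > config.max_exclusion_fraction * config.n_runs:
        raise ExperimentError(
            f"{n_excluded_runs} of {config.n_runs} runs excluded for failed "
            f"fits (> {config.max_exclusion_fraction:.0%} guard)")

    summary = _summarize(runs, config.N * config.M, complete)
    return MCSummary(summary=summary, runs=runs,
                     n_excluded_fits=n_excluded_fits,
                     n_excluded_runs=n_excluded_runs, config=config)


def _summarize(runs: pd.DataFrame, n_obs: int, complete=None) -> pd.DataFrame:
    ok = runs[runs["converged"]]
    norm = {"aic": n_obs, "aicc": n_obs, "ofv_v": n_obs, "nu2": 1}
    rows = []
    for (model, K, D), grp in ok.groupby(["model", "K", "D"], sort=False):
        row = {"model": model, "K": int(K), "D": int(D), "n_fits": len(grp)}
        for col, div in norm.items():
            vals = grp[col].to_numpy() / div
            m = float(np.mean(vals))
            half = float(1.959963984540054 * np.std(vals, ddof=1)
                         / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            row[f"mean_{col}"] = m
            row[f"ci95_lo_{col}"] = m - half
            row[f"ci95_hi_{col}"] = m + half
        rows.append(row)
    summary = pd.DataFrame(rows).sort_values(["K", "model"], kind="stable")
    summary = summary.reset_index(drop=True)
    freqs = selection_frequencies(runs, complete=complete)
    summary = summary.merge(freqs, on="model", how="left")
    summary["selection_frequency"] = summary["selection_frequency"].fillna(0.0)
    return summary


def selection_frequencies(runs: pd.DataFrame, criterion: str = "aicc",
                          complete=None) -> pd.DataFrame:
    """Fraction of runs in which each model attains the minimal criterion.

    Only runs where every candidate fit converged enter the tally (the
    comparison needs the full set).  Ties break toward smaller K, then
    lexicographic model string.
    """
    if complete is None:
        complete = runs.groupby("run")["converged"].all()
    good_runs = complete[complete].index
    sub = runs[runs["run"].isin(good_runs)]
    if len(sub) == 0:
        raise ValueError("runs: no complete runs to tally frequencies over")
    sub = sub.sort_values(["run", "K", "model"], kind="stable")
    winners = sub.loc[sub.groupby("run")[criterion].idxmin(), "model"]
    freq = winners.value_counts(normalize=True)
    return freq.rename("selection_frequency").rename_axis("model").reset_index()
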
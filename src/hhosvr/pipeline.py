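"""Forecasting workflow: normalisation, lag embedding, CV-MAPE tuning, reports.

The workflow mirrors a standard metaheuristic-tuned SVR forecasting setup:

1. min-max normalise the daily concentration series onto [0, 1];
2. embed it as a supervised set of autoregressive lag windows;
3. let an optimizer (HHO by default) minimise the k-fold cross-validated
   MAPE of an epsilon-SVR over the (C, sigma) box [1, 1000]^2, where MAPE
   is always computed on the original concentration scale after inverse
   normalisation;
4. repeat the tuning run several times with distinct seeds and summarise
   best/worst/average/SD plus the winning hyperparameters;
5. optionally race several optimizers on identical data, folds and seeds
   and rank them with the Friedman test.

Optimizers are pluggable: any callable
``optimize(objective, space, budget, seed) -> OptimizationResult`` with
``budget = (n_agents, max_iter)`` can be registered and benchmarked.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import evalstats, svr
from .hho import OptimizationResult, SearchSpace, hho_optimizer

__all__ = [
    "NormalizationParams",
    "LagConfig",
    "SupervisedSet",
    "TuningConfig",
    "TrialResult",
    "RunReport",
    "minmax_normalize",
    "minmax_inverse",
    "lag_embed",
    "kfold_plan",
    "cv_mape_objective",
    "run_single_trial",
    "run_experiment",
    "run_comparison",
    "supervised_from_xy",
    "register_optimizer",
    "random_search_optimizer",
    "OPTIMIZERS",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Min and max of the series used for the affine map onto [0, 1]."""

    min_val: float
    max_val: float

    def __post_init__(self) -> None:
        if not self.max_val > self.min_val:
            raise ValueError("max_val must exceed min_val (constant series has zero range)")


@dataclass(frozen=True)
class LagConfig:
    """Autoregressive embedding: ``n_lags`` past values predict ``horizon`` ahead."""

    n_lags: int = 7
    horizon: int = 1

    def __post_init__(self) -> None:
        if self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class SupervisedSet:
    """Lagged feature matrix with aligned targets (both on the normalised scale)."""

    features: np.ndarray
    targets: np.ndarray
    index: np.ndarray | None = None  # target timestamps, when known

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.targets.size:
            raise ValueError("features and targets disagree on sample count")

    @property
    def n_samples(self) -> int:
        return self.targets.size


@dataclass(frozen=True)
class TuningConfig:
    """Experiment protocol: optimizer budget, CV folds, runs and SVR settings.

    Defaults follow the benchmarking protocol used throughout this package:
    30 agents, 50 iterations, 10 independent runs, 10-fold CV, both decision
    variables bounded to [1, 1000], fixed epsilon tube of 0.1 on normalised
    targets.  ``svr_tol``/``svr_kkt_tol`` trade objective precision for
    speed inside the tuning loop and are intentionally looser than the
    standalone training defaults.
    """

    optimizer: str = "hho"
    n_agents: int = 30
    max_iter: int = 50
    runs: int = 10
    bounds: tuple[float, float] = (1.0, 1000.0)
    k_folds: int = 10
    master_seed: int = 0
    epsilon: float = 0.1
    svr_tol: float = 1e-4
    svr_kkt_tol: float = 1.0
    blocked_folds: bool = False

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be well ordered")

    def search_space(self) -> SearchSpace:
        lo, hi = self.bounds
        return SearchSpace([lo, lo], [hi, hi])


@dataclass
class TrialResult:
    best_C: float
    best_sigma: float
    best_mape: float
    convergence: np.ndarray
    n_evals: int
    elapsed: float
    seed: int


@dataclass
class RunReport:
    """Per-experiment record mirroring one row of the published summary tables."""

    best: float
    worst: float
    average: float
    sd: float
    cpu_time: float
    best_C: float
    best_sigma: float
    per_run: list[float]
    convergence: list[list[float]]
    seeds: list[int]

    def as_dict(self) -> dict:
        return {
            "best": self.best,
            "worst": self.worst,
            "average": self.average,
            "sd": self.sd,
            "cpu_time": self.cpu_time,
            "best_C": self.best_C,
            "best_sigma": self.best_sigma,
            "per_run": list(self.per_run),
            "convergence": [list(c) for c in self.convergence],
            "seeds": list(self.seeds),
        }


def minmax_normalize(series) -> tuple[np.ndarray, NormalizationParams]:
    """Map a series affinely onto [0, 1]; the minimum goes to 0, the maximum to 1."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values")
    params = NormalizationParams(min_val=float(x.min()), max_val=float(x.max()))
    return (x - params.min_val) / (params.max_val - params.min_val), params


def minmax_inverse(normalized, params: NormalizationParams) -> np.ndarray:
    """Undo :func:`minmax_normalize`: ``x = xn * (max - min) + min``."""
    xn = np.asarray(normalized, dtype=float)
    return xn * (params.max_val - params.min_val) + params.min_val


def lag_embed(series, cfg: LagConfig, index=None) -> SupervisedSet:
    """Sliding-window embedding of a (normalised) series.

    Row t collects ``(x_t, ..., x_{t+n_lags-1})`` and its target is
    ``x_{t+n_lags+horizon-1}``, giving ``n - n_lags - horizon + 1`` rows.
    """
    x = np.asarray(series, dtype=float).ravel()
    n_rows = x.size - cfg.n_lags - cfg.horizon + 1
    if n_rows < 1:
        raise ValueError(
            f"series of length {x.size} too short for {cfg.n_lags} lags, horizon {cfg.horizon}"
        )
    features = np.lib.stride_tricks.sliding_window_view(x, cfg.n_lags)[:n_rows].copy()
    targets = x[cfg.n_lags + cfg.horizon - 1 :].copy()
    target_index = None
    if index is not None:
        target_index = np.asarray(index)[cfg.n_lags + cfg.horizon - 1 :]
    return SupervisedSet(features=features, targets=targets, index=target_index)


def kfold_plan(
    n: int, k: int, rng: np.random.Generator, blocked: bool = False
) -> list[np.ndarray]:
    """Partition ``0..n-1`` into k folds whose sizes differ by at most one.

    Shuffled uniformly by default; ``blocked=True`` keeps contiguous
    time-ordered blocks instead (for leakage-averse evaluation of ordered
    series).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    indices = np.arange(n) if blocked else rng.permutation(n)
    return [fold.copy() for fold in np.array_split(indices, k)]


def _fold_plan_for(data: SupervisedSet, cfg: TuningConfig) -> list[np.ndarray]:
    rng = np.random.default_rng(cfg.master_seed)
    return kfold_plan(data.n_samples, cfg.k_folds, rng, blocked=cfg.blocked_folds)


def cv_mape_objective(
    position,
    data: SupervisedSet,
    params: NormalizationParams,
    cfg: TuningConfig,
    folds: Sequence[np.ndarray] | None = None,
) -> float:
    """k-fold cross-validated MAPE of an SVR at ``(C, sigma) = position``.

    Each fold is held out once; the model is fitted on the remaining folds,
    predictions and targets are mapped back to the original concentration
    scale, and the fold MAPEs are averaged.  The fold plan is derived
    deterministically from ``cfg.master_seed`` unless supplied, so repeated
    evaluations at the same position agree exactly.
    """
    position = np.asarray(position, dtype=float).ravel()
    if position.size != 2:
        raise ValueError("position must be the 2-vector (C, sigma)")
    hyper = svr.SVRHyperparams(C=float(position[0]), sigma=float(position[1]), epsilon=cfg.epsilon)
    if folds is None:
        folds = _fold_plan_for(data, cfg)
    actual_all = minmax_inverse(data.targets, params)
    if np.any(actual_all == 0.0):
        raise ValueError("a target is zero on the original scale; MAPE is undefined")

    fold_mapes = []
    for fold_idx, test_idx in enumerate(folds):
        mask = np.ones(data.n_samples, dtype=bool)
        mask[test_idx] = False
        try:
            model = svr.train_svr(
                data.features[mask],
                data.targets[mask],
                hyper,
                tol=cfg.svr_tol,
                kkt_tol=cfg.svr_kkt_tol,
            )
        except svr.SVRConvergenceError as exc:
            raise svr.SVRConvergenceError(
                exc.residual, f"SVR failed on fold {fold_idx}: {exc}"
            ) from exc
        pred = minmax_inverse(svr.predict(model, data.features[test_idx]), params)
        fold_mapes.append(evalstats.mape(actual_all[test_idx], pred))
    return float(np.mean(fold_mapes))


def random_search_optimizer(
    objective, space: SearchSpace, budget: tuple[int, int], seed: int
) -> OptimizationResult:
    """Uniform random search reference baseline under the optimizer contract.

    Spends the same ``n_agents * max_iter`` evaluation budget as a
    population optimizer and records the best-so-far value once per
    ``n_agents`` evaluations, so convergence curves are comparable.
    """
    start = time.perf_counter()
    n_agents, max_iter = budget
    rng = np.random.default_rng(seed)
    best_x, best_f = None, np.inf
    convergence = np.empty(max_iter)
    n_evals = 0
    for t in range(max_iter):
        for x in space.sample(rng, n_agents):
            f = float(objective(x))
            n_evals += 1
            if f < best_f:
                best_f, best_x = f, x.copy()
        convergence[t] = best_f
    return OptimizationResult(
        best_position=best_x,
        best_fitness=best_f,
        convergence=convergence,
        n_evals=n_evals,
        elapsed=time.perf_counter() - start,
    )


OPTIMIZERS: dict[str, Callable] = {
    "hho": hho_optimizer,
    "random": random_search_optimizer,
}


def register_optimizer(name: str, optimize: Callable) -> None:
    """Register a third-party metaheuristic under the plug-in contract."""
    OPTIMIZERS[name] = optimize


def _trial_seeds(master_seed: int, runs: int) -> list[int]:
    """Independent per-run seeds from a splittable generator (below 2^31)."""
    children = np.random.SeedSequence(master_seed).spawn(runs)
    return [int(c.generate_state(1, np.uint32)[0] & 0x7FFFFFFF) for c in children]


def run_single_trial(
    data: SupervisedSet,
    params: NormalizationParams,
    cfg: TuningConfig,
    seed: int,
) -> TrialResult:
    """One tuning run: optimize the CV-MAPE objective over the (C, sigma) box."""
    try:
        optimize = OPTIMIZERS[cfg.optimizer]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {cfg.optimizer!r}; registered: {sorted(OPTIMIZERS)}"
        ) from None
    folds = _fold_plan_for(data, cfg)

    def objective(position):
        return cv_mape_objective(position, data, params, cfg, folds)

    result = optimize(objective, cfg.search_space(), (cfg.n_agents, cfg.max_iter), seed)
    return TrialResult(
        best_C=float(result.best_position[0]),
        best_sigma=float(result.best_position[1]),
        best_mape=float(result.best_fitness),
        convergence=np.asarray(result.convergence, dtype=float),
        n_evals=int(result.n_evals),
        elapsed=float(result.elapsed),
        seed=seed,
    )


def run_experiment(
    data: SupervisedSet, params: NormalizationParams, cfg: TuningConfig
) -> RunReport:
    """Repeat the tuning run ``cfg.runs`` times and summarise the best MAPEs."""
    start = time.perf_counter()
    seeds = _trial_seeds(cfg.master_seed, cfg.runs)
    trials = [run_single_trial(data, params, cfg, seed) for seed in seeds]
    per_run = [t.best_mape for t in trials]
    stats = evalstats.summarize_runs(per_run)
    winner = trials[int(np.argmin(per_run))]
    return RunReport(
        best=stats.best,
        worst=stats.worst,
        average=stats.average,
        sd=stats.sd,
        cpu_time=time.perf_counter() - start,
        best_C=winner.best_C,
        best_sigma=winner.best_sigma,
        per_run=per_run,
        convergence=[t.convergence.tolist() for t in trials],
        seeds=seeds,
    )


def run_comparison(
    data: SupervisedSet,
    params: NormalizationParams,
    cfg: TuningConfig,
    optimizers: Sequence[str],
) -> tuple[pd.DataFrame, evalstats.RankResult]:
    """Race several optimizers on identical data, folds, budget and seeds.

    Returns the runs x optimizers matrix of per-run best MAPEs and its
    Friedman ranking.
    """
    if len(optimizers) < 2:
        raise ValueError("need at least 2 optimizers to compare")
    unknown = [name for name in optimizers if name not in OPTIMIZERS]
    if unknown:
        raise ValueError(f"unknown optimizers {unknown}; registered: {sorted(OPTIMIZERS)}")
    if cfg.runs < 2:
        raise ValueError("need at least 2 runs for a Friedman comparison")
    columns = {}
    for name in optimizers:
        sub_cfg = dataclass_replace(cfg, optimizer=name)
        report = run_experiment(data, params, sub_cfg)
        columns[name] = report.per_run
    matrix = pd.DataFrame(columns)
    return matrix, evalstats.friedman_test(matrix)


def supervised_from_xy(X, y) -> tuple[SupervisedSet, NormalizationParams]:
    """Wrap a generic regression set: normalise targets, keep features as-is."""
    X = np.asarray(X, dtype=float)
    targets, params = minmax_normalize(y)
    return SupervisedSet(features=X, targets=targets), params


def dataclass_replace(cfg: TuningConfig, **changes) -> TuningConfig:
    import dataclasses

    return dataclasses.replace(cfg, **changes)
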
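"""Download-free synthetic data: PM2.5-like daily series, SVR-recoverable
regression testbeds, and analytic benchmark objectives.

The daily series generator emulates the statistical profile of county-level
Downscaler PM2.5 concentrations: strictly positive, right-skewed (skewness
around 1.3-1.5), mean around 11-13 ug/m3, SD around 4.6-6.2, mild day-to-day
autocorrelation and an annual seasonal cycle.  It is an exponentiated
Gaussian AR(1) with a sinusoidal seasonal term, affinely calibrated so the
sample mean and SD hit their targets exactly; skewness is emergent from the
log-normal marginal and only approximately matches its target.  It stands in
for the real data in tests and demos; it is not a model of the atmospheric
process.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .data_io import CdcRecord

__all__ = [
    "SeriesSpec",
    "Benchmark",
    "gen_pm25_series",
    "gen_cdc_records",
    "gen_svr_recoverable",
    "benchmark_objectives",
]


@dataclass(frozen=True)
class SeriesSpec:
    """Targets for the daily-series generator.

    Defaults reproduce the marginal profile of the county 1001 series
    (mean 12.12 ug/m3, SD 5.07, skewness 1.38) with lag-1 autocorrelation
    0.6 and a 2 ug/m3 annual cycle.
    """

    n: int = 3500
    target_mean: float = 12.124
    target_sd: float = 5.067
    target_skewness: float = 1.376
    ar_coef: float = 0.6
    seasonal_amp: float = 2.0
    period: int = 365
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.target_mean <= 0 or self.target_sd <= 0:
            raise ValueError("target mean and SD must be positive")
        if not 0.0 <= self.ar_coef <= 0.99:
            raise ValueError("ar_coef must lie in [0, 0.99]")
        if self.seasonal_amp < 0 or self.period < 2:
            raise ValueError("invalid seasonal settings")
        if self.target_skewness <= 0:
            raise ValueError(
                "this exponentiated-Gaussian family only produces positive skewness"
            )


def _lognormal_shape_for_skewness(skew: float) -> float:
    """Shape s with exp(s*Z) skewness equal to ``skew`` (Z standard normal)."""

    def f(s: float) -> float:
        w = math.exp(s * s)
        return (w + 2.0) * math.sqrt(w - 1.0) - skew

    return brentq(f, 1e-6, 2.0)


def gen_pm25_series(spec: SeriesSpec) -> np.ndarray:
    """Strictly positive daily series matching the spec's mean/SD exactly.

    Construction: a unit-variance Gaussian AR(1) is exponentiated with the
    shape that gives the target log-normal skewness, a seasonal sinusoid is
    added, and the result is affinely rescaled so the sample mean and
    sample SD (n-1 denominator) equal the targets.  Raises if the
    calibrated series is not strictly positive (infeasible spec, e.g. a
    seasonal amplitude larger than the target SD allows).
    """
    rng = np.random.default_rng(spec.seed)
    s = _lognormal_shape_for_skewness(spec.target_skewness)

    z = np.empty(spec.n)
    z[0] = rng.standard_normal()
    innov_sd = math.sqrt(1.0 - spec.ar_coef**2)
    eps = rng.standard_normal(spec.n - 1)
    for t in range(1, spec.n):
        z[t] = spec.ar_coef * z[t - 1] + innov_sd * eps[t - 1]

    core = np.exp(s * z)
    t_axis = np.arange(spec.n)
    seasonal = spec.seasonal_amp * np.sin(2.0 * math.pi * t_axis / spec.period)

    var_c = float(np.var(core, ddof=1))
    var_m = float(np.var(seasonal, ddof=1))
    cov_cm = float(np.cov(core, seasonal, ddof=1)[0, 1])
    disc = cov_cm**2 - var_c * (var_m - spec.target_sd**2)
    if disc < 0 or var_c == 0:
        raise ValueError("infeasible spec: seasonal amplitude exceeds the target SD")
    scale = (-cov_cm + math.sqrt(disc)) / var_c
    if scale <= 0:
        raise ValueError("infeasible spec: no positive scaling calibrates the SD")
    raw = scale * core + seasonal
    series = raw + (spec.target_mean - float(np.mean(raw)))
    if series.min() <= 0.0:
        raise ValueError(
            "infeasible spec: calibrated series is not strictly positive "
            f"(min {series.min():.3f})"
        )
    return series


def gen_cdc_records(
    spec: SeriesSpec,
    statefips: int = 1,
    countyfips: int = 9001,
    start: dt.date = dt.date(2001, 1, 1),
) -> list[CdcRecord]:
    """Wrap a synthetic series in the county-day CSV schema (one county).

    The generated series is used as the daily maximum; the other three
    concentration columns are scaled-down proxies so every column is
    populated and positive.
    """
    series = gen_pm25_series(spec)
    records = []
    for offset, value in enumerate(series):
        day = start + dt.timedelta(days=offset)
        records.append(
            CdcRecord(
                statefips=statefips,
                countyfips=countyfips,
                year=day.year,
                date=day,
                pm25_max_pred=float(value),
                pm25_med_pred=float(value) * 0.82,
                pm25_mean_pred=float(value) * 0.85,
                pm25_pop_pred=float(value) * 0.87,
            )
        )
    return records


def gen_svr_recoverable(
    n: int, noise_sd: float, seed: int
) -> tuple[np.ndarray, np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Smooth two-bump regression surface with additive Gaussian noise.

    Features are uniform on the [0, 100] square; the noiseless target is a
    positive sum of two Gaussian bumps (length scales 20 and 25) over a
    baseline of 1, so percentage errors are always defined and the surface
    is RBF-representable with a kernel width well inside the [1, 1000]
    hyperparameter box used for tuning.  The noiseless oracle function is
    returned for error-floor comparisons.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 100.0, size=(n, 2))

    c1 = np.array([30.0, 30.0])
    c2 = np.array([75.0, 70.0])

    def oracle(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d1 = np.sum((pts - c1) ** 2, axis=1)
        d2 = np.sum((pts - c2) ** 2, axis=1)
        return 1.0 + np.exp(-d1 / (2 * 20.0**2)) + 0.8 * np.exp(-d2 / (2 * 25.0**2))

    y = oracle(X) + noise_sd * rng.standard_normal(n)
    return X, y, oracle


@dataclass(frozen=True)
class Benchmark:
    """Analytic objective with a known minimiser (minimum value 0)."""

    func: Callable[[np.ndarray], float]
    minimizer: np.ndarray
    minimum: float
    lower: float
    upper: float


def benchmark_objectives() -> dict[str, Benchmark]:
    """Sphere, shifted quadratic and 2-D Rosenbrock test objectives."""
    shift = np.array([2.5, -1.5])

    return {
        "sphere": Benchmark(
            func=lambda x: float(np.sum(np.square(x))),
            minimizer=np.zeros(2),
            minimum=0.0,
            lower=-10.0,
            upper=10.0,
        ),
        "shifted_quadratic": Benchmark(
            func=lambda x: float(np.sum(np.square(np.asarray(x) - shift))),
            minimizer=shift.copy(),
            minimum=0.0,
            lower=-10.0,
            upper=10.0,
        ),
        "rosenbrock": Benchmark(
            func=lambda x: float(
                100.0 * (x[1] - x[0] ** 2) ** 2 + (1.0 - x[0]) ** 2
            ),
            minimizer=np.ones(2),
            minimum=0.0,
            lower=-5.0,
            upper=5.0,
        ),
    }
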
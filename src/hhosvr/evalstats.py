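"""Forecast-accuracy metrics and the Friedman rank test for algorithm comparison.

MAPE is the headline metric and tuning objective; multi-run experiments are
summarised by best/worst/average/SD; competing optimizers are compared with
the Friedman two-way rank ANOVA (runs are blocks, algorithms treatments).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

__all__ = [
    "MetricSet",
    "RankResult",
    "mape",
    "summarize_runs",
    "friedman_test",
    "rank_algorithms",
]


@dataclass(frozen=True)
class MetricSet:
    """Best/worst/average/SD summary of M repeated runs of one method."""

    best: float
    worst: float
    average: float
    sd: float
    n_runs: int


@dataclass(frozen=True)
class RankResult:
    """Friedman test outcome over an n-blocks x k-treatments matrix.

    ``mean_ranks`` are within-block average ranks (lower = better);
    ``ordinal`` maps each treatment to its 1..k place by ascending mean
    rank, earlier column winning ties.
    """

    names: tuple[str, ...]
    mean_ranks: np.ndarray
    chi_square: float
    p_value: float
    ordinal: np.ndarray
    n_blocks: int
    tie_corrected: bool

    def as_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mean_ranks": self.mean_ranks.tolist(),
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "ordinal": self.ordinal.tolist(),
            "n_blocks": self.n_blocks,
            "tie_corrected": self.tie_corrected,
        }


def mape(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute percentage error ``mean(|(a_i - p_i) / a_i|)``.

    Reported as a fraction (0.1 means 10%).  Any zero actual value makes
    the ratio undefined and is rejected.
    """
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size:
        raise ValueError("actual and predicted lengths differ")
    if a.size == 0:
        raise ValueError("empty input")
    if np.any(a == 0.0):
        raise ValueError("actual values must be non-zero for a percentage error")
    return float(np.mean(np.abs((a - p) / a)))


def summarize_runs(values: Sequence[float]) -> MetricSet:
    """Min / max / mean / sample SD (M-1 denominator) of per-run objectives.

    A single run has no dispersion estimate; its SD is reported as 0 by
    convention.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return MetricSet(
        best=float(v.min()),
        worst=float(v.max()),
        average=float(v.mean()),
        sd=sd,
        n_runs=int(v.size),
    )


def friedman_test(
    matrix: np.ndarray | pd.DataFrame,
    names: Sequence[str] | None = None,
    tie_correction: bool = True,
) -> RankResult:
    """Friedman chi-square test on an n x k matrix (rows = blocks/runs).

    Values are ranked 1..k ascending within each block (lower value =
    better rank), ties receiving average ranks.  The statistic is

        chi2 = [12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)] / Ctie

    with ``R_j`` the column rank sums and, when ``tie_correction`` is on,
    ``Ctie = 1 - sum(t^3 - t) / (n (k^3 - k))`` summed over tie groups —
    the convention of the common statistical packages.  The p-value is the
    upper chi-square tail with k - 1 degrees of freedom.
    """
    if isinstance(matrix, pd.DataFrame):
        if names is None:
            names = [str(c) for c in matrix.columns]
        matrix = matrix.to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be two-dimensional")
    n, k = matrix.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    if names is None:
        names = [f"col{j}" for j in range(k)]
    if len(names) != k:
        raise ValueError("names length does not match number of treatments")

    ranks = np.apply_along_axis(rankdata, 1, matrix)
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    if tie_correction:
        tie_term = 0.0
        for row in matrix:
            _, counts = np.unique(row, return_counts=True)
            tie_term += float(np.sum(counts**3 - counts))
        correction = 1.0 - tie_term / (n * (k**3 - k))
        if correction <= 0.0:  # every block fully tied: no evidence at all
            stat = 0.0
        else:
            stat = stat / correction
    stat = max(stat, 0.0)
    p_value = float(chi2.sf(stat, k - 1))

    mean_ranks = rank_sums / n
    order = np.argsort(mean_ranks, kind="stable")  # earlier column wins ties
    ordinal = np.empty(k, dtype=int)
    ordinal[order] = np.arange(1, k + 1)
    return RankResult(
        names=tuple(names),
        mean_ranks=mean_ranks,
        chi_square=float(stat),
        p_value=p_value,
        ordinal=ordinal,
        n_blocks=n,
        tie_corrected=bool(tie_correction),
    )


def rank_algorithms(rank_result: RankResult) -> dict[str, int]:
    """Ordinal placement (1 = smallest mean rank) keyed by algorithm name."""
    return {name: int(o) for name, o in zip(rank_result.names, rank_result.ordinal)}
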
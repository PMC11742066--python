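"""Independent reference computations used as test oracles.

Everything here is deliberately written against different libraries or in a
different style from the package implementation (SLSQP convex programming
instead of SMO; explicit sorting loops instead of vectorised rank calls) so
that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def brute_force_svr_dual(X, y, C, sigma, epsilon):
    """Solve the epsilon-SVR dual as a generic constrained program.

    Optimises over the 2n stacked variables (alpha, alpha*) with SLSQP,
    returning the net coefficients ``beta = alpha* - alpha`` and the
    minimised dual objective value.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    diff = X[:, None, :] - X[None, :, :]
    K = np.exp(-np.sum(diff**2, axis=2) / (2.0 * sigma**2))

    def objective(z):
        beta = z[n:] - z[:n]
        return 0.5 * beta @ K @ beta + epsilon * z.sum() - y @ beta

    def gradient(z):
        beta = z[n:] - z[:n]
        Kb = K @ beta
        return np.concatenate([-Kb + epsilon + y, Kb + epsilon - y])

    constraints = [
        {
            "type": "eq",
            "fun": lambda z: (z[n:] - z[:n]).sum(),
            "jac": lambda z: np.concatenate([-np.ones(n), np.ones(n)]),
        }
    ]
    best = None
    for start in (np.zeros(2 * n), np.full(2 * n, 0.01 * min(C, 1.0))):
        res = minimize(
            objective,
            start,
            jac=gradient,
            bounds=[(0.0, C)] * (2 * n),
            constraints=constraints,
            method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    beta = best.x[n:] - best.x[:n]
    return beta, float(best.fun), K


def feasible_bias(beta, K, y, C, epsilon, atol=1e-6):
    """Bias from the KKT-feasible interval of the dual solution (midpoint rule)."""
    e = y - K @ beta
    lo, hi = -np.inf, np.inf
    tol = atol * max(1.0, C)
    for b_i, e_i in zip(beta, e):
        if abs(b_i) <= tol:
            lo = max(lo, e_i - epsilon)
            hi = min(hi, e_i + epsilon)
        elif b_i >= C - tol:
            hi = min(hi, e_i - epsilon)
        elif b_i <= -C + tol:
            lo = max(lo, e_i + epsilon)
        elif b_i > 0:
            lo = max(lo, e_i - epsilon)
            hi = min(hi, e_i - epsilon)
        else:
            lo = max(lo, e_i + epsilon)
            hi = min(hi, e_i + epsilon)
    if not np.isfinite(lo):
        return float(hi)
    if not np.isfinite(hi):
        return float(lo)
    return float((lo + hi) / 2.0)


def friedman_by_enumeration(matrix):
    """Rank-sum Friedman statistic via explicit per-row sorting loops."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    rank_sums = np.zeros(k)
    tie_term = 0.0
    for row in matrix:
        order = sorted(range(k), key=lambda j: row[j])
        ranks = [0.0] * k
        pos = 0
        while pos < k:
            group = [order[pos]]
            while pos + len(group) < k and row[order[pos + len(group)]] == row[order[pos]]:
                group.append(order[pos + len(group)])
            avg_rank = (2 * pos + len(group) + 1) / 2.0  # mean of positions pos+1..pos+len
            for j in group:
                ranks[j] = avg_rank
            t = len(group)
            tie_term += t**3 - t
            pos += len(group)
        rank_sums += ranks
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    correction = 1.0 - tie_term / (n * (k**3 - k))
    corrected = stat / correction if correction > 0 else 0.0
    return rank_sums, stat, corrected
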
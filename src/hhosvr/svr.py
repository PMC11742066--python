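"""Epsilon-insensitive support vector regression with a Gaussian RBF kernel.

The model solves the standard dual problem

    minimize_{a, a*}  1/2 (a* - a)' K (a* - a) + eps * sum(a + a*) - y'(a* - a)
    subject to        sum(a* - a) = 0,   0 <= a_i, a_i* <= C

with kernel ``K(x, x') = exp(-||x - x'||^2 / (2 sigma^2))`` and prediction
``f(x) = sum_i beta_i K(x_i, x) + b`` where ``beta_i = a_i* - a_i``.

Training delegates the box-constrained QP to the libsvm SMO working-set
solver (via scikit-learn) at a tight tolerance; this module then recomputes
the dual objective and the maximum KKT violation from the returned
coefficients and records them in the model diagnostics, so optimality is
checked independently of the solver's own stopping rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVR as _LibsvmSVR

__all__ = [
    "SVRHyperparams",
    "SVRModel",
    "SVRConvergenceError",
    "rbf_kernel",
    "gram_matrix",
    "cross_gram",
    "train_svr",
    "predict",
    "dual_objective",
    "kkt_residual",
    "model_to_json",
    "model_from_json",
]


class SVRConvergenceError(RuntimeError):
    """Training did not reach the requested KKT residual; carries the residual."""

    def __init__(self, residual: float, message: str | None = None):
        self.residual = residual
        super().__init__(message or f"SVR training stopped with KKT residual {residual:.3e}")


@dataclass(frozen=True)
class SVRHyperparams:
    """Box constant C, RBF width sigma, and epsilon-tube half width.

    C trades training error against flatness of the regression function;
    sigma sets the kernel length scale; residuals smaller than epsilon are
    not penalised, which is what creates a sparse support-vector expansion.
    C and sigma are the two tuned parameters; epsilon is held fixed.
    """

    C: float
    sigma: float
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma**2)


@dataclass
class SVRModel:
    """Fitted dual coefficients ``beta_i = a_i* - a_i``, bias and training inputs."""

    coeffs: np.ndarray
    bias: float
    train_inputs: np.ndarray
    params: SVRHyperparams
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_support(self) -> int:
        return int(np.count_nonzero(self.coeffs))


def rbf_kernel(x: np.ndarray, x2: np.ndarray, sigma: float) -> float:
    """Gaussian kernel ``exp(-||x - x2||^2 / (2 sigma^2))`` of two samples."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    if x.shape != x2.shape:
        raise ValueError("samples must have equal dimension")
    d2 = float(np.sum((x - x2) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _as_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def gram_matrix(X: np.ndarray, sigma: float) -> np.ndarray:
    """Symmetric kernel matrix of a sample set (unit diagonal, entries in (0, 1])."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = _as_matrix(X)
    d2 = cdist(X, X, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def cross_gram(X1: np.ndarray, X2: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X1, X2 = _as_matrix(X1), _as_matrix(X2)
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("feature dimensions differ")
    return np.exp(-cdist(X1, X2, metric="sqeuclidean") / (2.0 * sigma**2))


def train_svr(
    X: np.ndarray,
    y: np.ndarray,
    params: SVRHyperparams,
    tol: float = 1e-9,
    max_iter: int = -1,
    kkt_tol: float = 1e-6,
) -> SVRModel:
    """Fit the dual problem and return the model with optimality diagnostics.

    ``tol`` is the SMO stopping tolerance; ``kkt_tol`` is the acceptance
    threshold on the recomputed maximum KKT violation.  The SMO stopping
    rule does not map one-to-one onto that violation, so when a fit misses
    ``kkt_tol`` it is retried at a 100x tighter ``tol`` (twice); a fit whose
    residual still exceeds ``kkt_tol`` raises :class:`SVRConvergenceError`
    carrying the residual rather than returning a silently inaccurate model.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data must be finite")

    model = None
    residual = np.inf
    for attempt_tol in (tol, tol * 1e-2):
        solver = _LibsvmSVR(
            kernel="rbf",
            C=params.C,
            gamma=params.gamma,
            epsilon=params.epsilon,
            tol=attempt_tol,
            max_iter=max_iter,
            cache_size=200,
        )
        solver.fit(X, y)
        coeffs = np.zeros(X.shape[0])
        coeffs[solver.support_] = solver.dual_coef_[0]
        model = SVRModel(
            coeffs=coeffs,
            bias=float(solver.intercept_[0]),
            train_inputs=X.copy(),
            params=params,
        )
        residual = kkt_residual(model, X, y)
        if residual <= kkt_tol:
            break
        polished = _polish_free_set(model, y)
        if polished is not None:
            polished_residual = kkt_residual(polished, X, y)
            if polished_residual < residual:
                model, residual = polished, polished_residual
        if residual <= kkt_tol:
            break
    model.diagnostics = {
        "dual_objective": dual_objective(model, y),
        "kkt_residual": residual,
        "n_support": model.n_support,
    }
    if residual > kkt_tol:
        raise SVRConvergenceError(residual)
    return model


def _polish_free_set(model: SVRModel, y: np.ndarray) -> SVRModel | None:
    """Refine free support-vector coefficients and bias to exact KKT equality.

    The SMO solver maintains its gradient incrementally, so on
    ill-conditioned kernels its returned solution can violate the tube
    equalities of the free support vectors by more than the recomputed
    residual tolerance even though its internal bookkeeping says optimal.
    Keeping the solver's active-set classification fixed, the free
    coefficients and the bias satisfy the linear system

        K_FF beta_F + b = y_F - eps * sign(beta_F) - K_FB beta_B
        sum(beta_F)      = -sum(beta_B)

    which this solves directly.  Returns None when there are no free
    support vectors or the polished coefficients leave their box segment
    (then the classification was wrong and the original fit stands).
    """
    C = model.params.C
    eps = model.params.epsilon
    beta = model.coeffs
    atol = 1e-10 * max(1.0, C)
    free = (np.abs(beta) > atol) & (np.abs(beta) < C - atol)
    if not free.any():
        return None
    bound = ~free
    K = gram_matrix(model.train_inputs, model.params.sigma)
    sign = np.sign(beta[free])
    n_free = int(free.sum())
    lhs = np.zeros((n_free + 1, n_free + 1))
    lhs[:n_free, :n_free] = K[np.ix_(free, free)]
    lhs[:n_free, n_free] = 1.0
    lhs[n_free, :n_free] = 1.0
    rhs = np.zeros(n_free + 1)
    rhs[:n_free] = y[free] - eps * sign - K[np.ix_(free, bound)] @ beta[bound]
    rhs[n_free] = -beta[bound].sum()
    solution, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
    beta_free = solution[:n_free]
    if np.any(np.sign(beta_free) != sign) or np.any(np.abs(beta_free) >= C - atol):
        return None
    polished = beta.copy()
    polished[free] = beta_free
    return SVRModel(
        coeffs=polished,
        bias=float(solution[n_free]),
        train_inputs=model.train_inputs,
        params=model.params,
    )


def predict(model: SVRModel, X: np.ndarray) -> np.ndarray:
    """Support-vector expansion ``f(x) = sum_i beta_i K(x_i, x) + b``."""
    X = _as_matrix(X)
    if X.shape[1] != model.train_inputs.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training dimension "
            f"{model.train_inputs.shape[1]}"
        )
    K = cross_gram(model.train_inputs, X, model.params.sigma)
    return K.T @ model.coeffs + model.bias


def dual_objective(model: SVRModel, y: np.ndarray) -> float:
    """Value of the minimised dual at the fitted coefficients.

    Valid at any point where ``a_i`` and ``a_i*`` are not simultaneously
    active, in which case ``sum(a + a*) = sum(|beta|)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    beta = model.coeffs
    K = gram_matrix(model.train_inputs, model.params.sigma)
    return float(
        0.5 * beta @ K @ beta
        + model.params.epsilon * np.abs(beta).sum()
        - y @ beta
    )


def kkt_residual(model: SVRModel, X: np.ndarray, y: np.ndarray) -> float:
    """Maximum violation of the first-order optimality conditions.

    With prediction error ``g_i = f(x_i) - y_i`` the optimal coefficients
    satisfy, for each sample,

    * ``beta_i = 0``        : ``|g_i| <= eps``
    * ``0 < beta_i < C``    : ``g_i = -eps``
    * ``beta_i = C``        : ``g_i <= -eps``
    * ``-C < beta_i < 0``   : ``g_i = +eps``
    * ``beta_i = -C``       : ``g_i >= +eps``

    Returns the largest violation across samples; 0 means exact optimality
    (this also validates the bias, which enters through ``g``).
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    g = predict(model, X) - y
    beta = model.coeffs
    C, eps = model.params.C, model.params.epsilon
    atol = 1e-10 * max(1.0, C)  # boundary classification tolerance

    res = np.zeros_like(beta)
    at_zero = np.abs(beta) <= atol
    at_upper = beta >= C - atol
    at_lower = beta <= -C + atol
    pos_free = (~at_zero) & (~at_upper) & (beta > 0)
    neg_free = (~at_zero) & (~at_lower) & (beta < 0)

    res[at_zero] = np.maximum(0.0, np.abs(g[at_zero]) - eps)
    res[at_upper & ~at_zero] = np.maximum(0.0, g[at_upper & ~at_zero] + eps)
    res[at_lower & ~at_zero] = np.maximum(0.0, eps - g[at_lower & ~at_zero])
    res[pos_free] = np.abs(g[pos_free] + eps)
    res[neg_free] = np.abs(g[neg_free] - eps)
    # equality constraint of the dual
    eq_violation = abs(beta.sum())
    return float(max(res.max(initial=0.0), eq_violation))


def model_to_json(model: SVRModel, path: str | Path | None = None) -> str:
    """Serialize a fitted model to a flat JSON record (round-trips bit-exactly)."""
    record = {
        "coeffs": model.coeffs.tolist(),
        "bias": model.bias,
        "train_inputs": model.train_inputs.tolist(),
        "C": model.params.C,
        "sigma": model.params.sigma,
        "epsilon": model.params.epsilon,
        "diagnostics": model.diagnostics,
    }
    text = json.dumps(record, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> SVRModel:
    """Load a model produced by :func:`model_to_json` (text or file path)."""
    text = Path(source).read_text() if isinstance(source, Path) else source
    record = json.loads(text)
    return SVRModel(
        coeffs=np.asarray(record["coeffs"], dtype=float),
        bias=float(record["bias"]),
        train_inputs=np.asarray(record["train_inputs"], dtype=float),
        params=SVRHyperparams(
            C=record["C"], sigma=record["sigma"], epsilon=record["epsilon"]
        ),
        diagnostics=record.get("diagnostics", {}),
    )
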
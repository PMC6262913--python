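"""Conditional-logit (discrete-choice) likelihood.

The probability that an individual chooses alternative l from the C
alternatives of choice set i is

    P_il = exp(beta . X_il) / sum_c exp(beta . X_ic),

where beta . X_il is the *utility* of the alternative — a linear predictor
over its k covariates.  There is no intercept: any column constant within a
set cancels from the ratio, which is also why the categorical habitat layer
is reference-coded.

All likelihood quantities are evaluated with a per-set max-utility
subtraction, so large |beta| cannot overflow the exponentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .choices import ChoiceData, ChoiceSet
from .errors import InvalidInputError, ShapeError


@dataclass
class Coefficients:
    """Selection coefficients, one per design column."""

    beta: np.ndarray
    column_names: list[str] | None = None

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(self.beta)):
            raise InvalidInputError("coefficients must be finite")
        if self.column_names is not None and len(self.column_names) != len(self.beta):
            raise ShapeError("column_names length must match beta")


def _as_beta(beta) -> np.ndarray:
    b = beta.beta if isinstance(beta, Coefficients) else np.atleast_1d(np.asarray(beta, dtype=float))
    return b


def utility(beta: Coefficients | np.ndarray, x: np.ndarray) -> float:
    """Inner product beta . x, the utility of one alternative."""
    b = _as_beta(beta)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != b.shape[0]:
        raise ShapeError(f"design has {x.shape[-1]} columns, beta has {b.shape[0]}")
    return float(x @ b) if x.ndim == 1 else x @ b


def _set_log_probs(b: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Log choice probabilities for stacked sets X of shape (..., C, k)."""
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("design values must be finite")
    u = X @ b
    u = u - u.max(axis=-1, keepdims=True)
    # stable after max subtraction; avoids scipy logsumexp overhead in the
    # sampler's innermost loop
    return u - np.log(np.exp(u).sum(axis=-1, keepdims=True))


def choice_probabilities(beta: Coefficients | np.ndarray, cs: ChoiceSet | np.ndarray) -> np.ndarray:
    """Softmax choice probabilities over the alternatives of one set."""
    b = _as_beta(beta)
    X = cs.X if isinstance(cs, ChoiceSet) else np.asarray(cs, dtype=float)
    if X.shape[-1] != b.shape[0]:
        raise ShapeError(f"design has {X.shape[-1]} columns, beta has {b.shape[0]}")
    return np.exp(_set_log_probs(b, X))


def all_choice_probabilities(beta: Coefficients | np.ndarray, data: ChoiceData) -> np.ndarray:
    """(n_sets, C) matrix of choice probabilities for every set."""
    b = _as_beta(beta)
    if data.n_columns != b.shape[0]:
        raise ShapeError(f"data has {data.n_columns} columns, beta has {b.shape[0]}")
    return np.exp(_set_log_probs(b, data.X))


def log_likelihood(
    beta: Coefficients | np.ndarray, data: ChoiceData
) -> tuple[float, np.ndarray]:
    """Total and per-set log-likelihood of the chosen alternatives.

    The per-set vector is the pointwise contribution needed by WAIC.
    """
    b = _as_beta(beta)
    if data.n_columns != b.shape[0]:
        raise ShapeError(f"data has {data.n_columns} columns, beta has {b.shape[0]}")
    logp = _set_log_probs(b, data.X)
    pointwise = logp[np.arange(data.n_sets), data.chosen]
    return float(pointwise.sum()), pointwise


def log_likelihood_gradient(beta: Coefficients | np.ndarray, data: ChoiceData) -> np.ndarray:
    """Analytic score: sum_i ( x_chosen - sum_l P_il x_il )."""
    b = _as_beta(beta)
    if data.n_columns != b.shape[0]:
        raise ShapeError(f"data has {data.n_columns} columns, beta has {b.shape[0]}")
    P = np.exp(_set_log_probs(b, data.X))
    x_chosen = data.X[np.arange(data.n_sets), data.chosen]
    expected = np.einsum("ic,ick->ik", P, data.X)
    return (x_chosen - expected).sum(axis=0)


def pointwise_log_likelihood(draws: np.ndarray, data: ChoiceData) -> np.ndarray:
    """(n_draws, n_sets) pointwise log-likelihood matrix for posterior draws."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[1] != data.n_columns:
        raise ShapeError("draw dimension does not match data columns")
    rows = np.arange(data.n_sets)
    out = np.empty((len(draws), data.n_sets))
    # chunked over draws to bound the (chunk, n_sets, C) utility tensor
    for lo in range(0, len(draws), 256):
        block = draws[lo : lo + 256]
        u = np.einsum("ick,sk->sic", data.X, block)
        u -= u.max(axis=2, keepdims=True)
        denom = np.log(np.exp(u).sum(axis=2))
        out[lo : lo + len(block)] = u[:, rows, data.chosen] - denom
    return out


def log_likelihood_hessian(beta: Coefficients | np.ndarray, data: ChoiceData) -> np.ndarray:
    """Analytic Hessian: -sum_i Cov_{P_i}(x), always negative semidefinite."""
    b = _as_beta(beta)
    P = np.exp(_set_log_probs(b, data.X))
    Ex = np.einsum("ic,ick->ik", P, data.X)
    Exx = np.einsum("ic,ick,icl->ikl", P, data.X, data.X)
    cov = Exx - np.einsum("ik,il->ikl", Ex, Ex)
    return -cov.sum(axis=0)


def fit_mle(data: ChoiceData, beta0: np.ndarray | None = None, tol: float = 1e-10) -> np.ndarray:
    """Maximum-likelihood coefficients (the log-likelihood is concave)."""
    x0 = np.zeros(data.n_columns) if beta0 is None else np.asarray(beta0, dtype=float)

    def neg(b):
        ll, _ = log_likelihood(b, data)
        return -ll

    def grad(b):
        return -log_likelihood_gradient(b, data)

    res = minimize(neg, x0, jac=grad, method="BFGS", options={"gtol": tol, "maxiter": 500})
    return res.x
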
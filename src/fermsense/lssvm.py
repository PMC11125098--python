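"""Least squares support vector machine (LSSVM) regression with RBF kernel.

The LSSVM replaces the epsilon-insensitive SVM program with equality
constraints, so the fit reduces to one linear "saddle" system

    [ 0   1'        ] [b]     [0]
    [ 1   Omega+I/g ] [alpha] [y]

with Omega_ij = k(x_i, x_j), regularization gamma (g) and RBF width sigma.
Prediction is y(x) = sum_i alpha_i k(x, x_i) + b.  Suitable for the small,
nonlinear per-condition fermentation datasets this package targets; inputs
are assumed pre-scaled (the TCA embedding upstream handles scaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

__all__ = ["LSSVMModel", "kernel_rbf", "fit_lssvm", "predict"]


def kernel_rbf(x: np.ndarray, x_prime: np.ndarray, sigma: float) -> float:
    """RBF kernel exp(-||x - x'||^2 / (2 sigma^2))."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float).ravel()
    x_prime = np.asarray(x_prime, dtype=float).ravel()
    d2 = float(np.sum((x - x_prime) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _rbf_gram(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-cdist(X, Y, metric="sqeuclidean") / (2.0 * sigma**2))


@dataclass
class LSSVMModel:
    """Fitted dual solution: support data, coefficients alpha, bias b."""

    X_train: np.ndarray
    alpha: np.ndarray
    b: float
    gamma: float
    sigma: float


def fit_lssvm(X: np.ndarray, y: np.ndarray, gamma: float, sigma: float) -> LSSVMModel:
    """Solve the LSSVM dual system by a Schur complement on the bias.

    With A = Omega + I/gamma (symmetric positive definite), solving
    A u = 1 and A v = y gives b = (1'v)/(1'u) and alpha = v - b u, which
    satisfies both KKT rows, in particular sum(alpha) = 0 exactly up to
    round-off.
    """
    if not gamma > 0 or not sigma > 0:
        raise ValueError("gamma and sigma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    N = X.shape[0]
    if y.shape[0] != N:
        raise ValueError("X and y lengths differ")

    A = _rbf_gram(X, X, sigma) + np.eye(N) / gamma
    try:
        c = cho_factor(A)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(A)
        raise np.linalg.LinAlgError(
            f"LSSVM system not positive definite (cond ~ {cond:.3e}); "
            "increase gamma or check for duplicate samples"
        ) from exc
    ones = np.ones(N)
    u = cho_solve(c, ones)
    v = cho_solve(c, y)
    b = float(ones @ v) / float(ones @ u)
    alpha = v - b * u
    return LSSVMModel(X_train=X, alpha=alpha, b=b, gamma=gamma, sigma=sigma)


def predict(model: LSSVMModel, X_new: np.ndarray) -> np.ndarray:
    """Evaluate y(x) = sum_i alpha_i k(x, x_i) + b at each row of X_new."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"expected {model.X_train.shape[1]} features, got {X_new.shape[1]}"
        )
    K = _rbf_gram(X_new, model.X_train, model.sigma)
    return K @ model.alpha + model.b
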
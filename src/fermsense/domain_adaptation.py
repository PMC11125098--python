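"""Transfer component analysis (TCA) for cross-condition domain adaptation.

A soft sensor trained on one fermentation working condition degrades when the
feature distribution shifts under a new condition.  TCA learns a shared
kernel subspace in which the maximum mean discrepancy (MMD) between a labeled
source condition and the (unlabeled) target condition is small while data
variance is preserved, so a regressor fitted on embedded source samples
transfers to embedded target samples.

The embedding solves

    min_W  tr(W' K L K W) + mu * tr(W' W)    s.t.  W' K H K W = I

where ``K`` is the kernel matrix of the pooled source+target samples, ``L``
the MMD coefficient matrix, ``H`` the centering matrix and ``mu`` a ridge
trade-off.  The fit is transductive: all available target features enter the
pool; new samples are embedded through their kernel rows against the stored
pool (empirical kernel map).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

__all__ = [
    "ConditionDataset",
    "KernelSpec",
    "TCAModel",
    "build_mmd_matrix",
    "build_centering_matrix",
    "gram_matrix",
    "mmd_distance",
    "median_heuristic_sigma",
    "fit_tca",
    "transform",
]

#: canonical order of the auxiliary sensor channels
CHANNEL_NAMES = ("v", "T", "q", "Ph", "Do", "P")


@dataclass
class ConditionDataset:
    """Samples from one fermentation working condition.

    ``features`` holds the auxiliary sensor channels (stirring speed v,
    temperature T, airflow q, pH, dissolved oxygen Do, pressure P), one row
    per sampling instant.  Label vectors (cell and product concentration,
    g/L) are optional: target conditions are typically unlabeled.
    """

    features: np.ndarray
    labels_cell: Optional[np.ndarray] = None
    labels_product: Optional[np.ndarray] = None
    condition_id: str = ""
    time_h: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing/non-finite values")
        for name in ("labels_cell", "labels_product", "time_h"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (self.n_samples,):
                    raise ValueError(f"{name} must have length {self.n_samples}")
                setattr(self, name, v)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]

    def label(self, target: str) -> np.ndarray:
        if target == "cell":
            y = self.labels_cell
        elif target == "product":
            y = self.labels_product
        else:
            raise ValueError(f"unknown target {target!r}")
        if y is None:
            raise ValueError(f"condition {self.condition_id!r} has no {target} labels")
        return y


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and bandwidth used for TCA and MMD."""

    kind: str = "rbf"
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf" and not self.sigma > 0:
            raise ValueError("rbf kernel requires sigma > 0")


def build_mmd_matrix(n: int, m: int) -> np.ndarray:
    """MMD coefficient matrix L for ``n`` source and ``m`` target samples.

    Entries are 1/n^2 within the source block, 1/m^2 within the target
    block and -1/(nm) across blocks, so that tr(KL) equals the squared
    empirical MMD for kernel matrix K of the stacked pool.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    v = np.concatenate([np.full(n, 1.0 / n), np.full(m, -1.0 / m)])
    return np.outer(v, v)


def build_centering_matrix(N: int) -> np.ndarray:
    """Centering matrix H = I - (1/N) 11'; symmetric and idempotent."""
    if N < 1:
        raise ValueError("N must be positive")
    return np.eye(N) - np.full((N, N), 1.0 / N)


def gram_matrix(X: np.ndarray, Y: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Kernel matrix K[i, j] = k(X[i], Y[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} columns, Y has {Y.shape[1]}"
        )
    if kernel.kind == "linear":
        return X @ Y.T
    d2 = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * kernel.sigma**2))


def mmd_distance(Xs: np.ndarray, Xt: np.ndarray, kernel: KernelSpec) -> float:
    """Squared empirical MMD between two sample sets, computed as tr(KL)."""
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
    if Xs.shape[0] == 0 or Xt.shape[0] == 0:
        raise ValueError("both sample sets must be non-empty")
    pool = np.vstack([Xs, Xt])
    K = gram_matrix(pool, pool, kernel)
    L = build_mmd_matrix(Xs.shape[0], Xt.shape[0])
    return float(np.trace(K @ L))


def median_heuristic_sigma(X: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise distance of the pooled data."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = cdist(X, X)
    off = d[np.triu_indices_from(d, k=1)]
    med = float(np.median(off)) if off.size else 1.0
    return med if med > 0 else 1.0


@dataclass
class TCAModel:
    """Fitted transfer map: stored fit pool, kernel, projection matrix W."""

    fit_pool: np.ndarray
    kernel: KernelSpec
    W: np.ndarray
    m_c: int
    mu: float
    scaler_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    scaler_std: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_source: int = 0
    n_target: int = 0


def _pooled_scaler(pool: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = pool.mean(axis=0)
    std = pool.std(axis=0)
    std = np.where(std > 0, std, 1.0)  # constant channels pass through centered
    return mean, std


def fit_tca(
    Xs: np.ndarray,
    Xt: np.ndarray,
    kernel: Optional[KernelSpec] = None,
    m_c: Optional[int] = None,
    mu: float = 1.0,
    scale: bool = True,
) -> TCAModel:
    """Fit the transfer components on pooled source + target features.

    Parameters
    ----------
    Xs, Xt
        Source and target feature matrices (same channel count).  The fit is
        transductive: ``Xt`` is every unlabeled target sample available.
    kernel
        Kernel for the pooled Gram matrix.  Default: rbf with the median
        pairwise-distance bandwidth of the (scaled) pool.
    m_c
        Number of transfer components; default ``min(8, n+m-1)``.
    mu
        Ridge trade-off on tr(W'W) (must be positive).
    scale
        Z-score each channel with pooled statistics before kernel
        evaluation; the scaler is stored on the model and reapplied by
        :func:`transform`.  The channels mix rpm, degrees Celsius and MPa,
        so this is on by default.

    Returns
    -------
    TCAModel with columns of ``W`` satisfying W' K H K W = I within
    numerical tolerance, deterministic up to a fixed sign convention.
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target must share the channel count")
    n, m = Xs.shape[0], Xt.shape[0]
    N = n + m
    if not mu > 0:
        raise ValueError("mu must be positive")
    if m_c is None:
        m_c = min(8, N - 1)
    if m_c < 1 or m_c > N:
        raise ValueError(f"m_c must be in [1, {N}]")

    pool_raw = np.vstack([Xs, Xt])
    if scale:
        mean, std = _pooled_scaler(pool_raw)
    else:
        mean = np.zeros(pool_raw.shape[1])
        std = np.ones(pool_raw.shape[1])
    pool = (pool_raw - mean) / std

    if kernel is None:
        kernel = KernelSpec("rbf", median_heuristic_sigma(pool))

    K = gram_matrix(pool, pool, kernel)
    L = build_mmd_matrix(n, m)
    H = build_centering_matrix(N)

    A = K @ H @ K  # variance term, to maximize
    B = K @ L @ K + mu * np.eye(N)  # MMD + ridge term, to minimize
    A = 0.5 * (A + A.T)
    B = 0.5 * (B + B.T)

    # leading generalized eigenvectors of A w = lambda B w (B is PD: L is PSD
    # rank-1 and mu > 0)
    try:
        eigvals, eigvecs = eigh(A, B)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"TCA eigenproblem failed despite ridge mu={mu}: {exc}"
        ) from exc
    order = np.argsort(eigvals)[::-1][:m_c]
    lam = eigvals[order]
    W = eigvecs[:, order]
    if np.any(lam <= 1e-12):
        raise np.linalg.LinAlgError(
            f"requested m_c={m_c} components but only {int(np.sum(eigvals > 1e-12))} "
            "have positive variance; reduce m_c"
        )
    # eigh returns B-orthonormal columns; rescale so W' A W = I (A-quadratic
    # form of a generalized eigenvector is lambda * its B-form)
    W = W / np.sqrt(lam)[None, :]
    # sign convention: largest-magnitude entry of each column positive
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    W = W * signs[None, :]

    return TCAModel(
        fit_pool=pool,
        kernel=kernel,
        W=W,
        m_c=m_c,
        mu=mu,
        scaler_mean=mean,
        scaler_std=std,
        n_source=n,
        n_target=m,
    )


def transform(model: TCAModel, X: np.ndarray) -> np.ndarray:
    """Embed samples through the empirical kernel map of the fit pool.

    Rows of the returned matrix are ``[k(x, pool_1), ..., k(x, pool_N)] W``;
    applying this to the fit pool itself reproduces the training embedding.
    """
    if model.W is None:
        raise ValueError("model is not fitted")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xsc = (X - model.scaler_mean) / model.scaler_std
    Kx = gram_matrix(Xsc, model.fit_pool, model.kernel)
    return Kx @ model.W


def embedded_mmd(model: TCAModel) -> float:
    """Squared MMD between source and target blocks of the fit-pool embedding.

    Equals tr(K-tilde L) for the projected kernel K-tilde = K W W' K; a
    linear kernel on the embedding coordinates gives exactly that quantity.
    """
    Z = gram_matrix(model.fit_pool, model.fit_pool, model.kernel) @ model.W
    Zs, Zt = Z[: model.n_source], Z[model.n_source :]
    return mmd_distance(Zs, Zt, KernelSpec("linear"))
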
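"""Maximal information coefficient (MIC) machinery for sub-model weighting.

Each labeled source condition ("subset") is summarized by a single weighted
centroid sample.  The chain is:

1. pairwise MIC between every two samples of the subset, treating a sample's
   d channel values paired with another sample's as the scatter to grid;
2. the sample most MIC-correlated with all others becomes the raw centroid;
3. a per-feature information matrix against that reference sample feeds the
   entropy-weight method (features whose information shares are less uniform
   across samples carry more weight);
4. the weighted centroid is the elementwise product of the weights and the
   raw centroid.

MIC itself is the grid-normalized maximum of plug-in mutual information over
admissible grid partitions of the paired scatter, bounded in [0, 1] and
invariant under strictly monotone transformations of either argument (only
the induced orderings matter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MICConfig",
    "CentroidResult",
    "grid_mutual_information",
    "mic",
    "pairwise_mic_matrix",
    "select_centroid_index",
    "feature_mi_matrix",
    "entropy_weights",
    "compute_centroid",
]


@dataclass(frozen=True)
class MICConfig:
    """Grid-search budget for MIC.

    The admissible grid shapes (a, b) satisfy ``min_bins <= a, b <= max_bins``
    and ``a * b <= max(4, ceil(count ** b_exponent))`` — the floor of 4
    guarantees the 2 x 2 family is always searchable even for very short
    sequences (six channel values), where a literal ``count ** 0.6`` budget
    would forbid every grid.  For counts up to ``exact_threshold`` the cut
    placement search is exhaustive over all boundaries between distinct
    sorted values; beyond that, equi-spaced quantile candidates with local
    refinement are used.
    """

    b_exponent: float = 0.6
    min_bins: int = 2
    max_bins: int = 15
    exact_threshold: int = 12

    def __post_init__(self) -> None:
        if self.min_bins < 2:
            raise ValueError("min_bins must be >= 2")
        if self.max_bins < self.min_bins:
            raise ValueError("max_bins must be >= min_bins")

    def budget(self, count: int) -> int:
        return max(4, math.ceil(count**self.b_exponent))


def grid_mutual_information(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    x_cuts: Sequence[float],
    y_cuts: Sequence[float],
) -> float:
    """Plug-in mutual information (bits) of the grid-cell contingency table.

    ``x_cuts``/``y_cuts`` are strictly increasing cut positions; a value v
    lands in cell index ``#{cuts < v}`` (values equal to a cut go to the
    upper cell).  Empty cells contribute zero (0 log 0 = 0 convention).
    """
    P = np.atleast_2d(np.asarray(pairs, dtype=float))
    if P.shape[0] < 2 or P.shape[1] != 2:
        raise ValueError("need at least 2 (x, y) pairs")
    xc = np.asarray(x_cuts, dtype=float)
    yc = np.asarray(y_cuts, dtype=float)
    for c in (xc, yc):
        if c.size > 1 and not np.all(np.diff(c) > 0):
            raise ValueError("cut lists must be strictly increasing")
    ix = np.searchsorted(xc, P[:, 0], side="right")
    iy = np.searchsorted(yc, P[:, 1], side="right")
    counts = np.zeros((xc.size + 1, yc.size + 1))
    np.add.at(counts, (ix, iy), 1.0)
    return _table_mi_bits(counts)


def _table_mi_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    terms = np.zeros_like(p)
    terms[mask] = p[mask] * np.log2(p[mask] / (px * py + ~mask)[mask])
    return float(terms.sum())


def _best_mi_2x2(x: np.ndarray, y: np.ndarray, return_cuts: bool = False):
    """Exact max plug-in MI over every 2 x 2 grid, vectorized over cut pairs.

    Equivalent to the exhaustive placement search for shape (2, 2) but
    evaluates all cut combinations at once via 0/1 membership matrices.
    With ``return_cuts`` the argmax cut pair (first maximum in x-major
    order) is returned alongside the value.
    """
    cx = _gap_cuts(x)
    cy = _gap_cuts(y)
    if cx.size == 0 or cy.size == 0:
        return (0.0, np.empty(0), np.empty(0)) if return_cuts else 0.0
    n = float(x.size)
    X1 = (x[None, :] > cx[:, None]).astype(float)  # upper x-cell membership
    Y1 = (y[None, :] > cy[:, None]).astype(float)
    n11 = X1 @ Y1.T
    nx1 = X1.sum(axis=1)[:, None]
    ny1 = Y1.sum(axis=1)[None, :]
    n10 = nx1 - n11
    n01 = ny1 - n11
    n00 = n - nx1 - ny1 + n11
    mi = np.zeros_like(n11)
    for cnt, rx, cy_ in (
        (n11, nx1, ny1),
        (n10, nx1, n - ny1),
        (n01, n - nx1, ny1),
        (n00, n - nx1, n - ny1),
    ):
        mask = cnt > 0
        contrib = np.zeros_like(cnt)
        marg = np.broadcast_to(rx * cy_, cnt.shape)  # positive wherever cnt > 0
        contrib[mask] = (cnt[mask] / n) * np.log2(n * cnt[mask] / marg[mask])
        mi += contrib
    if not return_cuts:
        return float(mi.max())
    i, j = np.unravel_index(int(np.argmax(mi)), mi.shape)
    return float(mi[i, j]), cx[[i]], cy[[j]]


def _gap_cuts(x: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values (candidate cuts)."""
    xs = np.unique(x)
    return (xs[:-1] + xs[1:]) / 2.0


def _best_mi_over_cuts(
    x: np.ndarray, y: np.ndarray, a: int, b: int, config: MICConfig,
    return_cuts: bool = False,
):
    """Max plug-in MI over placements of a-1 x-cuts and b-1 y-cuts."""
    n = x.size
    pairs = np.column_stack([x, y])
    cx = _gap_cuts(x)
    cy = _gap_cuts(y)
    empty = (0.0, np.empty(0), np.empty(0))
    if cx.size < a - 1 or cy.size < b - 1:
        return empty if return_cuts else 0.0  # not enough distinct values
    if n <= config.exact_threshold:
        best, bx, by = 0.0, np.empty(0), np.empty(0)
        for xcut in combinations(cx, a - 1):
            for ycut in combinations(cy, b - 1):
                mi = grid_mutual_information(pairs, xcut, ycut)
                if mi > best:
                    best, bx, by = mi, np.asarray(xcut), np.asarray(ycut)
        return (best, bx, by) if return_cuts else best
    # approximate: equi-quantile candidate cuts, then greedy local refinement
    def pick(cands: np.ndarray, k: int) -> np.ndarray:
        if cands.size <= k:
            return np.arange(cands.size)
        return np.unique(
            np.round(np.linspace(0, cands.size - 1, k)).astype(int)
        )
    kx = pick(cx, 16)
    ky = pick(cy, 16)
    best = -1.0
    best_ix = best_iy = None
    for xidx in combinations(kx, a - 1):
        for yidx in combinations(ky, b - 1):
            mi = grid_mutual_information(pairs, cx[list(xidx)], cy[list(yidx)])
            if mi > best:
                best, best_ix, best_iy = mi, list(xidx), list(yidx)
    # local refinement: shift each chosen cut to neighboring gap midpoints
    improved = True
    while improved:
        improved = False
        for cuts, idx in ((cx, best_ix), (cy, best_iy)):
            for pos in range(len(idx)):
                for step in (-1, 1):
                    trial = idx[pos] + step
                    if 0 <= trial < cuts.size and trial not in idx:
                        cand = sorted(idx[:pos] + [trial] + idx[pos + 1 :])
                        if cuts is cx:
                            mi = grid_mutual_information(pairs, cx[cand], cy[best_iy])
                        else:
                            mi = grid_mutual_information(pairs, cx[best_ix], cy[cand])
                        if mi > best:
                            best = mi
                            idx[:] = cand
                            improved = True
    if return_cuts:
        return best, cx[best_ix], cy[best_iy]
    return best


def mic(x: np.ndarray, y: np.ndarray, config: Optional[MICConfig] = None) -> float:
    """Maximal information coefficient of the paired sequences x, y in [0, 1]."""
    if config is None:
        config = MICConfig()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("MIC needs at least 4 paired points (a 2 x 2 grid)")
    best, _, _ = _optimal_grid(x, y, config)
    return min(best, 1.0)


def _optimal_grid(
    x: np.ndarray, y: np.ndarray, config: MICConfig
) -> tuple[float, np.ndarray, np.ndarray]:
    """Best normalized grid MI over admissible shapes, with its cut lists."""
    B = config.budget(x.size)
    best, bx, by = 0.0, np.empty(0), np.empty(0)
    for a in range(config.min_bins, config.max_bins + 1):
        for b in range(config.min_bins, config.max_bins + 1):
            if a * b > B:
                continue
            if a == 2 and b == 2:
                mi, xc, yc = _best_mi_2x2(x, y, return_cuts=True)
            else:
                mi, xc, yc = _best_mi_over_cuts(x, y, a, b, config, return_cuts=True)
            val = mi / math.log2(min(a, b))
            if val > best:
                best, bx, by = val, xc, yc
    return best, bx, by


def pairwise_mic_matrix(samples: np.ndarray, config: Optional[MICConfig] = None) -> np.ndarray:
    """Sample-by-sample MIC matrix; each pair of rows supplies the d paired
    channel values as the scatter.  Diagonal is 1 by definition."""
    S = np.atleast_2d(np.asarray(samples, dtype=float))
    n_q, d = S.shape
    if n_q < 2:
        raise ValueError("need at least two samples")
    if d < 4:
        raise ValueError("need at least 4 channels to grid a sample pair")
    phi = np.eye(n_q)
    for i in range(n_q):
        for j in range(i + 1, n_q):
            phi[i, j] = phi[j, i] = mic(S[i], S[j], config)
    return phi


def select_centroid_index(phi: np.ndarray) -> int:
    """Index of the sample most correlated with all others (row sums without
    the diagonal); ties resolve to the smallest index."""
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    sums = phi.sum(axis=1) - np.diag(phi)
    return int(np.argmax(sums))


def feature_mi_matrix(
    samples: np.ndarray, k: int, config: Optional[MICConfig] = None
) -> np.ndarray:
    """Per-feature information of each sample against the reference sample k.

    For each sample i, the d channel values of the reference x_k are paired
    with those of x_i (the same scatter the pairwise MIC grids) and the
    MIC-optimal grid of that scatter is located.  ``psi[i, d']`` is then the
    pointwise mutual information of feature d' 's paired point under that
    grid, clamped at zero — each feature's contribution to the dependence
    between sample i and the reference.  Nonnegative; zero wherever the
    pair carries no grid (e.g. a constant comparison sample).
    """
    if config is None:
        config = MICConfig()
    S = np.atleast_2d(np.asarray(samples, dtype=float))
    n_q, d = S.shape
    if not 0 <= k < n_q:
        raise ValueError(f"reference index {k} out of range")
    psi = np.zeros((n_q, d))
    xk = S[k]
    for i in range(n_q):
        _, xc, yc = _optimal_grid(xk, S[i], config)
        if xc.size == 0 or yc.size == 0:
            continue
        psi[i] = _pointwise_mi(xk, S[i], xc, yc)
    return psi


def _pointwise_mi(x: np.ndarray, y: np.ndarray, x_cuts, y_cuts) -> np.ndarray:
    """Clamped per-point PMI log2(p(cell) / (p(row) p(col))) under the grid."""
    n = x.size
    ix = np.searchsorted(np.asarray(x_cuts, float), x, side="right")
    iy = np.searchsorted(np.asarray(y_cuts, float), y, side="right")
    nx = np.bincount(ix, minlength=len(x_cuts) + 1)
    ny = np.bincount(iy, minlength=len(y_cuts) + 1)
    joint = np.zeros((len(x_cuts) + 1, len(y_cuts) + 1))
    np.add.at(joint, (ix, iy), 1.0)
    pmi = np.log2(n * joint[ix, iy] / (nx[ix] * ny[iy]))
    return np.maximum(pmi, 0.0)


def entropy_weights(psi: np.ndarray, normalizer: str = "samples") -> np.ndarray:
    """Entropy-method feature weights from a nonnegative information matrix.

    Column shares rho[i, d] = psi[i, d] / sum_i psi[i, d]; column entropy
    E_d = -sum rho log rho / log(n) (0 log 0 = 0); weights
    w_d = (1 - E_d) / (d - sum E_d), summing to 1.  ``normalizer`` selects
    the entropy denominator: "samples" (log n_q, keeping E_d in [0, 1]) or
    "features" (log d).  An all-zero column has zero entropy by convention
    and therefore maximal weight; an all-zero matrix raises.
    """
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if np.any(psi < 0):
        raise ValueError("information matrix must be nonnegative")
    n_q, d = psi.shape
    colsum = psi.sum(axis=0)
    if np.all(colsum == 0):
        raise ValueError("all-zero information matrix: weights undefined")
    if normalizer == "samples":
        log_norm = math.log(n_q)
    elif normalizer == "features":
        log_norm = math.log(d)
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if log_norm <= 0:
        raise ValueError("entropy normalizer requires more than one row")

    E = np.zeros(d)
    for dp in range(d):
        if colsum[dp] == 0:
            continue
        rho = psi[:, dp] / colsum[dp]
        nz = rho[rho > 0]
        E[dp] = float(-np.sum(nz * np.log(nz)) / log_norm)
    E = np.clip(E, 0.0, 1.0)
    denom = d - E.sum()
    if denom <= 1e-12:
        raise ValueError(
            "degenerate entropies: every channel's information shares are "
            "uniform, weight denominator vanishes"
        )
    w = (1.0 - E) / denom
    return w


@dataclass
class CentroidResult:
    """Weighted centroid of one condition subset."""

    index_k: int
    raw_centroid: np.ndarray
    feature_weights: np.ndarray
    weighted_centroid: np.ndarray


def compute_centroid(
    features: np.ndarray,
    config: Optional[MICConfig] = None,
    drop_constant_channels: bool = False,
) -> CentroidResult:
    """Chain MIC matrix -> reference sample -> entropy weights -> centroid.

    ``features`` is the subset's n_q x d sample matrix (a ConditionDataset's
    ``features`` attribute works directly).  When every sample carries zero
    information against the reference (e.g. an all-identical subset) the
    weights fall back to uniform.  ``drop_constant_channels`` zeroes the
    weight of channels constant across the subset instead of granting them
    the maximal weight the literal entropy formula assigns.
    """
    S = np.atleast_2d(np.asarray(features, dtype=float))
    n_q, d = S.shape
    if n_q < 2:
        raise ValueError("need at least two samples")
    phi = pairwise_mic_matrix(S, config)
    k = select_centroid_index(phi)
    psi = feature_mi_matrix(S, k, config)
    constant = np.array([np.all(S[:, dp] == S[0, dp]) for dp in range(d)])
    psi_used = psi[:, ~constant] if drop_constant_channels else psi
    try:
        if psi_used.size == 0:
            raise ValueError("no varying channels")
        if drop_constant_channels:
            w = np.zeros(d)
            w[~constant] = entropy_weights(psi_used)
        else:
            w = entropy_weights(psi)
    except ValueError:
        # all-zero or perfectly uniform information: no basis to
        # discriminate channels, fall back to uniform weights
        w = np.full(d, 1.0 / d)
    z_star = S[k].copy()
    return CentroidResult(
        index_k=k,
        raw_centroid=z_star,
        feature_weights=w,
        weighted_centroid=w * z_star,
    )
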
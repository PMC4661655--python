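"""Per-indicator separation statistics and the weight-adjustment rules.

The weighted K-means objective scores an indicator weighting w (on the
probability simplex) by the ratio of between-cluster to within-cluster
separation,

    V(w) = (sum_n w_n * b_n) / (sum_n w_n * a_n),

where a_n is the within-cluster separation of indicator n (sum over samples
of squared deviation from their centroid) and b_n its between-cluster
separation.  Two forms of b_n are supported:

* ``original``: size-weighted squared distance of each centroid from the
  global center g,    b_n = sum_k |C_k| (c_kn - g_n)^2;
* ``modified``: size-weighted pairwise squared centroid differences,
  b_n = sum_k sum_{j != k} |C_k| (c_kn - c_jn)^2.

Maximising V over the simplex is a linear-fractional program whose optimum
sits at a corner: all weight on the indicator with the largest b_n/a_n
(winner-take-all).  Because that discards the other indicators entirely, the
weights are instead nudged each iteration toward an adjustment margin dw:

* ``ratio`` margin: dw_n proportional to b_n/(a_n + sigma), with sigma the
  average dispersion of the data guarding against a_n = 0;
* ``difference`` margin: based on delta_n = b_n/sum(b) - a_n/sum(a).  Since
  delta sums to zero by construction, the raw differences cannot be
  normalised by their sum; the margin is the min-shifted simplex projection
  dw_n = (delta_n - min delta) / sum(delta - min delta), which preserves the
  ranking of delta and puts zero on the least separating indicator.

The update then mixes half-and-half: w(s+1) = (w(s) + dw(s)) / 2, which keeps
the weights on the simplex without renormalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SeparationStats",
    "within_separations",
    "between_separations_modified",
    "between_separations_original",
    "normalize_separations",
    "corner_solution",
    "margin_ratio",
    "margin_difference",
    "update_weights",
    "sigma_dispersion",
    "uniform_weights",
    "check_simplex",
]

_SIMPLEX_TOL = 1e-10
_DELTA_TIE_TOL = 1e-12


def uniform_weights(n: int) -> np.ndarray:
    return np.full(n, 1.0 / n)


def check_simplex(w: np.ndarray, tol: float = _SIMPLEX_TOL) -> None:
    w = np.asarray(w, dtype=float)
    if (w < -tol).any() or abs(w.sum() - 1.0) > tol:
        raise ValueError("weights must be nonnegative and sum to 1")


@dataclass
class SeparationStats:
    """Within (a) and between (b) separations with sum-normalised forms.

    ``degenerate`` flags sum(a) == 0 (perfect within-cluster fit) or
    sum(b) == 0 (coincident centroids); callers fall back to a uniform
    margin in that state, and the normalised fields hold uniform vectors.
    """

    a: np.ndarray
    b: np.ndarray
    a0: np.ndarray
    b0: np.ndarray
    delta: np.ndarray
    degenerate: bool = False


def within_separations(
    X: np.ndarray, labels: np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    """a_n = sum_m (x_mn - c_{k(m),n})^2 with k(m) the sample's cluster."""
    X = np.asarray(X, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if X.shape[1] != centroids.shape[1]:
        raise ValueError("X and centroids disagree on indicator count")
    diff = X - centroids[np.asarray(labels, dtype=int)]
    return (diff**2).sum(axis=0)


def between_separations_modified(
    centroids: np.ndarray, sizes: np.ndarray
) -> np.ndarray:
    """b_n = sum_k sum_{j != k} |C_k| (c_kn - c_jn)^2 (pairwise form)."""
    centroids = np.asarray(centroids, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    K = centroids.shape[0]
    if K < 2:
        raise ValueError("pairwise between-cluster separation needs K >= 2")
    if sizes.shape != (K,):
        raise ValueError("sizes must have one entry per cluster")
    # (K,K,N) pairwise squared differences, diagonal is zero anyway
    d2 = (centroids[:, None, :] - centroids[None, :, :]) ** 2
    return np.einsum("k,kjn->n", sizes, d2)


def between_separations_original(
    centroids: np.ndarray, sizes: np.ndarray, g: np.ndarray
) -> np.ndarray:
    """b_n = sum_k |C_k| (c_kn - g_n)^2 (global-center form)."""
    centroids = np.asarray(centroids, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    g = np.asarray(g, dtype=float)
    if centroids.shape[1] != g.shape[0]:
        raise ValueError("centroids and global center disagree on indicators")
    if sizes.shape != (centroids.shape[0],):
        raise ValueError("sizes must have one entry per cluster")
    return np.einsum("k,kn->n", sizes, (centroids - g) ** 2)


def normalize_separations(a: np.ndarray, b: np.ndarray) -> SeparationStats:
    """Sum-normalise a and b to the simplex; delta = b0 - a0 sums to zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have the same length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("separations must be nonnegative")
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        u = uniform_weights(a.size)
        return SeparationStats(a=a, b=b, a0=u, b0=u, delta=np.zeros_like(u),
                               degenerate=True)
    a0 = a / sa
    b0 = b / sb
    return SeparationStats(a=a, b=b, a0=a0, b0=b0, delta=b0 - a0)


def corner_solution(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Winner-take-all optimum: unit weight on argmax b_n/a_n.

    This is the corner-point solution of the linear-fractional weight
    objective; ties break to the lowest index.  Any a_n = 0 makes the ratio
    undefined (use the sigma-guarded ratio margin instead).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a <= 0).any():
        raise ZeroDivisionError("corner solution undefined when some a_n = 0")
    w = np.zeros_like(a)
    w[int(np.argmax(b / a))] = 1.0
    return w


def margin_ratio(
    a: np.ndarray, b: np.ndarray, sigma: float
) -> tuple[np.ndarray, bool]:
    """sigma-guarded ratio margin dw_n ∝ b_n / (a_n + sigma).

    Returns (dw, fallback): ``fallback`` is True when all b_n are zero and a
    uniform margin was substituted.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    denom = a + sigma
    if (denom <= 0).any():
        raise ZeroDivisionError("a_n + sigma must be positive for every n")
    r = b / denom
    s = r.sum()
    if s <= 0:
        return uniform_weights(a.size), True
    return r / s, False


def margin_difference(stats: SeparationStats) -> tuple[np.ndarray, bool]:
    """Difference margin: min-shifted simplex projection of delta = b0 - a0.

    Rank-preserving in delta; the minimal-delta indicator gets weight 0.
    Degenerate stats or an (effectively) constant delta fall back to the
    uniform margin.  Returns (dw, fallback).
    """
    n = stats.delta.size
    if stats.degenerate:
        return uniform_weights(n), True
    delta = stats.delta
    spread = delta.max() - delta.min()
    if spread < _DELTA_TIE_TOL:
        return uniform_weights(n), True
    shifted = delta - delta.min()
    return shifted / shifted.sum(), False


def update_weights(w: np.ndarray, dw: np.ndarray) -> np.ndarray:
    """Half-and-half mix w(s+1) = (w(s) + dw(s)) / 2; stays on the simplex."""
    w = np.asarray(w, dtype=float)
    dw = np.asarray(dw, dtype=float)
    check_simplex(w)
    check_simplex(dw)
    return 0.5 * (w + dw)


def sigma_dispersion(X: np.ndarray) -> float:
    """Average per-indicator dispersion about the global center.

    sigma = (1/N) sum_n (1/M) sum_m (x_mn - g_n)^2, population (1/M) form.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("dispersion needs at least 2 samples")
    return float(X.var(axis=0, ddof=0).mean())
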
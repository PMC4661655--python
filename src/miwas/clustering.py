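"""Iterative weighted K-means with per-iteration indicator-weight adaptation.

Each outer iteration (1) assigns every sample to the cluster minimising the
weighted squared distance sum_n w_n (x_mn - c_kn)^2, (2) recomputes centroids
as member means, and (3) when weight adaptation is on, recomputes the
within/between separation statistics and mixes the current weights
half-and-half with the adjustment margin.  Iteration stops when the
object-cluster membership matrix no longer changes, or at ``max_iter``.

Initial centroids come either from a grade-standards table (each grade's
boundary values pushed through the fitted preprocessing transform — the
domain-informed seeding for water-quality data) or from randomly chosen
samples for generic data.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .io_standards import STANDARDIZED, SampleTable, StandardsTable
from .preprocessing import PreprocessParams
from .weighting import (
    between_separations_modified,
    between_separations_original,
    check_simplex,
    margin_difference,
    margin_ratio,
    normalize_separations,
    sigma_dispersion,
    uniform_weights,
    update_weights,
    within_separations,
)

__all__ = [
    "Centroids",
    "ClusteringConfig",
    "ClusteringResult",
    "IterationRecord",
    "membership_matrix",
    "init_centroids_from_standards",
    "init_centroids_random",
    "assign",
    "update_centroids",
    "miwas_kmeans",
    "iwas_kmeans",
    "kmeans",
]

logger = logging.getLogger("miwas")


@dataclass
class Centroids:
    """K x N centroid matrix in clustering space plus cluster sizes."""

    c: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.c.ndim != 2 or self.sizes.shape != (self.c.shape[0],):
            raise ValueError("centroids must be K x N with K sizes")

    @property
    def k(self) -> int:
        return self.c.shape[0]


@dataclass
class ClusteringConfig:
    """Knobs of the weighted K-means family.

    ``margin`` picks the weight-adjustment rule (``difference`` is the
    modified rule, ``ratio`` the sigma-guarded prior rule, ``none`` disables
    adaptation like ``adapt_weights=False``); ``between`` picks the
    between-cluster separation form.  ``empty_cluster`` chooses whether an
    emptied cluster keeps its previous centroid or is reseeded to the sample
    farthest from its own centroid.
    """

    n_clusters: int = 5
    max_iter: int = 100
    margin: str = "difference"
    between: str = "modified"
    adapt_weights: bool = True
    init_weights: np.ndarray | None = None
    empty_cluster: str = "keep"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.margin not in ("difference", "ratio", "none"):
            raise ValueError(f"unknown margin rule {self.margin!r}")
        if self.between not in ("modified", "original"):
            raise ValueError(f"unknown between form {self.between!r}")
        if self.empty_cluster not in ("keep", "reseed"):
            raise ValueError(f"unknown empty-cluster policy {self.empty_cluster!r}")
        if self.init_weights is not None:
            self.init_weights = np.asarray(self.init_weights, dtype=float)
            check_simplex(self.init_weights)


@dataclass
class IterationRecord:
    """Per-iteration trace entry."""

    iteration: int
    weights: np.ndarray
    weighted_sse: float
    n_changed: int
    margin_fallback: bool = False
    empty_clusters: int = 0


@dataclass
class ClusteringResult:
    labels: np.ndarray
    centroids: Centroids
    weights: np.ndarray
    n_iter: int
    converged: bool
    trace: list[IterationRecord] = field(default_factory=list)


def membership_matrix(labels: np.ndarray, k: int) -> np.ndarray:
    """Binary M x K membership matrix U with u_mk = 1 iff sample m is in k."""
    labels = np.asarray(labels, dtype=int)
    u = np.zeros((labels.size, k), dtype=int)
    u[np.arange(labels.size), labels] = 1
    return u


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SampleTable):
        if X.space != STANDARDIZED:
            raise ValueError("clustering expects a standardized table")
        return X.values
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------


def init_centroids_from_standards(
    standards: StandardsTable,
    params: PreprocessParams,
    table: SampleTable,
) -> Centroids:
    """Seed one centroid per grade from the standards' boundary values.

    Each indicator with a standard contributes its grade-k boundary pushed
    through the fitted log10+z transform; a no-standard indicator (pH style)
    contributes the standardized column mean for every seed.
    """
    X = _as_matrix(table)
    k = standards.n_grades
    col_means = X.mean(axis=0)
    c = np.tile(col_means, (k, 1))
    log_mask = params._log_mask()
    for j, ind in enumerate(table.indicator_names):
        if not standards.has_standard(ind):
            continue
        bounds = standards.boundaries_for(ind).astype(float)
        if log_mask[j]:
            if (bounds <= 0).any():
                raise ValueError(
                    f"{ind}: boundary <= 0 cannot pass the log transform"
                )
            bounds = np.log10(bounds)
        c[:, j] = (bounds - params.mu[j]) / params.sigma[j]
    return Centroids(c=c, sizes=np.zeros(k, dtype=int))


def init_centroids_random(X, k: int, seed: int = 0) -> Centroids:
    """Seed centroids at k distinct samples chosen uniformly at random."""
    X = _as_matrix(X)
    rng = np.random.default_rng(seed)
    idx = rng.choice(X.shape[0], size=k, replace=False)
    return Centroids(c=X[idx].copy(), sizes=np.zeros(k, dtype=int))


# ---------------------------------------------------------------------------
# Lloyd steps
# ---------------------------------------------------------------------------


def assign(X, centroids: Centroids, w: np.ndarray) -> np.ndarray:
    """Each sample joins the cluster minimising sum_n w_n (x_n - c_kn)^2.

    Ties break to the lowest cluster index.
    """
    X = _as_matrix(X)
    w = np.asarray(w, dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(centroids.c).all():
        raise ValueError("non-finite values in assignment")
    # (M,K) weighted squared distances
    d = np.einsum("n,mkn->mk", w, (X[:, None, :] - centroids.c[None, :, :]) ** 2)
    return d.argmin(axis=1)


def update_centroids(
    X,
    labels: np.ndarray,
    prev: Centroids,
    policy: str = "keep",
    w: np.ndarray | None = None,
) -> Centroids:
    """Member means per cluster; empty clusters follow ``policy``.

    ``keep`` retains the previous centroid (size 0); ``reseed`` moves the
    empty centroid to the sample farthest (weighted distance) from its own
    cluster's centroid.
    """
    X = _as_matrix(X)
    labels = np.asarray(labels, dtype=int)
    k = prev.k
    c = np.array(prev.c, copy=True)
    sizes = np.bincount(labels, minlength=k)
    for kk in range(k):
        if sizes[kk] > 0:
            c[kk] = X[labels == kk].mean(axis=0)
    empty = np.nonzero(sizes == 0)[0]
    if empty.size:
        logger.warning("empty cluster(s) %s under policy %r", empty.tolist(), policy)
    if policy == "reseed" and empty.size:
        # move each empty centroid to the sample farthest (weighted distance)
        # from its own cluster's centroid; the next assignment pass claims it
        ww = uniform_weights(X.shape[1]) if w is None else np.asarray(w, float)
        d = np.einsum("n,mn->m", ww, (X - c[labels]) ** 2)
        order = np.argsort(d)[::-1]
        for i, kk in enumerate(empty):
            c[kk] = X[order[i % order.size]]
    return Centroids(c=c, sizes=sizes)


# ---------------------------------------------------------------------------
# Main loops
# ---------------------------------------------------------------------------


def _adjust_weights(
    X: np.ndarray,
    labels: np.ndarray,
    cents: Centroids,
    w: np.ndarray,
    cfg: ClusteringConfig,
    sigma: float,
) -> tuple[np.ndarray, bool]:
    a = within_separations(X, labels, cents.c)
    if cfg.between == "modified":
        b = between_separations_modified(cents.c, cents.sizes)
    else:
        b = between_separations_original(cents.c, cents.sizes, X.mean(axis=0))
    if cfg.margin == "difference":
        dw, fallback = margin_difference(normalize_separations(a, b))
    else:  # ratio
        dw, fallback = margin_ratio(a, b, sigma)
    return update_weights(w, dw), fallback


def miwas_kmeans(X, init: Centroids, cfg: ClusteringConfig) -> ClusteringResult:
    """Weighted K-means with per-iteration indicator-weight self-adjustment.

    Stops when the membership matrix is unchanged between consecutive
    iterations, or at ``cfg.max_iter`` (then ``converged`` is False; this is
    reported, not raised).  The trace records weights, weighted SSE and the
    number of membership changes at every iteration.
    """
    X = _as_matrix(X)
    m, n = X.shape
    if init.k != cfg.n_clusters:
        raise ValueError(
            f"init has {init.k} centroids but config wants {cfg.n_clusters}"
        )
    w = (
        uniform_weights(n)
        if cfg.init_weights is None
        else np.array(cfg.init_weights, dtype=float)
    )
    adapt = cfg.adapt_weights and cfg.margin != "none"
    sigma = sigma_dispersion(X) if (adapt and cfg.margin == "ratio") else 0.0

    cents = Centroids(c=init.c.copy(), sizes=init.sizes.copy())
    prev_labels: np.ndarray | None = None
    labels = np.zeros(m, dtype=int)
    trace: list[IterationRecord] = []
    converged = False
    n_iter = 0

    for s in range(1, cfg.max_iter + 1):
        n_iter = s
        labels = assign(X, cents, w)
        n_changed = m if prev_labels is None else int((labels != prev_labels).sum())
        if prev_labels is not None and n_changed == 0:
            converged = True
            trace.append(
                IterationRecord(
                    iteration=s,
                    weights=w.copy(),
                    weighted_sse=_weighted_sse(X, labels, cents.c, w),
                    n_changed=0,
                )
            )
            break
        prev_labels = labels
        cents = update_centroids(X, labels, cents, policy=cfg.empty_cluster, w=w)
        fallback = False
        if adapt:
            w, fallback = _adjust_weights(X, labels, cents, w, cfg, sigma)
            if fallback:
                logger.info("uniform-margin fallback at iteration %d", s)
        trace.append(
            IterationRecord(
                iteration=s,
                weights=w.copy(),
                weighted_sse=_weighted_sse(X, labels, cents.c, w),
                n_changed=n_changed,
                margin_fallback=fallback,
                empty_clusters=int((cents.sizes == 0).sum()),
            )
        )
    if not converged:
        logger.warning("no convergence within %d iterations", cfg.max_iter)
    return ClusteringResult(
        labels=labels,
        centroids=cents,
        weights=w,
        n_iter=n_iter,
        converged=converged,
        trace=trace,
    )


def _weighted_sse(X, labels, c, w) -> float:
    diff = X - np.asarray(c)[np.asarray(labels, dtype=int)]
    return float(np.einsum("n,mn->", np.asarray(w, float), diff**2))


def iwas_kmeans(X, init: Centroids, cfg: ClusteringConfig | None = None,
                **kwargs) -> ClusteringResult:
    """Prior weight-adjustment variant: sigma-guarded ratio margin against the
    global-center between-cluster separation."""
    base = cfg or ClusteringConfig(**kwargs)
    return miwas_kmeans(
        X,
        init,
        dataclasses.replace(base, margin="ratio", between="original",
                            adapt_weights=True),
    )


def kmeans(X, init: Centroids, cfg: ClusteringConfig | None = None,
           **kwargs) -> ClusteringResult:
    """Equal-weight K-means: the adaptation-free baseline, same loop and
    tie-breaks, weights fixed at the (uniform by default) initial weights."""
    base = cfg or ClusteringConfig(**kwargs)
    return miwas_kmeans(X, init, dataclasses.replace(base, adapt_weights=False))
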
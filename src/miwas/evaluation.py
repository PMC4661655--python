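"""Cluster validity (SSE), algorithm comparison, LOOCV and summary tables.

The validity measure is the weighted within-cluster sum of squared errors

    SSE(U, c, w) = sum_m sum_k sum_n u_mk w_n (x_mn - c_kn)^2,

which equals dot(w, a) with a the per-indicator within-cluster separations;
lower is better.  Leave-one-out cross-validation re-assigns each held-out
sample and tabulates agreement with the full-data cluster labels as a row-
percentage confusion matrix.  Summary tables (per-cluster means, site
crosstabs) are computed in original measurement units even though clustering
runs in standardized space; labels travel back by row index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clustering import Centroids, ClusteringConfig, ClusteringResult, miwas_kmeans
from .io_standards import SampleTable
from .weighting import uniform_weights, within_separations

__all__ = [
    "ConfusionMatrix",
    "ComparisonReport",
    "sse",
    "compare_algorithms",
    "loocv",
    "cluster_summary",
    "crosstab",
]


@dataclass
class ConfusionMatrix:
    """K x K row-percentage matrix: reference cluster x held-out assignment.

    Rows of populated reference clusters sum to 100 (up to rounding); rows of
    empty reference clusters are NaN.  ``skipped`` counts folds that could
    not be evaluated (e.g. a singleton cluster in centroid mode).
    """

    percent: np.ndarray
    counts: np.ndarray
    skipped: int = 0

    def diagonal(self) -> np.ndarray:
        return np.diag(self.percent)

    def to_frame(self) -> pd.DataFrame:
        k = self.percent.shape[0]
        labels = [str(i + 1) for i in range(k)]
        return pd.DataFrame(self.percent, index=labels, columns=labels)


@dataclass
class ComparisonReport:
    """Per-algorithm metrics from a shared initialisation."""

    rows: pd.DataFrame
    results: dict[str, ClusteringResult]
    errors: dict[str, str]


def sse(X, labels: np.ndarray, centroids: np.ndarray, w: np.ndarray) -> float:
    """Weighted within-cluster sum of squared errors (= dot(w, a))."""
    a = within_separations(np.asarray(X, dtype=float), labels, np.asarray(centroids))
    return float(np.dot(np.asarray(w, dtype=float), a))


def compare_algorithms(
    X,
    init: Centroids,
    configs: dict[str, ClusteringConfig],
    runner=miwas_kmeans,
) -> ComparisonReport:
    """Run each configured algorithm from the identical init and report both
    the weighted SSE (each algorithm's own final weights) and the equal-weight
    SSE, so the comparison is apples-to-apples.  Lower SSE is better."""
    X = np.asarray(X, dtype=float) if not isinstance(X, SampleTable) else X.values
    rows = []
    results: dict[str, ClusteringResult] = {}
    errors: dict[str, str] = {}
    n = X.shape[1]
    for name, cfg in configs.items():
        try:
            res = runner(X, Centroids(init.c.copy(), init.sizes.copy()), cfg)
        except Exception as exc:  # partial report with error markers
            errors[name] = f"{type(exc).__name__}: {exc}"
            rows.append({"algorithm": name, "error": errors[name]})
            continue
        results[name] = res
        rows.append(
            {
                "algorithm": name,
                "weighted_sse": sse(X, res.labels, res.centroids.c, res.weights),
                "equal_weight_sse": sse(
                    X, res.labels, res.centroids.c, uniform_weights(n)
                ),
                "n_iter": res.n_iter,
                "converged": res.converged,
                "weights": tuple(np.round(res.weights, 6)),
            }
        )
    return ComparisonReport(rows=pd.DataFrame(rows), results=results, errors=errors)


def _match_clusters(fold_c: np.ndarray, ref_c: np.ndarray) -> np.ndarray:
    """Map fold cluster index -> reference cluster index by nearest-centroid
    pairing (Hungarian assignment on squared centroid distances)."""
    d = ((fold_c[:, None, :] - ref_c[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(d)
    mapping = np.empty(fold_c.shape[0], dtype=int)
    mapping[rows] = cols
    return mapping


def loocv(
    X,
    init: Centroids,
    cfg: ClusteringConfig,
    mode: str = "refit",
) -> ConfusionMatrix:
    """Leave-one-out verification of a clustering against itself.

    Reference labels come from clustering the full data.  For each held-out
    sample: ``refit`` mode reclusters the remaining M-1 samples from the same
    init, matches fold clusters to reference clusters by nearest-centroid
    Hungarian pairing, and assigns the held-out sample to the nearest fold
    centroid under the fold's weights; ``centroid`` mode (fast) assigns it to
    the nearest reference centroid recomputed without the sample.  Tabulated
    as row percentages of the reference labels.
    """
    X = np.asarray(X, dtype=float) if not isinstance(X, SampleTable) else X.values
    m = X.shape[0]
    k = cfg.n_clusters
    if m < k + 1:
        raise ValueError("LOOCV needs at least K+1 samples")
    if mode not in ("refit", "centroid"):
        raise ValueError(f"unknown LOOCV mode {mode!r}")

    ref = miwas_kmeans(X, Centroids(init.c.copy(), init.sizes.copy()), cfg)
    counts = np.zeros((k, k), dtype=int)
    skipped = 0

    if mode == "centroid":
        sizes = ref.centroids.sizes.astype(float)
        for i in range(m):
            ki = int(ref.labels[i])
            if sizes[ki] <= 1:
                skipped += 1
                continue
            c = np.array(ref.centroids.c, copy=True)
            c[ki] = (c[ki] * sizes[ki] - X[i]) / (sizes[ki] - 1)
            d = np.einsum("n,kn->k", ref.weights, (X[i] - c) ** 2)
            counts[ki, int(d.argmin())] += 1
    else:
        idx = np.arange(m)
        for i in range(m):
            rest = idx != i
            fold = miwas_kmeans(
                X[rest], Centroids(init.c.copy(), init.sizes.copy()), cfg
            )
            populated = fold.centroids.sizes > 0
            if populated.sum() < 1:
                skipped += 1
                continue
            mapping = _match_clusters(fold.centroids.c, ref.centroids.c)
            d = np.einsum(
                "n,kn->k", fold.weights, (X[i] - fold.centroids.c) ** 2
            )
            d[~populated] = np.inf
            counts[int(ref.labels[i]), int(mapping[int(d.argmin())])] += 1

    row_sums = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(row_sums > 0, 100.0 * counts / row_sums, np.nan)
    return ConfusionMatrix(percent=percent, counts=counts, skipped=skipped)


def cluster_summary(table: SampleTable, labels: np.ndarray, k: int | None = None
                    ) -> pd.DataFrame:
    """Per-cluster mean ± SD per indicator plus counts, in original units.

    SD uses n-1; a singleton cluster reports SD 0 with ``sd_flag`` set; an
    empty cluster reports count 0 and absent (NaN) means.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != table.n_samples:
        raise ValueError("labels must have one entry per row")
    k = int(labels.max()) + 1 if k is None else k
    rows = []
    for kk in range(k):
        mask = labels == kk
        cnt = int(mask.sum())
        row: dict = {"cluster": kk + 1, "count": cnt, "sd_flag": cnt == 1}
        for j, name in enumerate(table.indicator_names):
            vals = table.values[mask, j]
            if cnt == 0:
                row[f"{name}_mean"] = np.nan
                row[f"{name}_sd"] = np.nan
            else:
                row[f"{name}_mean"] = float(vals.mean())
                row[f"{name}_sd"] = float(vals.std(ddof=1)) if cnt > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def crosstab(labels: np.ndarray, groups: np.ndarray, k: int | None = None
             ) -> pd.DataFrame:
    """Site x cluster count matrix with a leading per-site Sum column."""
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups, dtype=object)
    if labels.shape != groups.shape:
        raise ValueError("labels and groups must have equal length")
    k = int(labels.max()) + 1 if k is None else k
    ct = pd.crosstab(pd.Series(groups, name="site"),
                     pd.Series(labels + 1, name="cluster"))
    ct = ct.reindex(columns=range(1, k + 1), fill_value=0)
    ct.columns = [f"Cl.{c}" for c in range(1, k + 1)]
    ct.insert(0, "Sum", ct.sum(axis=1))
    return ct
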
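"""Cleaning and transformation chain for monitoring tables.

The chain is: drop rows with missing cells, screen outliers by per-column
z-score (|z| > 3 by default), log10-transform all indicators (concentration
data are right-skewed; the log brings them near normal), then z-scale
standardize so clustering distances are dimensionless.  Skewness/kurtosis
diagnostics are advisory, not gating.

The fitted standardization parameters are kept so that any vector in original
units — notably grade-standard boundary values — can be pushed through the
identical transform into the clustering space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_standards import (
    LOG10,
    RAW,
    STANDARDIZED,
    EmptyInputError,
    SampleTable,
)

__all__ = [
    "PreprocessParams",
    "ShapeDiagnostics",
    "DegenerateColumnError",
    "drop_missing",
    "outlier_screen",
    "log10_transform",
    "standardize",
    "shape_diagnostics",
    "preprocess",
]


class DegenerateColumnError(ValueError):
    """A column has zero spread where positive spread is required."""


@dataclass
class PreprocessParams:
    """Fitted per-indicator location/scale of the standardization step.

    ``mu``/``sigma`` live in post-log space when ``log_applied`` is true.
    ``exempt_log`` lists indicators excluded from the log transform.
    The params transform any vector in original units into clustering space
    and back; sample (n-1) standard deviations throughout.
    """

    indicator_names: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    log_applied: bool = True
    exempt_log: frozenset[str] = frozenset()
    outlier_threshold: float = 3.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if (self.sigma <= 0).any():
            raise DegenerateColumnError("sigma must be positive for every indicator")

    def _log_mask(self) -> np.ndarray:
        return np.array(
            [self.log_applied and n not in self.exempt_log for n in self.indicator_names]
        )

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Original units -> clustering space (log10 where applicable, then z)."""
        v = np.array(values, dtype=float, copy=True)
        mask = self._log_mask()
        if mask.any():
            cols = v[..., mask]
            if (cols <= 0).any():
                raise ValueError("log10 transform requires strictly positive values")
            v[..., mask] = np.log10(cols)
        return (v - self.mu) / self.sigma

    def inverse(self, values: np.ndarray) -> np.ndarray:
        """Clustering space -> original units."""
        v = np.asarray(values, dtype=float) * self.sigma + self.mu
        mask = self._log_mask()
        v = np.array(v, copy=True)
        v[..., mask] = 10.0 ** v[..., mask]
        return v

    def inverse_to_log(self, values: np.ndarray) -> np.ndarray:
        """Undo only the z-scale step (clustering space -> log space)."""
        return np.asarray(values, dtype=float) * self.sigma + self.mu


@dataclass
class ShapeDiagnostics:
    """Per-indicator moment skewness and excess kurtosis (dimensionless)."""

    indicator_names: list[str]
    skewness: np.ndarray
    kurtosis: np.ndarray


def drop_missing(table: SampleTable) -> tuple[SampleTable, int]:
    """Remove every row containing at least one missing cell."""
    if table.space != RAW:
        raise ValueError("drop_missing operates on raw-space tables")
    keep = ~np.isnan(table.values).any(axis=1)
    if not keep.any():
        raise EmptyInputError("every row has a missing cell")
    return table.take_rows(keep), int((~keep).sum())


def _column_sd(values: np.ndarray) -> np.ndarray:
    return values.std(axis=0, ddof=1)


def outlier_screen(
    table: SampleTable, threshold: float = 3.0
) -> tuple[SampleTable, int]:
    """Remove rows with any per-column |z-score| above ``threshold``.

    z-scores are computed once from the full input (single pass, no
    re-screening after removal), using sample (n-1) standard deviations.
    """
    if np.isnan(table.values).any():
        raise ValueError("outlier_screen requires a table with no missing cells")
    mu = table.values.mean(axis=0)
    sd = _column_sd(table.values)
    bad = sd <= 0
    if bad.any():
        names = [n for n, b in zip(table.indicator_names, bad) if b]
        raise DegenerateColumnError(f"constant column(s): {', '.join(names)}")
    z = (table.values - mu) / sd
    keep = (np.abs(z) <= threshold).all(axis=1)
    if not keep.any():
        raise EmptyInputError("outlier screen removed every row")
    return table.take_rows(keep), int((~keep).sum())


def log10_transform(
    table: SampleTable, exempt: frozenset[str] | set[str] = frozenset()
) -> SampleTable:
    """Elementwise log10 of every non-exempt indicator column."""
    mask = np.array([n not in exempt for n in table.indicator_names])
    offending = (table.values[:, mask] <= 0) | np.isnan(table.values[:, mask])
    if offending.any():
        rows = sorted(set(np.nonzero(offending)[0].tolist()))
        raise ValueError(
            f"log10 requires strictly positive values; offending rows: {rows[:20]}"
        )
    out = np.array(table.values, copy=True)
    out[:, mask] = np.log10(out[:, mask])
    return table.with_values(out, LOG10)


def standardize(
    table: SampleTable,
    log_applied: bool = True,
    exempt_log: frozenset[str] | set[str] = frozenset(),
    outlier_threshold: float = 3.0,
) -> tuple[SampleTable, PreprocessParams]:
    """z-scale each column to sample mean 0 and sample SD 1.

    Returns the fitted :class:`PreprocessParams`; the ``log_applied`` /
    ``exempt_log`` flags record the provenance of the incoming table so the
    params can replay the full original-units -> clustering-space transform.
    """
    mu = table.values.mean(axis=0)
    sd = _column_sd(table.values)
    bad = sd <= 0
    if bad.any():
        names = [n for n, b in zip(table.indicator_names, bad) if b]
        raise DegenerateColumnError(f"constant column(s): {', '.join(names)}")
    params = PreprocessParams(
        indicator_names=list(table.indicator_names),
        mu=mu,
        sigma=sd,
        log_applied=log_applied,
        exempt_log=frozenset(exempt_log),
        outlier_threshold=outlier_threshold,
    )
    return table.with_values((table.values - mu) / sd, STANDARDIZED), params


def shape_diagnostics(table: SampleTable) -> ShapeDiagnostics:
    """Moment skewness b1 = m3/m2^1.5 and excess kurtosis m4/m2^2 - 3."""
    if table.n_samples < 4:
        raise ValueError("shape diagnostics need at least 4 samples")
    sd = _column_sd(table.values)
    if (sd <= 0).any():
        raise DegenerateColumnError("constant column in shape diagnostics")
    return ShapeDiagnostics(
        indicator_names=list(table.indicator_names),
        skewness=stats.skew(table.values, axis=0, bias=True),
        kurtosis=stats.kurtosis(table.values, axis=0, fisher=True, bias=True),
    )


def preprocess(
    table: SampleTable,
    outlier_threshold: float = 3.0,
    log: bool = True,
    exempt_log: frozenset[str] | set[str] = frozenset(),
    screen_space: str = "raw",
) -> tuple[SampleTable, PreprocessParams, dict]:
    """Run the full cleaning chain and return (table, params, stage report).

    Default order: drop_missing -> outlier_screen (raw space) -> log10 ->
    standardize.  ``screen_space="log"`` instead screens after the log
    transform, for data whose raw-scale skew would dominate the z-scores.
    """
    report: dict = {"rows_in": table.n_samples}
    kept = np.arange(table.n_samples)  # indices into the input table
    miss = ~np.isnan(table.values).any(axis=1)
    table, n_missing = drop_missing(table)
    kept = kept[miss]
    report["removed_missing"] = n_missing
    if screen_space not in ("raw", "log"):
        raise ValueError("screen_space must be 'raw' or 'log'")

    def _screen(t):
        mu = t.values.mean(axis=0)
        sd = _column_sd(t.values)
        t2, n_out = outlier_screen(t, outlier_threshold)
        ok = (np.abs((t.values - mu) / sd) <= outlier_threshold).all(axis=1)
        return t2, n_out, ok

    if screen_space == "raw":
        table, n_out, ok = _screen(table)
        kept = kept[ok]
        report["removed_outliers"] = n_out
    if log:
        table = log10_transform(table, exempt=exempt_log)
    if screen_space == "log":
        table, n_out, ok = _screen(table)
        kept = kept[ok]
        report["removed_outliers"] = n_out
    table, params = standardize(
        table,
        log_applied=log,
        exempt_log=exempt_log,
        outlier_threshold=outlier_threshold,
    )
    report["rows_out"] = table.n_samples
    report["kept_row_indices"] = kept
    return table, params, report
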
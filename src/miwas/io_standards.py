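"""Tabular data model, CSV I/O and grade-standards semantics.

Monitoring data are an M x N matrix of indicator measurements (one row per
sample, one column per indicator such as pH, DO, COD, NH3-N), optionally
carrying a site label and sampling date per row.  Grade standards (GB3838-2002
style) give, per indicator, the boundary value of each quality grade together
with a direction of degradation: concentrations like COD get worse as they
rise, dissolved oxygen gets worse as it falls.  The standards drive both the
removal of beyond-scale samples and the standards-based centroid
initialisation used by the clustering stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RAW",
    "LOG10",
    "STANDARDIZED",
    "BEYOND_SCALE",
    "HIGHER_IS_WORSE",
    "LOWER_IS_WORSE",
    "SampleTable",
    "StandardsTable",
    "SchemaError",
    "EmptyInputError",
    "gb3838_standards",
    "read_samples",
    "write_samples",
    "read_standards",
    "global_center",
    "grade_filter",
    "grade_of_sample",
    "grades_of_table",
]

# Transform-state tags: values move raw -> log10 -> standardized, never back.
RAW = "raw"
LOG10 = "log10"
STANDARDIZED = "standardized"
_SPACES = (RAW, LOG10, STANDARDIZED)

#: Sentinel grade for a value beyond the worst boundary of the standard.
BEYOND_SCALE = "beyond-scale"

HIGHER_IS_WORSE = "higher_is_worse"
LOWER_IS_WORSE = "lower_is_worse"


class SchemaError(ValueError):
    """A declared column is absent or a table/standard mismatch was found."""


class EmptyInputError(ValueError):
    """An operation would leave (or received) a table with zero rows."""


@dataclass
class SampleTable:
    """M x N matrix of indicator values with optional per-row metadata.

    ``values`` uses NaN as the missing-value marker; missing cells are only
    legal in the raw state, before cleaning.  ``space`` records which
    transform state the values are in (see module docstring).
    """

    values: np.ndarray
    indicator_names: list[str]
    site: np.ndarray | None = None
    date: np.ndarray | None = None
    space: str = RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1:
            raise EmptyInputError("a sample table needs at least one row")
        if n < 2:
            raise ValueError("a sample table needs at least two indicators")
        self.indicator_names = [str(s) for s in self.indicator_names]
        if len(self.indicator_names) != n:
            raise ValueError("indicator_names length must match column count")
        if len(set(self.indicator_names)) != n or any(
            not s for s in self.indicator_names
        ):
            raise ValueError("indicator names must be unique and non-empty")
        if self.space not in _SPACES:
            raise ValueError(f"unknown space tag {self.space!r}")
        if self.space != RAW and np.isnan(self.values).any():
            raise ValueError("missing values are only permitted in raw space")
        for attr in ("site", "date"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=object)
                if v.shape != (m,):
                    raise ValueError(f"{attr} must have one entry per row")
                setattr(self, attr, v)

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.indicator_names.index(name)]

    def take_rows(self, mask_or_index: np.ndarray) -> "SampleTable":
        """Row subset preserving order; metadata travels with the rows."""
        return dataclasses.replace(
            self,
            values=self.values[mask_or_index],
            site=None if self.site is None else self.site[mask_or_index],
            date=None if self.date is None else self.date[mask_or_index],
        )

    def with_values(self, values: np.ndarray, space: str) -> "SampleTable":
        order = {s: i for i, s in enumerate(_SPACES)}
        if order[space] < order[self.space]:
            raise ValueError(
                f"illegal transform-state transition {self.space} -> {space}"
            )
        return dataclasses.replace(self, values=values, space=space)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.indicator_names)
        if self.site is not None:
            df.insert(0, "site", self.site)
        if self.date is not None:
            df.insert(1 if self.site is not None else 0, "date", self.date)
        return df


@dataclass
class StandardsTable:
    """Per-indicator, per-grade boundary values with degradation direction.

    ``boundary[i, g]`` is the boundary of grade ``grades[g]`` for
    ``indicators[i]``; a value exactly equal to a boundary belongs to that
    grade (GB-style standards state boundaries as the limit of the grade).
    Indicators with no standard (pH style) are listed in ``no_standard`` and
    never participate in filtering.
    """

    indicators: list[str]
    grades: list[str]
    boundary: np.ndarray
    direction: dict[str, str]
    no_standard: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.shape != (len(self.indicators), len(self.grades)):
            raise ValueError("boundary must be indicators x grades")
        for i, ind in enumerate(self.indicators):
            d = self.direction.get(ind)
            if d not in (HIGHER_IS_WORSE, LOWER_IS_WORSE):
                raise ValueError(f"indicator {ind!r} needs a direction flag")
            diffs = np.diff(self.boundary[i])
            ok = (diffs > 0).all() if d == HIGHER_IS_WORSE else (diffs < 0).all()
            if not ok:
                raise ValueError(
                    f"boundaries for {ind!r} must be strictly monotone along"
                    " the grade order in the direction of degradation"
                )

    @property
    def n_grades(self) -> int:
        return len(self.grades)

    def has_standard(self, indicator: str) -> bool:
        return indicator in self.indicators

    def check_covers(self, table: SampleTable) -> None:
        """Every table indicator must have a standard or be flagged no-standard."""
        for ind in table.indicator_names:
            if not self.has_standard(ind) and ind not in self.no_standard:
                raise SchemaError(
                    f"indicator {ind!r} has no grade standard and is not"
                    " flagged as no-standard"
                )

    def boundaries_for(self, indicator: str) -> np.ndarray:
        return self.boundary[self.indicators.index(indicator)]


def gb3838_standards() -> StandardsTable:
    """GB3838-2002 surface-water boundaries for DO, COD and NH3-N.

    pH has no per-grade boundary in the standard's grades I-V and is flagged
    no-standard.  DO degrades downwards; COD and NH3-N degrade upwards.
    """
    return StandardsTable(
        indicators=["DO", "COD", "NH3-N"],
        grades=["I", "II", "III", "IV", "V"],
        boundary=np.array(
            [
                [7.5, 6.0, 5.0, 3.0, 2.0],
                [2.0, 4.0, 6.0, 10.0, 15.0],
                [0.15, 0.5, 1.0, 1.5, 2.0],
            ]
        ),
        direction={
            "DO": LOWER_IS_WORSE,
            "COD": HIGHER_IS_WORSE,
            "NH3-N": HIGHER_IS_WORSE,
        },
        no_standard={"pH"},
    )


# ---------------------------------------------------------------------------
# CSV I/O.  Dialect: comma-separated, UTF-8, header row required, "." decimal
# mark, empty cell or "NA" = missing.  Row order is never changed by any I/O
# op, so row indices are stable identifiers across the pipeline.
# ---------------------------------------------------------------------------


def read_samples(
    path,
    indicators: list[str] | None = None,
    site_col: str | None = None,
    date_col: str | None = None,
) -> SampleTable:
    """Read a monitoring CSV into a raw-space :class:`SampleTable`.

    ``indicators`` selects the indicator columns (default: every column not
    claimed as site/date).  Unparseable or empty numeric cells become NaN for
    the preprocessing stage to handle; extra columns are ignored.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")
    if indicators is None:
        indicators = [c for c in df.columns if c not in (site_col, date_col)]
    for col in list(indicators) + [c for c in (site_col, date_col) if c]:
        if col not in df.columns:
            raise SchemaError(f"{path}: declared column {col!r} not in header")
    values = np.column_stack(
        [pd.to_numeric(df[c], errors="coerce").to_numpy() for c in indicators]
    )
    return SampleTable(
        values=values,
        indicator_names=list(indicators),
        site=df[site_col].to_numpy(dtype=object) if site_col else None,
        date=df[date_col].astype(str).to_numpy(dtype=object) if date_col else None,
    )


def write_samples(
    table: SampleTable,
    path,
    labels: np.ndarray | None = None,
    grades: list[str] | None = None,
) -> None:
    """Write a table (optionally with cluster/grade columns) as CSV."""
    df = table.to_frame()
    if labels is not None:
        df["cluster"] = np.asarray(labels) + 1  # 1-based for reporting
    if grades is not None:
        df["grade"] = grades
    df.to_csv(path, index=False, float_format="%.12g")


def read_standards(path) -> StandardsTable:
    """Read a standards CSV: columns ``indicator, direction, <grade>...``.

    A row with direction ``none`` marks a no-standard indicator (its grade
    cells are ignored).
    """
    df = pd.read_csv(path)
    need = {"indicator", "direction"}
    if not need.issubset(df.columns):
        raise SchemaError(f"{path}: standards CSV needs columns {sorted(need)}")
    grade_cols = [c for c in df.columns if c not in need]
    with_std = df[df["direction"] != "none"]
    return StandardsTable(
        indicators=with_std["indicator"].tolist(),
        grades=grade_cols,
        boundary=with_std[grade_cols].to_numpy(dtype=float),
        direction=dict(zip(with_std["indicator"], with_std["direction"])),
        no_standard=set(df.loc[df["direction"] == "none", "indicator"]),
    )


# ---------------------------------------------------------------------------
# Grade semantics
# ---------------------------------------------------------------------------


def global_center(table: SampleTable) -> np.ndarray:
    """Per-indicator mean over all samples (the global center g)."""
    return table.values.mean(axis=0)


def grade_filter(
    table: SampleTable, standards: StandardsTable, worst_grade: str = "V"
) -> tuple[SampleTable, int]:
    """Remove rows with any indicator beyond the worst-grade boundary.

    A value exactly on the boundary belongs to that grade and is kept.
    Indicators flagged no-standard never trigger removal; rows with missing
    values are not judged here.
    """
    if table.space != RAW:
        raise ValueError("grade_filter operates on raw-space values")
    if worst_grade not in standards.grades:
        raise ValueError(f"unknown grade {worst_grade!r}")
    standards.check_covers(table)
    gi = standards.grades.index(worst_grade)
    beyond = np.zeros(table.n_samples, dtype=bool)
    for j, ind in enumerate(table.indicator_names):
        if not standards.has_standard(ind):
            continue
        bound = standards.boundaries_for(ind)[gi]
        col = table.values[:, j]
        if standards.direction[ind] == HIGHER_IS_WORSE:
            beyond |= col > bound
        else:
            beyond |= col < bound
    kept = table.take_rows(~beyond)
    if kept.values.shape[0] == 0:
        raise EmptyInputError("grade filter removed every row")
    return kept, int(beyond.sum())


def grade_of_sample(
    values: np.ndarray, indicator_names: list[str], standards: StandardsTable
) -> str:
    """Grade of one complete sample: the worst per-indicator grade.

    Per indicator with a standard, the grade is the first whose boundary is
    not exceeded in the direction of degradation (boundary values inclusive).
    A value beyond the worst boundary yields the ``beyond-scale`` sentinel.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("grade_of_sample requires a complete sample")
    worst = -1
    for j, ind in enumerate(indicator_names):
        if not standards.has_standard(ind):
            continue
        bounds = standards.boundaries_for(ind)
        if standards.direction[ind] == HIGHER_IS_WORSE:
            within = values[j] <= bounds
        else:
            within = values[j] >= bounds
        if not within.any():
            return BEYOND_SCALE
        worst = max(worst, int(np.argmax(within)))
    if worst < 0:
        raise SchemaError("no indicator in the sample has a grade standard")
    return standards.grades[worst]


def grades_of_table(table: SampleTable, standards: StandardsTable) -> list[str]:
    """Vector of :func:`grade_of_sample` over a (complete) table."""
    return [
        grade_of_sample(row, table.indicator_names, standards)
        for row in table.values
    ]
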
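"""Core data model: variable declarations, per-cohort summaries, snapshots.

A flow is a sequence of cohort snapshots connected by exclusion steps.
Each snapshot carries descriptive statistics for every tracked variable:
mean/SD for normally distributed continuous variables, median/IQR for
non-normal ones, and category counts/proportions (with missingness as an
explicit category) for categorical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, SchemaError

MISSING_LABEL_DEFAULT = "Missing"


class VarType(str, Enum):
    """Declared statistical type of a tracked variable."""

    CATEGORICAL = "categorical"
    CONTINUOUS_NORMAL = "continuous_normal"
    CONTINUOUS_NONNORMAL = "continuous_nonnormal"

    @property
    def is_continuous(self) -> bool:
        return self is not VarType.CATEGORICAL


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one tracked variable.

    Parameters
    ----------
    name : str
        Column name in the participant table.
    var_type : VarType
        One of categorical / continuous_normal / continuous_nonnormal.
    display_order : int, optional
        Rank of the variable among all tracked variables in outputs.
    class_order : tuple of str, optional
        Explicit display order of category labels (categorical only).
    category_limit : int, optional
        Maximum number of categories displayed before the remainder is
        pooled into an "Other" group. Display-only: drift statistics
        always use the full category set.
    """

    name: str
    var_type: VarType
    display_order: int | None = None
    class_order: tuple[str, ...] | None = None
    category_limit: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.var_type, VarType):
            try:
                object.__setattr__(self, "var_type", VarType(self.var_type))
            except ValueError:
                valid = ", ".join(v.value for v in VarType)
                raise ConfigurationError(
                    f"invalid var_type {self.var_type!r} for variable "
                    f"{self.name!r}; expected one of: {valid}"
                ) from None
        if self.class_order is not None:
            co = tuple(self.class_order)
            if len(set(co)) != len(co):
                raise ConfigurationError(
                    f"class_order for {self.name!r} contains duplicate labels"
                )
            object.__setattr__(self, "class_order", co)
        if self.category_limit is not None and self.category_limit < 1:
            raise ConfigurationError(
                f"category_limit for {self.name!r} must be >= 1, "
                f"got {self.category_limit}"
            )


def make_variable_spec(
    name: str,
    var_type: str | VarType,
    display_order: int | None = None,
    class_order: Sequence[str] | None = None,
    category_limit: int | None = None,
) -> VariableSpec:
    """Construct an immutable :class:`VariableSpec`, validating the type."""
    return VariableSpec(
        name=name,
        var_type=var_type,  # coerced/validated in __post_init__
        display_order=display_order,
        class_order=tuple(class_order) if class_order is not None else None,
        category_limit=category_limit,
    )


@dataclass(frozen=True)
class SummaryStat:
    """Descriptive summary of one variable in one cohort.

    Exactly one of the three blocks is populated, depending on the
    declared type. Categorical proportions are computed against the
    total cohort size ``n`` so that the missingness category competes
    for probability mass with the observed levels and all proportions
    sum to one.
    """

    var_type: VarType
    n: int
    n_nonmissing: int
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    categories: tuple[tuple[str, int, float], ...] | None = None

    def proportions(self) -> dict[str, float]:
        """Category label -> proportion map (categorical summaries only)."""
        if self.categories is None:
            raise ValueError("proportions() requires a categorical summary")
        return {label: p for label, _, p in self.categories}

    def counts(self) -> dict[str, int]:
        if self.categories is None:
            raise ValueError("counts() requires a categorical summary")
        return {label: c for label, c, _ in self.categories}


@dataclass(frozen=True)
class ExclusionRecord:
    """One exclusion step: its reason and the participant bookkeeping."""

    reason: str
    n_before: int
    n_removed: int
    n_after: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.reason:
            raise ConfigurationError("an exclusion step requires a reason")
        if min(self.n_before, self.n_removed, self.n_after) < 0:
            raise ConfigurationError("exclusion counts must be non-negative")
        if self.n_before != self.n_removed + self.n_after:
            raise ConfigurationError(
                f"exclusion conservation violated: {self.n_before} != "
                f"{self.n_removed} + {self.n_after}"
            )


@dataclass
class CohortSnapshot:
    """State of the cohort after ``step_index`` exclusions."""

    label: str
    step_index: int
    table: pd.DataFrame
    summaries: dict[str, SummaryStat] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.table)


def _continuous_values(series: pd.Series, name: str) -> np.ndarray:
    """Non-missing values of a continuous column as floats.

    Raises DataError if any non-missing cell is not numeric.
    """
    nonmiss = series.dropna()
    try:
        values = pd.to_numeric(nonmiss)
    except (ValueError, TypeError):
        bad = [v for v in nonmiss if not isinstance(v, (int, float, np.number))]
        raise DataError(
            f"continuous column {name!r} contains non-numeric values, "
            f"e.g. {bad[0]!r}" if bad else
            f"continuous column {name!r} contains non-numeric values"
        ) from None
    return values.to_numpy(dtype=float)


def summarize_variable(
    table: pd.DataFrame,
    spec: VariableSpec,
    missing_label: str = MISSING_LABEL_DEFAULT,
) -> SummaryStat:
    """Summarize one column of ``table`` according to its declared type.

    Continuous summaries use non-missing values only (sample SD with the
    n-1 denominator; quartiles by linear interpolation). Categorical
    summaries list every observed level plus a missingness category,
    with proportions over the total row count.
    """
    if spec.name not in table.columns:
        raise SchemaError(f"column {spec.name!r} not found in table")
    col = table[spec.name]
    n = len(col)
    n_nonmissing = int(col.notna().sum())

    if spec.var_type is VarType.CATEGORICAL:
        nonmiss = col.dropna().astype(str)
        counts = nonmiss.value_counts()
        # deterministic order: frequency desc, label asc on ties
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
        cats: list[tuple[str, int, float]] = []
        for label, count in ordered:
            cats.append((str(label), int(count), (count / n) if n else 0.0))
        n_missing = n - n_nonmissing
        if n_missing or not cats:
            cats.append(
                (missing_label, n_missing, (n_missing / n) if n else 1.0)
            )
        return SummaryStat(
            var_type=spec.var_type, n=n, n_nonmissing=n_nonmissing,
            categories=tuple(cats),
        )

    values = _continuous_values(col, spec.name)
    if values.size == 0:
        return SummaryStat(var_type=spec.var_type, n=n, n_nonmissing=0)
    if spec.var_type is VarType.CONTINUOUS_NORMAL:
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        return SummaryStat(
            var_type=spec.var_type, n=n, n_nonmissing=n_nonmissing,
            mean=float(np.mean(values)), sd=sd,
        )
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    # mean/SD retained even for non-normal variables: the standardized
    # difference has a single continuous form based on them
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return SummaryStat(
        var_type=spec.var_type, n=n, n_nonmissing=n_nonmissing,
        median=float(med), q1=float(q1), q3=float(q3),
        mean=float(np.mean(values)), sd=sd,
    )


def ordered_specs(specs: Sequence[VariableSpec]) -> list[VariableSpec]:
    """Specs sorted by display_order (declared order breaks ties / fills gaps)."""
    indexed = list(enumerate(specs))
    return [
        s for _, s in sorted(
            indexed,
            key=lambda t: (t[1].display_order is None,
                           t[1].display_order if t[1].display_order is not None else 0,
                           t[0]),
        )
    ]
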
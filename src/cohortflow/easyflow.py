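"""Simplified interface with automatic variable-type detection.

The full-control interface requires the user to declare every tracked
variable's type. For rapid use, :func:`easy_flow` infers types from the
data: non-numeric columns are categorical, numeric columns with few
distinct values are categorical, and the remaining continuous columns
are split into normal / non-normal by a sample-skewness heuristic.
The wrapper adds no computation of its own — feeding the detected
specs to the full interface yields identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .errors import DetectionError
from .flow import FlowOptions, FlowState, add_exclusion, init_flow
from .missing import MissingPolicy, standardize_missing
from .model import VariableSpec, VarType, make_variable_spec


@dataclass(frozen=True)
class TypeDetectionRule:
    """Heuristics for automatic type detection.

    max_levels_categorical
        Numeric columns with at most this many distinct non-missing
        values are treated as categorical (so {0, 1} indicators get the
        binary SMD). Default 10.
    normality_rule
        "skewness_threshold" (default) classifies a continuous column
        as normally distributed when |sample skewness| <= skew_cutoff;
        "always_nonnormal" never assumes normality.
    skew_cutoff
        Absolute skewness bound for the normal classification. Default 1.0.
    """

    max_levels_categorical: int = 10
    normality_rule: str = "skewness_threshold"
    skew_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.max_levels_categorical < 2:
            raise ValueError("max_levels_categorical must be >= 2")
        if self.normality_rule not in {"always_nonnormal", "skewness_threshold"}:
            raise ValueError(f"unknown normality_rule {self.normality_rule!r}")


def detect_variable_type(
    column: pd.Series, rule: TypeDetectionRule | None = None
) -> VarType:
    """Infer the variable type of one (missing-standardized) column."""
    rule = rule or TypeDetectionRule()
    nonmiss = column.dropna()
    if nonmiss.empty:
        raise DetectionError(
            f"column {column.name!r} is entirely missing; specify its "
            "type explicitly"
        )
    numeric = pd.to_numeric(nonmiss, errors="coerce")
    if numeric.isna().any():
        return VarType.CATEGORICAL
    if numeric.nunique() <= rule.max_levels_categorical:
        return VarType.CATEGORICAL
    if rule.normality_rule == "always_nonnormal":
        return VarType.CONTINUOUS_NONNORMAL
    skew = float(stats.skew(numeric.to_numpy(dtype=float)))
    if abs(skew) <= rule.skew_cutoff:
        return VarType.CONTINUOUS_NORMAL
    return VarType.CONTINUOUS_NONNORMAL


def detect_specs(
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    rule: TypeDetectionRule | None = None,
    policy: MissingPolicy | None = None,
) -> list[VariableSpec]:
    """Detected VariableSpec for each requested (default: every) column."""
    clean = standardize_missing(table, policy or MissingPolicy())
    names = list(variables) if variables is not None else list(table.columns)
    return [
        make_variable_spec(name, detect_variable_type(clean[name], rule))
        for name in names
    ]


def easy_flow(
    table: pd.DataFrame,
    exclusions: Sequence[Sequence[bool]] = (),
    reasons: Sequence[str] = (),
    variables: Sequence[str] | None = None,
    rule: TypeDetectionRule | None = None,
    policy: MissingPolicy | None = None,
    options: FlowOptions | None = None,
) -> FlowState:
    """Run a whole flow with auto-typed variables.

    ``exclusions`` is a list of boolean keep-masks, each over the
    cohort remaining at that point, paired one-to-one with ``reasons``.
    """
    if len(exclusions) != len(reasons):
        raise ValueError("exclusions and reasons must have the same length")
    specs = detect_specs(table, variables, rule, policy)
    state = init_flow(table, specs, policy=policy, options=options)
    for mask, reason in zip(exclusions, reasons):
        add_exclusion(state, keep=mask, reason=reason)
    return state
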
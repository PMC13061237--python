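"""Flow orchestration: initialization, sequential exclusions, validation.

The workflow has three phases: (1) initialize with the raw participant
table and variable declarations, (2) apply exclusion criteria in study
order — each as either a boolean keep-mask or a pre-filtered table —
and (3) generate outputs (tables, diagram). Cohort consistency is
validated on every mutation: counts are conserved, sizes never
increase, and filtered tables must be genuine subsets of the current
cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError, ConsistencyError, SchemaError, ValidationError
from .missing import MissingPolicy, standardize_missing
from .model import (
    CohortSnapshot,
    ExclusionRecord,
    VariableSpec,
    ordered_specs,
    summarize_variable,
)

#: Internal stable row identity, assigned once at initialization.
ROW_ID = "_cohortflow_row_id"


@dataclass(frozen=True)
class FlowOptions:
    """Display and validation settings for a flow.

    strict
        Require every exclusion step to remove at least one participant
        (violations raise); when False they only warn, for pipeline use.
    correct
        Apply the Hedges small-sample correction to continuous and
        binary SMDs.
    decimals_smd / decimals_percent / decimals_mean
        Display rounding; computation always keeps full precision.
    """

    strict: bool = True
    correct: bool = True
    decimals_smd: int = 2
    decimals_percent: int = 1
    decimals_mean: int = 1


@dataclass
class FlowState:
    """Complete state of a participant flow.

    Invariants maintained by the mutating operations:
    ``len(snapshots) == len(exclusions) + 1``; snapshot sizes are
    non-increasing; and the initial size equals the final size plus all
    removals.
    """

    specs: list[VariableSpec]
    policy: MissingPolicy
    options: FlowOptions
    snapshots: list[CohortSnapshot] = field(default_factory=list)
    exclusions: list[ExclusionRecord] = field(default_factory=list)

    @property
    def current(self) -> CohortSnapshot:
        return self.snapshots[-1]

    def validate(self) -> None:
        """Check the structural invariants; raise ConsistencyError on failure."""
        if len(self.snapshots) != len(self.exclusions) + 1:
            raise ConsistencyError("snapshot/exclusion count mismatch")
        sizes = [s.n for s in self.snapshots]
        if any(b > a for a, b in zip(sizes, sizes[1:])):
            raise ConsistencyError(f"cohort sizes increase along the flow: {sizes}")
        removed = sum(e.n_removed for e in self.exclusions)
        if sizes and sizes[0] != sizes[-1] + removed:
            raise ConsistencyError(
                f"conservation violated: {sizes[0]} != {sizes[-1]} + {removed}"
            )


def _load_table(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(table, (str, Path)):
        return pd.read_csv(table)
    return table.copy()


def _make_snapshot(
    table: pd.DataFrame,
    label: str,
    step_index: int,
    specs: Sequence[VariableSpec],
    policy: MissingPolicy,
) -> CohortSnapshot:
    snap = CohortSnapshot(label=label, step_index=step_index, table=table)
    snap.summaries = {
        spec.name: summarize_variable(table, spec, policy.missing_label)
        for spec in specs
    }
    return snap


def init_flow(
    table: pd.DataFrame | str | Path,
    specs: Sequence[VariableSpec],
    policy: MissingPolicy | None = None,
    options: FlowOptions | None = None,
    label: str = "Initial cohort",
) -> FlowState:
    """Start a flow from a raw participant table.

    The table may be a DataFrame or a CSV path (header row required).
    Missing-value standardization is applied once here; snapshot 0 is
    created with full summaries for every declared variable.
    """
    policy = policy or MissingPolicy()
    options = options or FlowOptions()
    df = _load_table(table)
    if df.empty:
        raise ConfigurationError("input table is empty")
    absent = [s.name for s in specs if s.name not in df.columns]
    if absent:
        raise SchemaError(f"declared columns not found in table: {absent}")
    df = standardize_missing(df, policy)
    df = df.reset_index(drop=True)
    df[ROW_ID] = range(len(df))
    state = FlowState(
        specs=ordered_specs(list(specs)), policy=policy, options=options
    )
    state.snapshots.append(_make_snapshot(df, label, 0, state.specs, policy))
    return state


def add_exclusion(
    state: FlowState,
    keep: Sequence[bool] | pd.Series | None = None,
    table: pd.DataFrame | None = None,
    reason: str = "",
    label: str | None = None,
) -> FlowState:
    """Apply one exclusion step, given exactly one of ``keep`` / ``table``.

    ``keep`` is a boolean mask over the *current* cohort (True =
    retain). ``table`` is the already-filtered cohort; its rows must be
    a subset of the current rows (matched on the stable internal row
    identity when present, else on full-row equality, which requires
    unique rows). A step that removes nobody raises under strict
    validation and warns otherwise; a step that removes everybody is
    allowed with a warning, and downstream SMDs against the empty
    cohort are reported as missing values.
    """
    if (keep is None) == (table is None):
        raise ConfigurationError(
            "supply exactly one of keep=<mask> or table=<filtered table>"
        )
    current = state.current.table

    if keep is not None:
        mask = pd.Series(list(keep), dtype=bool)
        if len(mask) != len(current):
            raise ConfigurationError(
                f"keep mask has length {len(mask)}, cohort has {len(current)}"
            )
        new_table = current.loc[mask.to_numpy()].copy()
    else:
        filtered = standardize_missing(table, state.policy)
        new_table = _match_subset(current, filtered)

    n_before, n_after = len(current), len(new_table)
    n_removed = n_before - n_after
    if n_removed == 0:
        msg = f"exclusion step {len(state.exclusions) + 1} ({reason!r}) removed no participants"
        if state.options.strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    if n_after == 0:
        warnings.warn(
            f"exclusion step {len(state.exclusions) + 1} ({reason!r}) removed "
            "the entire cohort; downstream SMDs will be undefined",
            stacklevel=2,
        )

    step_index = len(state.snapshots)
    snap_label = label or f"Step {step_index + 1}"
    state.exclusions.append(
        ExclusionRecord(
            reason=reason, label=label,
            n_before=n_before, n_removed=n_removed, n_after=n_after,
        )
    )
    state.snapshots.append(
        _make_snapshot(new_table, snap_label, step_index, state.specs, state.policy)
    )
    state.validate()
    return state


def _match_subset(current: pd.DataFrame, filtered: pd.DataFrame) -> pd.DataFrame:
    """Verify ``filtered`` is a subset of ``current`` and return it in
    stable row order.
    """
    if ROW_ID in filtered.columns:
        ids = filtered[ROW_ID]
        if ids.duplicated().any():
            raise ConsistencyError("filtered table contains duplicated row ids")
        known = set(current[ROW_ID])
        foreign = [i for i in ids if i not in known]
        if foreign:
            raise ConsistencyError(
                f"filtered table contains rows not in the current cohort "
                f"(row ids {foreign[:5]}...)"
            )
        # re-sort by internal id so row order never depends on the caller
        return current[current[ROW_ID].isin(set(ids))].copy()
    # no row ids: fall back to full-row equality (slower; requires unique rows)
    cur = current.drop(columns=[ROW_ID])
    if cur.duplicated().any() or filtered.duplicated().any():
        raise ConsistencyError(
            "full-row matching requires unique rows; pass tables carrying "
            f"the {ROW_ID!r} column instead"
        )
    filt = filtered.drop(columns=[ROW_ID], errors="ignore")
    merged = cur.reset_index().merge(filt, on=list(cur.columns), how="inner")
    if len(merged) != len(filt):
        raise ConsistencyError(
            "filtered table contains rows not present in the current cohort"
        )
    return current.loc[sorted(merged["index"])].copy()


def from_prefiltered(
    tables: Sequence[pd.DataFrame | str | Path],
    labels: Sequence[str] | None = None,
    specs: Sequence[VariableSpec] = (),
    reasons: Sequence[str] | None = None,
    policy: MissingPolicy | None = None,
    options: FlowOptions | None = None,
) -> FlowState:
    """Build a flow from already-filtered tables, one per cohort state.

    An alternative workflow for preprocessing done elsewhere: pass the
    exported table at each step and the exclusion records are
    synthesized from the size differences. Sizes must be non-increasing.
    Each table after the first must be a row-subset of its predecessor.
    """
    if len(tables) < 2:
        raise ConfigurationError("from_prefiltered requires at least 2 tables")
    labels = list(labels) if labels is not None else [
        "Initial cohort", *[f"Step {i + 1}" for i in range(1, len(tables))]
    ]
    if len(labels) != len(tables):
        raise ConfigurationError("labels and tables differ in length")
    reasons = list(reasons) if reasons is not None else [
        f"Exclusion {i}" for i in range(1, len(tables))
    ]
    if len(reasons) != len(tables) - 1:
        raise ConfigurationError("need one reason per transition")

    frames = [_load_table(t) for t in tables]
    sizes = [len(f) for f in frames]
    for a, b in zip(sizes, sizes[1:]):
        if b > a:
            raise ConsistencyError(
                f"cohort size increases between consecutive tables: {sizes}"
            )

    opts = options or FlowOptions()
    # zero-removal transitions are tolerated here unless strict asked for
    state = init_flow(frames[0], specs, policy=policy, options=opts, label=labels[0])
    for i, frame in enumerate(frames[1:], start=1):
        add_exclusion(state, table=frame, reason=reasons[i - 1], label=labels[i])
    return state
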
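"""Tabular outputs: flow summary, characteristics, and drift tables.

All three are returned as pandas DataFrames and can be exported to CSV
(RFC 4180 quoting) and LaTeX. Display rounding is applied to the
formatted tables only; drift values are computed and kept at full
precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .drift import drift_between
from .flow import FlowState
from .model import SummaryStat, VariableSpec, VarType

OTHER_LABEL = "Other"


def flow_summary_table(state: FlowState) -> pd.DataFrame:
    """Participant counts at each step, with removals and reasons."""
    rows = []
    for i, snap in enumerate(state.snapshots):
        if i == 0:
            rows.append((snap.label, snap.n, pd.NA, ""))
        else:
            exc = state.exclusions[i - 1]
            rows.append((snap.label, snap.n, exc.n_removed, exc.reason))
    return pd.DataFrame(
        rows, columns=["label", "n", "n_removed", "reason"]
    ).rename_axis("step")


def _column_headers(state: FlowState) -> list[str]:
    return [
        f"{snap.label} (n = {snap.n:,})" for snap in state.snapshots
    ]


def _display_categories(
    state: FlowState, spec: VariableSpec
) -> list[tuple[str, tuple[str, ...] | None]]:
    """Rows to display for a categorical variable.

    Returns (display label, pooled source labels or None). Categories
    are ranked by frequency in the initial cohort (ties broken
    lexicographically); with a category_limit the top-N are shown and
    the rest pooled into "Other". An explicit class_order overrides the
    frequency ranking for the displayed order.
    """
    initial = state.snapshots[0].summaries[spec.name]
    counts = initial.counts()
    # union of labels across all snapshots, so late-appearing levels show
    all_labels: list[str] = list(counts)
    for snap in state.snapshots[1:]:
        for label in snap.summaries[spec.name].counts():
            if label not in all_labels:
                all_labels.append(label)
    ranked = sorted(
        all_labels, key=lambda l: (-counts.get(l, 0), l)
    )
    if spec.class_order is not None:
        explicit = [l for l in spec.class_order if l in all_labels]
        ranked = explicit + [l for l in ranked if l not in explicit]
    if spec.category_limit is not None and len(ranked) > spec.category_limit:
        shown = ranked[: spec.category_limit]
        pooled = tuple(ranked[spec.category_limit:])
        return [(l, None) for l in shown] + [(OTHER_LABEL, pooled)]
    return [(l, None) for l in ranked]


def _format_cell(
    summ: SummaryStat,
    spec: VariableSpec,
    category: str | None,
    pooled: tuple[str, ...] | None,
    state: FlowState,
) -> str:
    opts = state.options
    if spec.var_type is VarType.CONTINUOUS_NORMAL:
        if summ.mean is None:
            return ""
        d = opts.decimals_mean
        return f"{summ.mean:.{d}f} ({summ.sd:.{d}f})"
    if spec.var_type is VarType.CONTINUOUS_NONNORMAL:
        if summ.median is None:
            return ""
        d = opts.decimals_mean
        return f"{summ.median:.{d}f} [{summ.q1:.{d}f}, {summ.q3:.{d}f}]"
    counts = summ.counts()
    props = summ.proportions()
    if pooled is not None:
        count = sum(counts.get(l, 0) for l in pooled)
        prop = sum(props.get(l, 0.0) for l in pooled)
    else:
        count = counts.get(category, 0)
        prop = props.get(category, 0.0)
    return f"{count:,} ({100 * prop:.{opts.decimals_percent}f})"


def characteristics_table(state: FlowState) -> pd.DataFrame:
    """Variable distributions per cohort, one column per snapshot.

    Cells are "mean (SD)", "median [Q1, Q3]" or "count (percent)";
    categorical variables get one row per displayed category, with
    low-frequency categories pooled into "Other" when a category_limit
    is set (display-only: drift never uses the limited set).
    """
    headers = _column_headers(state)
    index: list[tuple[str, str]] = []
    rows: list[list[str]] = []
    for spec in state.specs:
        if spec.var_type.is_continuous:
            index.append((spec.name, ""))
            rows.append([
                _format_cell(s.summaries[spec.name], spec, None, None, state)
                for s in state.snapshots
            ])
        else:
            for category, pooled in _display_categories(state, spec):
                index.append((spec.name, category))
                rows.append([
                    _format_cell(
                        s.summaries[spec.name], spec, category, pooled, state
                    )
                    for s in state.snapshots
                ])
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["variable", "category"]),
        columns=headers,
    )


def drift_table(state: FlowState, rounded: bool = True) -> pd.DataFrame:
    """SMD of each variable over each consecutive transition.

    Columns are labeled "1 → 2", "2 → 3", ... With ``rounded=True``
    (display form) values are rounded to the configured number of
    decimals; pass ``rounded=False`` for full precision.
    """
    if len(state.snapshots) < 2:
        raise ValueError("drift requires at least two snapshots")
    data: dict[str, list[float]] = {}
    cols = []
    for a, b in zip(state.snapshots, state.snapshots[1:]):
        col = f"{a.step_index + 1} → {b.step_index + 1}"
        cols.append(col)
        values = drift_between(a, b, state.specs, correct=state.options.correct)
        data[col] = [v.smd for v in values]
    out = pd.DataFrame(
        data, index=pd.Index([s.name for s in state.specs], name="variable"),
        columns=cols,
    )
    if rounded:
        out = out.round(state.options.decimals_smd)
    return out


def export_tables(
    state: FlowState,
    directory: str | Path,
    formats: Iterable[str] = ("csv",),
) -> list[Path]:
    """Write flow_summary / characteristics / drift in each format.

    Returns the written paths. CSV output round-trips: re-reading a
    file reproduces the cell text exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = {
        "flow_summary": flow_summary_table(state),
        "characteristics": characteristics_table(state),
        "drift": drift_table(state),
    }
    written: list[Path] = []
    for fmt in formats:
        if fmt not in {"csv", "latex"}:
            raise ValueError(f"unsupported export format: {fmt!r}")
        for name, df in tables.items():
            ext = "csv" if fmt == "csv" else "tex"
            path = directory / f"{name}.{ext}"
            if fmt == "csv":
                df.to_csv(path)
            else:
                path.write_text(df.to_latex())
            written.append(path)
    return written
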
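"""Flow-diagram generation: DOT graph plus distribution panels.

The diagram follows the CONSORT-style layout: cohort boxes form a
vertical chain; each exclusion hangs off the chain as a terminal side
node stating the reason and the number removed. Distribution panels
(stacked proportion bars for categorical variables, histograms for
continuous ones) are written as separate image files referenced from
the cohort nodes, keeping the DOT file itself text-diffable.

Rendering the DOT file to SVG/PDF shells out to the Graphviz ``dot``
binary when it is on the PATH; when it is not, generation degrades
gracefully to DOT-only output with a warning.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .flow import FlowState
from .model import CohortSnapshot, VariableSpec, VarType
from .tables import drift_table

#: Fixed palette assigned to categories by initial-cohort frequency rank,
#: so a category keeps its color across snapshots.
DEFAULT_PALETTE = (
    "#4878d0", "#ee854a", "#6acc64", "#d65f5f", "#956cb4",
    "#8c613c", "#dc7ec0", "#797979", "#d5bb67", "#82c6e2",
)


@dataclass(frozen=True)
class DiagramOptions:
    show_smd: bool = True
    box_width: float = 2.6
    box_height: float = 1.0
    palette: tuple[str, ...] = DEFAULT_PALETTE
    panel_variables: tuple[str, ...] | None = None  # None = all tracked


@dataclass
class FlowDiagramSpec:
    """Graph description prior to rendering: nodes, edges, annotations."""

    cohort_nodes: list[dict] = field(default_factory=list)
    exclusion_nodes: list[dict] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)
    options: DiagramOptions = field(default_factory=DiagramOptions)


def build_diagram_spec(
    state: FlowState, options: DiagramOptions | None = None
) -> FlowDiagramSpec:
    """Deterministic node/edge set for a flow.

    Cohort node i connects to cohort node i+1 and to exclusion node i,
    which is terminal. SMD annotations (the largest per transition)
    are attached to the chain edges when enabled.
    """
    options = options or DiagramOptions()
    diag = FlowDiagramSpec(options=options)
    smd_annotations: list[str] = []
    if options.show_smd and len(state.snapshots) >= 2:
        dt = drift_table(state, rounded=False)
        for col in dt.columns:
            worst = dt[col].abs().max()
            smd_annotations.append(
                f"max |SMD| = {worst:.{state.options.decimals_smd}f}"
            )
    for i, snap in enumerate(state.snapshots):
        diag.cohort_nodes.append(
            {
                "id": f"cohort{i}",
                "label": f"{snap.label}\nn = {snap.n:,}",
                "n": snap.n,
                "panel": f"panel_step{i}.png",
            }
        )
    for i, exc in enumerate(state.exclusions):
        diag.exclusion_nodes.append(
            {
                "id": f"excl{i}",
                "label": f"Excluded: {exc.reason}\nn = {exc.n_removed:,}",
                "n_removed": exc.n_removed,
            }
        )
        diag.edges.append((f"cohort{i}", f"excl{i}"))
        edge = (f"cohort{i}", f"cohort{i + 1}")
        diag.edges.append(edge)
    # order edges along the chain for stable output
    diag.edges.sort()
    if options.show_smd:
        for i, ann in enumerate(smd_annotations):
            diag.cohort_nodes[i + 1]["smd_note"] = ann
    return diag


def _dot_escape(text: str) -> str:
    return (
        text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")
    )


def emit_graph_file(diagram: FlowDiagramSpec, path: str | Path) -> Path:
    """Write the diagram as DOT-language text; returns the path."""
    path = Path(path)
    lines = ["digraph cohort_flow {", "  rankdir=TB;", '  node [shape=box, fontname="Helvetica"];']
    for node in diagram.cohort_nodes:
        label = node["label"]
        if "smd_note" in node:
            label += "\n" + node["smd_note"]
        lines.append(
            f'  {node["id"]} [label="{_dot_escape(label)}", '
            f'width={diagram.options.box_width}, '
            f'height={diagram.options.box_height}, '
            f'image="{_dot_escape(node["panel"])}"];'
        )
    for node in diagram.exclusion_nodes:
        lines.append(
            f'  {node["id"]} [label="{_dot_escape(node["label"])}", '
            "style=rounded];"
        )
    for src, dst in diagram.edges:
        lines.append(f"  {src} -> {dst};")
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
    return path


def render_distribution_panel(
    snapshot: CohortSnapshot,
    spec: VariableSpec,
    path: str | Path,
    options: DiagramOptions | None = None,
    category_order: list[str] | None = None,
) -> Path:
    """Write the distribution panel for one variable in one snapshot.

    Categorical variables get a single stacked horizontal bar of
    category proportions (missingness included); continuous variables
    a compact histogram of the non-missing values. Output is
    deterministic: regenerating on unchanged input is byte-identical.

    ``category_order`` fixes segment order and color assignment across
    snapshots (typically initial-cohort frequency rank).
    """
    options = options or DiagramOptions()
    path = Path(path)
    fig, ax = plt.subplots(figsize=(3.2, 1.2), dpi=100)
    summ = snapshot.summaries[spec.name]
    if snapshot.n == 0:
        ax.text(0.5, 0.5, "n = 0", ha="center", va="center")
        ax.set_axis_off()
    elif spec.var_type is VarType.CATEGORICAL:
        props = summ.proportions()
        order = category_order or sorted(props, key=lambda l: (-props[l], l))
        left = 0.0
        for rank, label in enumerate(order):
            p = props.get(label, 0.0)
            ax.barh(
                0, p, left=left, height=0.6,
                color=options.palette[rank % len(options.palette)],
                label=label,
            )
            left += p
        ax.set_xlim(0, 1)
        ax.set_yticks([])
        ax.set_title(spec.name, fontsize=8)
    else:
        values = snapshot.table[spec.name].dropna().astype(float)
        ax.hist(values, bins=20, color=options.palette[0])
        ax.set_title(spec.name, fontsize=8)
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": None} if path.suffix == ".png" else None)
    plt.close(fig)
    return path


def render_flow_diagram(
    state: FlowState,
    directory: str | Path,
    options: DiagramOptions | None = None,
    render: bool = True,
) -> dict[str, Path]:
    """Emit the DOT file and all panels; render to SVG if ``dot`` exists.

    Returns a map of artifact name to written path.
    """
    options = options or DiagramOptions()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    diag = build_diagram_spec(state, options)
    out: dict[str, Path] = {}
    out["dot"] = emit_graph_file(diag, directory / "flow_diagram.dot")

    panel_specs = [
        s for s in state.specs
        if options.panel_variables is None or s.name in options.panel_variables
    ]
    for snap in state.snapshots:
        for spec in panel_specs:
            order = None
            if spec.var_type is VarType.CATEGORICAL:
                initial = state.snapshots[0].summaries[spec.name].proportions()
                order = sorted(initial, key=lambda l: (-initial[l], l))
            name = f"panel_step{snap.step_index}_{spec.name}.png"
            out[name] = render_distribution_panel(
                snap, spec, directory / name, options, category_order=order
            )

    if render:
        dot = shutil.which("dot")
        if dot is None:
            warnings.warn(
                "Graphviz 'dot' not found on PATH; diagram left as DOT text only",
                stacklevel=2,
            )
        else:
            svg = directory / "flow_diagram.svg"
            subprocess.run(
                [dot, "-Tsvg", str(out["dot"]), "-o", str(svg)], check=True
            )
            out["svg"] = svg
    return out
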
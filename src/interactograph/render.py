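"""GraphViz DOT emission.

Edge encodings follow the field's visual convention: a black line is a
protein-protein interaction and a red arrow a protein->DNA interaction
(arrowhead at the regulated gene); genetic interactions default to blue
dashed and the catch-all type to gray dotted.  Nodes are hypernodes —
one node per gene regardless of how many molecular roles (DNA, RNA,
protein) its incident edges imply.  Ortholog stacks are emitted as
single record-shaped nodes (one row per member) rather than clusters,
because the sfdp layout engine does not honor clusters.  A legend
describing every encoding present, plus the colored query-group boxes,
is inserted as its own cluster.

Output is deterministic: identical inputs yield identical bytes.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from .errors import RenderEnvironmentError
from .extract import Edge, InteractionGraph
from .model import (
    GeneRef,
    InteractionType,
    Knowledgebase,
    QuerySpec,
    default_group_name,
)
from .stacking import CompoundPartition

_TYPE_LABELS = {
    InteractionType.protein_protein: "protein-protein interaction",
    InteractionType.protein_dna: "protein->DNA interaction",
    InteractionType.genetic: "genetic interaction",
    InteractionType.other: "other interaction",
}


@dataclass(frozen=True)
class StyleConfig:
    """Visual and URL configuration.

    ``edge_color``/``edge_style`` are keyed by interaction type; the
    group palette is a colorblind-safe three-color set.  URL templates
    receive ``{gene_id}`` / ``{record_id}``; the record template
    defaults to a local anchor scheme since no web service is hosted.
    """

    edge_color: dict[InteractionType, str] = field(
        default_factory=lambda: {
            InteractionType.protein_protein: "black",
            InteractionType.protein_dna: "red",
            InteractionType.genetic: "blue",
            InteractionType.other: "gray50",
        }
    )
    edge_style: dict[InteractionType, str] = field(
        default_factory=lambda: {
            InteractionType.protein_protein: "solid",
            InteractionType.protein_dna: "solid",
            InteractionType.genetic: "dashed",
            InteractionType.other: "dotted",
        }
    )
    group_colors: tuple[str, str, str] = ("#1b9e77", "#d95f02", "#7570b3")
    node_shape: str = "ellipse"
    gene_url_template: str = "https://www.ncbi.nlm.nih.gov/gene/{gene_id}"
    record_url_template: str = "record://{record_id}"
    layout_engine: str = "sfdp"

    @classmethod
    def from_file(cls, path) -> "StyleConfig":
        """Load overrides from a flat ``key = value`` file.  Recognized
        keys: ``layout_engine``, ``node_shape``, ``gene_url_template``,
        ``record_url_template``, ``group_color_1..3``,
        ``edge_color_<PP|PD|GI|OTHER>``, ``edge_style_<...>``."""
        cfg = cls()
        edge_color = dict(cfg.edge_color)
        edge_style = dict(cfg.edge_style)
        group_colors = list(cfg.group_colors)
        simple: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("edge_color_"):
                edge_color[InteractionType.from_code(key[len("edge_color_"):])] = value
            elif key.startswith("edge_style_"):
                edge_style[InteractionType.from_code(key[len("edge_style_"):])] = value
            elif key.startswith("group_color_"):
                idx = int(key[len("group_color_"):]) - 1
                if not 0 <= idx <= 2:
                    raise ValueError(f"{path}:{lineno}: group index must be 1..3")
                group_colors[idx] = value
            elif key in ("layout_engine", "node_shape", "gene_url_template",
                         "record_url_template"):
                simple[key] = value
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return replace(
            cfg,
            edge_color=edge_color,
            edge_style=edge_style,
            group_colors=tuple(group_colors),  # type: ignore[arg-type]
            **simple,
        )


@dataclass
class DotDocument:
    dot_text: str
    url_map: dict[str, str] = field(default_factory=dict)
    legend_items: list[tuple[str, str]] = field(default_factory=list)
    layout_engine: str = "sfdp"


def _quote(s: str) -> str:
    # only double quotes are escaped: backslash sequences (record-label
    # escapes, \n) must pass through to the label interpreter verbatim
    return '"' + s.replace('"', '\\"') + '"'


def _record_escape(s: str) -> str:
    for ch in "\\{}|<> ":
        s = s.replace(ch, "\\" + ch)
    return s


def _attrs(d: dict[str, str]) -> str:
    return "[" + ", ".join(f"{k}={_quote(v)}" for k, v in d.items()) + "]"


def build_legend(
    graph: InteractionGraph,
    spec: QuerySpec,
    style: Optional[StyleConfig] = None,
) -> list[tuple[str, str]]:
    """Legend items: one per edge encoding present in the graph (enum
    order) plus one per query group when groups are multiple or renamed
    (index order)."""
    style = style or StyleConfig()
    present = {e.interaction_type for e in graph.edges}
    items: list[tuple[str, str]] = []
    for itype in InteractionType:
        if itype in present:
            shape = "arrow" if itype is InteractionType.protein_dna else "line"
            glyph = f"{style.edge_color[itype]} {style.edge_style[itype]} {shape}"
            items.append((glyph, _TYPE_LABELS[itype]))
    renamed = any(
        name != default_group_name(i) for i, (name, _) in enumerate(spec.groups)
    )
    if len(spec.groups) >= 2 or renamed:
        for i, (name, _) in enumerate(spec.groups):
            items.append((f"{style.group_colors[i]} border", name))
    return items


def _node_id(ref: GeneRef, partition: CompoundPartition) -> str:
    stack = partition.stack_of(ref.gene_id)
    if stack is not None:
        return f"hg{stack.homologene_id}"
    return f"g{ref.gene_id}"


def to_dot(
    graph: InteractionGraph,
    partition: CompoundPartition,
    spec: QuerySpec,
    style: Optional[StyleConfig] = None,
    kb: Optional[Knowledgebase] = None,
) -> DotDocument:
    """Emit the result graph as a DOT document with URL map and legend.

    ``kb`` supplies display labels (official symbols) and submitter
    attributions; without it genes are labeled by raw id.
    """
    style = style or StyleConfig()
    part_ids = {r.gene_id for r in partition.all_nodes()}
    graph_ids = {r.gene_id for r in graph.nodes}
    if part_ids != graph_ids:
        raise ValueError(
            "partition is inconsistent with graph: "
            f"missing={sorted(graph_ids - part_ids)} extra={sorted(part_ids - graph_ids)}"
        )

    def label_of(ref: GeneRef) -> str:
        return kb.label_of(ref) if kb is not None else str(ref.gene_id)

    def border(members: list[GeneRef]) -> dict[str, str]:
        groups: set[int] = set()
        for m in members:
            groups |= graph.query_membership.get(m.gene_id, frozenset())
        if not groups:
            return {}
        out = {"color": style.group_colors[min(groups)], "penwidth": "2"}
        if len(groups) > 1:
            out["peripheries"] = "2"  # member of multiple query groups
        return out

    url_map: dict[str, str] = {}
    lines = [
        "digraph interactions {",
        f"  graph [layout={_quote(style.layout_engine)}, overlap=false, outputorder=edgesfirst];",
        f"  node [shape={_quote(style.node_shape)}];",
    ]

    for stack in sorted(partition.stacks, key=lambda s: s.homologene_id):
        nid = f"hg{stack.homologene_id}"
        rows = "|".join(
            f"{_record_escape(label_of(m))}\\n({m.tax_id})" for m in stack.members
        )
        lead = stack.members[0]  # lowest tax_id: heads the stack label
        attrs = {
            "shape": "record",
            "label": "{" + rows + "}",
            "URL": style.gene_url_template.format(gene_id=lead.gene_id),
            "tooltip": f"orthologs of {label_of(lead)}",
        }
        attrs.update(border(list(stack.members)))
        lines.append(f"  {_quote(nid)} {_attrs(attrs)};")
        url_map[nid] = attrs["URL"]
        for m in stack.members:
            url_map[f"{nid}:g{m.gene_id}"] = style.gene_url_template.format(
                gene_id=m.gene_id
            )

    for ref in partition.singletons:
        nid = f"g{ref.gene_id}"
        attrs = {
            "label": label_of(ref),
            "URL": style.gene_url_template.format(gene_id=ref.gene_id),
            "tooltip": f"{label_of(ref)} (taxon {ref.tax_id})",
        }
        attrs.update(border([ref]))
        lines.append(f"  {_quote(nid)} {_attrs(attrs)};")
        url_map[nid] = attrs["URL"]

    record_index = (
        {r.record_id: r for r in kb.interactions} if kb is not None else {}
    )
    for n, edge in enumerate(graph.sorted_edges(), start=1):
        eid = f"e{n}"
        src = _node_id(edge.subject, partition)
        dst = _node_id(edge.object, partition)
        tooltip = (
            f"{edge.interaction_type.value} records "
            + ",".join(str(r) for r in edge.record_ids)
        )
        submitters = sorted(
            {
                record_index[rid].submitter
                for rid in edge.record_ids
                if rid in record_index and record_index[rid].submitter
            }
        )
        if submitters:
            tooltip += "; submitted by " + ", ".join(submitters)
        attrs = {
            "color": style.edge_color[edge.interaction_type],
            "style": style.edge_style[edge.interaction_type],
            "dir": "forward" if edge.directed else "none",
            "id": eid,
            "URL": style.record_url_template.format(record_id=edge.record_ids[0]),
            "tooltip": tooltip,
        }
        lines.append(f"  {_quote(src)} -> {_quote(dst)} {_attrs(attrs)};")
        url_map[eid] = attrs["URL"]

    legend_items = build_legend(graph, spec, style)
    lines.append("  subgraph cluster_legend {")
    lines.append(f"    label={_quote('Legend')};")
    rows = "|".join(
        f"{_record_escape(glyph)}:\\ {_record_escape(label)}"
        for glyph, label in legend_items
    )
    legend_label = "{" + ("Legend" + ("|" + rows if rows else "")) + "}"
    lines.append(
        f"    {_quote('legend')} "
        + _attrs({"shape": "record", "label": legend_label})
        + ";"
    )
    lines.append("  }")
    lines.append("}")
    return DotDocument(
        dot_text="\n".join(lines) + "\n",
        url_map=url_map,
        legend_items=legend_items,
        layout_engine=style.layout_engine,
    )


_FORMATS = ("dot", "gif_with_cmap", "pdf", "svg")


def render(doc: DotDocument, format: str, out) -> Path:
    """Write the document.

    ``dot`` writes the DOT text verbatim and is always available.  The
    other formats shell out to the configured GraphViz layout engine;
    ``gif_with_cmap`` additionally writes the clickable image-map
    sidecar next to the image.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}")
    out = Path(out)
    if format == "dot":
        out.write_text(doc.dot_text)
        return out
    exe = shutil.which(doc.layout_engine) or shutil.which("dot")
    if exe is None:
        raise RenderEnvironmentError(
            f"rendering to {format!r} requires a GraphViz executable "
            f"({doc.layout_engine!r} or 'dot') on PATH; none was found"
        )
    if format == "gif_with_cmap":
        _run_graphviz(exe, "gif", doc.dot_text, out)
        _run_graphviz(exe, "cmapx", doc.dot_text, out.with_suffix(out.suffix + ".map"))
    else:
        _run_graphviz(exe, format, doc.dot_text, out)
    return out


def _run_graphviz(exe: str, fmt: str, dot_text: str, out: Path) -> None:
    proc = subprocess.run(
        [exe, f"-T{fmt}", "-o", str(out)],
        input=dot_text.encode(),
        capture_output=True,
    )
    if proc.returncode != 0:
        raise RenderEnvironmentError(
            f"GraphViz failed ({exe} -T{fmt}): {proc.stderr.decode(errors='replace')}"
        )
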
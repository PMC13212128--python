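"""Table and graph I/O plus the end-to-end pipeline driver.

Graph text format (one edge per line, 1-indexed; latent nodes shown in
parentheses in the node list)::

    Graph Nodes:
    VisL;Att;(L1)
    Graph Edges:
    1. VisL --> Att [dd, nl]
    2. MoS o-o UoS

Directed PAG edges carry ``[dd|pd, nl|pl]`` annotations from the seven-type
classification; other marks are rendered ``o->``, ``o-o``, ``<->``.
All text outputs use LF endings, UTF-8 and fixed 3-decimal probabilities so
reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .graph import EdgeType, Mark, MixedGraph, classify_edge
from .stats import SearchParams, covariance_from_table
from .gfci import gfci_search
from .bootstrap import consensus, render_report, run_ensemble, tally

log = logging.getLogger(__name__)

_MARK_LEFT = {Mark.TAIL: "-", Mark.ARROW: "<", Mark.CIRCLE: "o"}
_MARK_RIGHT = {Mark.TAIL: "-", Mark.ARROW: ">", Mark.CIRCLE: "o"}
_LEFT_MARK = {v: k for k, v in _MARK_LEFT.items()}
_RIGHT_MARK = {v: k for k, v in _MARK_RIGHT.items()}


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_table(path: Union[str, Path],
               delimiter: Optional[str] = None) -> pd.DataFrame:
    """Read a CSV/TSV with a header row into a numeric table.

    The delimiter is sniffed unless forced; non-numeric cells become
    missing values; column order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    text = path.read_text(encoding="utf-8")
    first = text.splitlines()[0] if text.splitlines() else ""
    if not first.strip():
        raise ValueError(f"empty table: {path}")
    if delimiter is None:
        import csv
        try:
            delimiter = csv.Sniffer().sniff(first, delimiters=",\t;").delimiter
        except csv.Error:
            delimiter = ","
    header = [c.strip() for c in first.split(delimiter)]
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValueError(f"duplicate column names: {sorted(dupes)}")
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"empty table: {path}")
    return df.apply(pd.to_numeric, errors="coerce")


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    Path(path).write_text(df.to_csv(index=False, lineterminator="\n"),
                          encoding="utf-8")


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

def format_graph(graph: MixedGraph, annotate: bool = True) -> str:
    """Canonical edges-text rendering (node-order endpoints, 1-indexed)."""
    names = [f"({n})" if graph.is_latent(n) else n for n in graph.nodes]
    lines = ["Graph Nodes:", ";".join(names), "", "Graph Edges:"]
    for i, e in enumerate(graph.edges(), start=1):
        glyph = _MARK_LEFT[e.mark_a] + "-" + _MARK_RIGHT[e.mark_b]
        line = f"{i}. {e.a} {glyph} {e.b}"
        if annotate and graph.kind == "PAG":
            et = classify_edge(graph, e.a, e.b)
            if et.is_directed:
                dd = "dd" if et in (EdgeType.T1_DD_NLC, EdgeType.T3_DD_PLC) \
                    else "pd"
                nl = "nl" if et in (EdgeType.T1_DD_NLC, EdgeType.T2_PD_NLC) \
                    else "pl"
                line += f" [{dd}, {nl}]"
        lines.append(line)
    return "\n".join(lines) + "\n"


def parse_graph(text: str, kind: str = "PAG") -> MixedGraph:
    """Inverse of :func:`format_graph`; annotations are ignored (they are
    recomputable from the marks)."""
    lines = [ln.strip() for ln in text.splitlines()]
    try:
        ni = lines.index("Graph Nodes:")
        ei = lines.index("Graph Edges:")
    except ValueError:
        raise ValueError("not a graph text file (missing section headers)")
    g = MixedGraph(kind=kind)
    for raw in lines[ni + 1].split(";"):
        raw = raw.strip()
        if not raw:
            continue
        if raw.startswith("(") and raw.endswith(")"):
            g.add_node(raw[1:-1], latent=True)
        else:
            g.add_node(raw)
    for ln in lines[ei + 1:]:
        if not ln:
            continue
        body = ln.split(". ", 1)[1] if ". " in ln else ln
        if " [" in body:
            body = body.split(" [", 1)[0]
        a, glyph, b = body.rsplit(" ", 2)[-3:]
        g.add_edge(a, b, _LEFT_MARK[glyph[0]], _RIGHT_MARK[glyph[2]])
    return g


_PL_TYPES = (EdgeType.T3_DD_PLC, EdgeType.T4_PD_PLC)
_DD_TYPES = (EdgeType.T1_DD_NLC, EdgeType.T3_DD_PLC)


def format_dot(graph: MixedGraph,
               node_colors: Optional[dict] = None) -> str:
    """DOT export: blue directed edges, brown circle marks, gray bidirected;
    dashed when a latent confounder is possible, bold when definitely
    direct.  ``node_colors`` maps node name → fill color."""
    arrow = {Mark.TAIL: "none", Mark.ARROW: "normal", Mark.CIRCLE: "odot"}
    out = ["digraph G {", "  edge [dir=both];"]
    for n in graph.nodes:
        attrs = [f'label="{n}"']
        if node_colors and n in node_colors:
            attrs += ["style=filled", f'fillcolor="{node_colors[n]}"']
        out.append(f'  "{n}" [{", ".join(attrs)}];')
    for e in graph.edges():
        attrs = [f"arrowtail={arrow[e.mark_a]}", f"arrowhead={arrow[e.mark_b]}"]
        style = []
        if graph.kind == "PAG":
            et = classify_edge(graph, e.a, e.b)
            if et is EdgeType.T7_BIDIRECTED:
                attrs.append('color="gray50"')
            elif et.is_directed:
                attrs.append('color="blue"')
                if et in _PL_TYPES:
                    style.append("dashed")
                if et in _DD_TYPES:
                    style.append("bold")
            else:
                attrs.append('color="brown"')
        if style:
            attrs.append(f'style="{",".join(style)}"')
        out.append(f'  "{e.a}" -> "{e.b}" [{", ".join(attrs)}];')
    out.append("}")
    return "\n".join(out) + "\n"


def format_graphml(graph: MixedGraph) -> str:
    """GraphML export via networkx; marks stored as edge attributes."""
    import networkx as nx

    g = nx.DiGraph()
    for n in graph.nodes:
        g.add_node(n, latent=graph.is_latent(n))
    for e in graph.edges():
        g.add_edge(e.a, e.b, mark_at_source=e.mark_a.name,
                   mark_at_target=e.mark_b.name)
    lines = nx.generate_graphml(g)
    return "\n".join(lines) + "\n"


def write_graph(graph: MixedGraph, path: Union[str, Path],
                format: str = "edges-text",
                node_colors: Optional[dict] = None) -> None:
    path = Path(path)
    if format == "edges-text":
        text = format_graph(graph)
    elif format == "dot":
        text = format_dot(graph, node_colors)
    elif format == "graphml":
        text = format_graphml(graph)
    else:
        raise ValueError(f"unknown graph format {format!r}")
    path.write_text(text, encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one discovery run needs; serialized for provenance."""

    input_path: str
    out_dir: str
    params: SearchParams = field(default_factory=SearchParams)
    delimiter: Optional[str] = None
    labels: Optional[dict[str, str]] = None  # rename map, input -> display
    annotate_full_data: bool = False
    verbosity: str = "INFO"


class _StageFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        stage = record.name.rsplit(".", 1)[-1]
        return f"{stage}\t{record.levelname}\t{record.getMessage()}"


def run_pipeline(config: RunConfig) -> int:
    """read → ensemble → tally → consensus → report + graphs + provenance.

    Returns a process exit status: 0 on success, 2 on a missing/unreadable
    input, 1 on any other failure; every error is logged with its stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pkg_log = logging.getLogger("pagdiscover")
    handler = logging.FileHandler(out / "log.txt", mode="w", encoding="utf-8")
    handler.setFormatter(_StageFormatter())
    pkg_log.addHandler(handler)
    old_level = pkg_log.level
    pkg_log.setLevel(config.verbosity)
    try:
        try:
            table = read_table(config.input_path, config.delimiter)
        except FileNotFoundError as exc:
            log.error("read: %s", exc)
            return 2
        if config.labels:
            table = table.rename(columns=config.labels)
        log.info("read: %d rows × %d columns from %s",
                 len(table), table.shape[1], config.input_path)

        pags = run_ensemble(table, config.params)
        tly = tally(pags)
        graph, report = consensus(tly, config.params)
        log.info("consensus: %d pairs tallied, %d retained",
                 len(report.rows), sum(r.retained for r in report.rows))

        (out / "report.tsv").write_text(render_report(report),
                                        encoding="utf-8", newline="\n")
        write_graph(graph, out / "consensus.edges.txt", "edges-text")
        write_graph(graph, out / "consensus.dot", "dot")
        if config.annotate_full_data:
            cov = covariance_from_table(table)
            full = gfci_search(cov, config.params)
            write_graph(full, out / "fulldata.edges.txt", "edges-text")

        digest = hashlib.sha256(
            Path(config.input_path).read_bytes()).hexdigest()
        provenance = {
            "pagdiscover_version": __version__,
            "input_path": str(config.input_path),
            "input_sha256": digest,
            "n_rows": int(len(table)),
            "variables": [str(c) for c in table.columns],
            "params": dataclasses.asdict(config.params),
            "annotate_full_data": config.annotate_full_data,
        }
        (out / "params.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n",
            encoding="utf-8", newline="\n")
        return 0
    except Exception as exc:  # noqa: BLE001 — CLI boundary
        log.error("pipeline: %s", exc)
        return 1
    finally:
        handler.close()
        pkg_log.removeHandler(handler)
        pkg_log.setLevel(old_level)
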
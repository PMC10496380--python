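"""Readers and writers for the pipeline's tabular and network formats.

Tables are CSV/TSV (dialect sniffed from the delimiter); networks are
written both as Pajek ``.net`` (1-based vertex numbering, quoted labels)
and GraphML with the node type kept as a node attribute.  Both network
writers round-trip losslessly through the package's own readers.
"""

from __future__ import annotations

import csv
import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable

import pandas as pd

from .annotation import AnnotationHit, CompoundRecord, PeakRecord
from .network_build import Network
from .network_metrics import MetricsReport

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_mapping_table",
    "read_compound_library",
    "read_peak_table",
    "write_hits_csv",
    "write_mapping_table",
    "write_pajek",
    "read_pajek",
    "write_graphml",
    "read_graphml",
    "write_metrics_summary",
    "write_per_node_csv",
    "write_spectrum_csv",
]


class FormatError(ValueError):
    """Raised for malformed input tables."""


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_mapping_table(path: str | Path, kind: str = "ingredient-target") -> dict[str, set[str]]:
    """Read a two-column CSV/TSV (with header) into a key -> set-of-values
    map.  Keys and values are whitespace-trimmed; duplicate rows collapse
    with a debug log.  ``kind`` only labels error messages."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    n_rows = 0
    n_dups = 0
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=_sep(path))
        for lineno, row in enumerate(reader, 1):
            if lineno == 1:  # header
                if len(row) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected 2 columns for a {kind} table, got {len(row)}"
                    )
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            key, value = row[0].strip(), row[1].strip()
            if not key or not value:
                raise FormatError(f"{path}:{lineno}: empty {kind} id")
            n_rows += 1
            bucket = mapping.setdefault(key, set())
            if value in bucket:
                n_dups += 1
            bucket.add(value)
    if not mapping:
        raise FormatError(f"{path}: empty {kind} table")
    if n_dups:
        logger.debug("%s: collapsed %d duplicate row(s)", path, n_dups)
    logger.info("%s: %d keys, %d rows (%s)", path.name, len(mapping), n_rows, kind)
    return mapping


def write_mapping_table(mapping: dict[str, set[str]], path: str | Path, header: tuple[str, str]) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_sep(path))
        writer.writerow(header)
        for key in sorted(mapping):
            for value in sorted(mapping[key]):
                writer.writerow([key, value])


def read_compound_library(path: str | Path) -> list[CompoundRecord]:
    """Library CSV with columns name, category, formula and optional cas."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"name", "category", "formula"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                CompoundRecord.from_formula(
                    name=str(row["name"]).strip(),
                    category=str(row["category"]).strip(),
                    formula_text=str(row["formula"]).strip(),
                    cas=str(row["cas"]).strip() if "cas" in df.columns and pd.notna(row["cas"]) else None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Peak CSV with columns feature_id, mz, rt_min, area_sample, area_control."""
    df = pd.read_csv(path, sep=_sep(path))
    required = {"feature_id", "mz", "rt_min", "area_sample", "area_control"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    peaks = []
    for idx, row in df.iterrows():
        try:
            peaks.append(
                PeakRecord(
                    feature_id=str(row["feature_id"]),
                    measured_mz=float(row["mz"]),
                    retention_time=float(row["rt_min"]),
                    area_sample=float(row["area_sample"]),
                    area_control=float(row["area_control"]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {idx + 2}: {exc}") from exc
    return peaks


def write_hits_csv(hits: Iterable[AnnotationHit], path: str | Path) -> None:
    """Annotation/screen hits with ppm error to 1 dp and enrichment ratio
    to 2 dp."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["feature_id", "compound_name", "ppm_error", "enrichment_ratio", "ambiguous"])
        for h in hits:
            ratio = "inf" if h.enrichment_ratio == float("inf") else f"{h.enrichment_ratio:.2f}"
            writer.writerow([h.feature_id, h.compound_name, f"{h.ppm_error:.1f}", ratio, int(h.ambiguous)])


# --- network formats -------------------------------------------------------

def write_pajek(net: Network, path: str | Path) -> None:
    """Pajek .net: 1-based vertex numbering over lexicographically sorted
    node ids, quoted labels, *Vertices/*Edges sections."""
    nodes = net.nodes
    index = {node: i + 1 for i, node in enumerate(nodes)}
    lines = [f"*Vertices {len(nodes)}"]
    lines += [f'{index[v]} "{v}"' for v in nodes]
    lines.append("*Edges")
    lines += [
        f"{index[u]} {index[v]}"
        for u, v in sorted(net.edges, key=lambda e: (index[e[0]], index[e[1]]))
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pajek(path: str | Path, name: str = "", node_types: dict[str, str] | None = None) -> Network:
    """Read a Pajek .net written by :func:`write_pajek`.  Node types are
    not representable in Pajek; supply them via ``node_types`` or every
    node defaults to ``ingredient``."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].lower().startswith("*vertices"):
        raise FormatError(f"{path}: not a Pajek .net file")
    n = int(lines[0].split()[1])
    labels: dict[int, str] = {}
    i = 1
    while i <= n:
        parts = lines[i].split(None, 1)
        labels[int(parts[0])] = parts[1].strip().strip('"')
        i += 1
    if not lines[i].lower().startswith(("*edges", "*arcs")):
        raise FormatError(f"{path}: expected *Edges section at line {i + 1}")
    edges = set()
    for line in lines[i + 1 :]:
        if not line.strip():
            continue
        a, b = line.split()[:2]
        u, v = labels[int(a)], labels[int(b)]
        edges.add((u, v) if u < v else (v, u))
    types = {
        node: (node_types or {}).get(node, "ingredient") for node in labels.values()
    }
    return Network(name or Path(path).stem, types, edges)


def write_graphml(net: Network, path: str | Path) -> None:
    ET.register_namespace("", "http://graphml.graphdrawing.org/xmlns")
    ns = "{http://graphml.graphdrawing.org/xmlns}"
    root = ET.Element(f"{ns}graphml")
    key = ET.SubElement(root, f"{ns}key")
    key.set("id", "d0")
    key.set("for", "node")
    key.set("attr.name", "node_type")
    key.set("attr.type", "string")
    graph = ET.SubElement(root, f"{ns}graph")
    graph.set("id", net.name or "G")
    graph.set("edgedefault", "undirected")
    for node in net.nodes:
        el = ET.SubElement(graph, f"{ns}node", id=node)
        data = ET.SubElement(el, f"{ns}data", key="d0")
        data.text = net.node_types[node]
    for u, v in sorted(net.edges):
        ET.SubElement(graph, f"{ns}edge", source=u, target=v)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_graphml(path: str | Path) -> Network:
    ns = "{http://graphml.graphdrawing.org/xmlns}"
    root = ET.parse(path).getroot()
    graph = root.find(f"{ns}graph")
    if graph is None:
        raise FormatError(f"{path}: no <graph> element")
    node_types = {}
    for node in graph.findall(f"{ns}node"):
        data = node.find(f"{ns}data")
        node_types[node.get("id")] = data.text if data is not None else "ingredient"
    edges = set()
    for edge in graph.findall(f"{ns}edge"):
        u, v = edge.get("source"), edge.get("target")
        edges.add((u, v) if u < v else (v, u))
    return Network(graph.get("id", Path(path).stem), node_types, edges)


# --- metrics exports -------------------------------------------------------

_SUMMARY_ROWS = [
    ("Nodes", "n_nodes", "{:d}"),
    ("Edges", "n_edges", "{:d}"),
    ("Average degree", "avg_degree", "{:.2f}"),
    ("Density", "density", "{:.2f}"),
    ("Average path length", "avg_path_length", "{:.2f}"),
    ("Diameter", "diameter", "{:.2f}"),
    ("Clustering coefficient", "avg_clustering", "{:.2f}"),
    ("Degree centrality", "avg_degree_centrality", "{:.2f}"),
    ("Betweenness centrality", "avg_betweenness", "{:.2f}"),
    ("Closeness centrality", "avg_closeness", "{:.2f}"),
]


def write_metrics_summary(reports: list[MetricsReport], path: str | Path) -> None:
    """One row per statistic, one column per network (the study's summary
    table layout).  The IPB column additionally reports bipartite density
    in parentheses-free form via an extra row when available."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Characteristic"] + [r.network_name for r in reports])
        for label, attr, fmt in _SUMMARY_ROWS:
            row = [label]
            for r in reports:
                value = getattr(r, attr)
                row.append(fmt.format(value) if value == value else "")
            writer.writerow(row)
        if any(r.bipartite_density is not None for r in reports):
            writer.writerow(
                ["Bipartite density"]
                + [
                    f"{r.bipartite_density:.2f}" if r.bipartite_density is not None else ""
                    for r in reports
                ]
            )
        if any(r.powerlaw_gamma is not None for r in reports):
            writer.writerow(
                ["Clustering-spectrum exponent"]
                + [
                    f"{r.powerlaw_gamma:.2f}" if r.powerlaw_gamma is not None else ""
                    for r in reports
                ]
            )


def write_per_node_csv(report: MetricsReport, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["node", "degree", "clustering", "degree_centrality",
             "betweenness", "betweenness_raw", "closeness"]
        )
        for node in sorted(report.per_node):
            m = report.per_node[node]
            writer.writerow(
                [node, m.degree, f"{m.clustering:.6f}", f"{m.degree_centrality:.6f}",
                 f"{m.betweenness:.6f}", f"{m.betweenness_raw:.6f}", f"{m.closeness:.6f}"]
            )


def write_spectrum_csv(points: dict[int, float], path: str | Path, value_name: str) -> None:
    """Two-column CSV (k, value) for plotting degree distributions and
    clustering spectra."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["k", value_name])
        for k in sorted(points):
            writer.writerow([k, f"{points[k]:.6f}"])
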
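"""Knowledge-graph subgraph extraction.

A user-supplied knowledge graph (nodes: genes, biological processes,
diseases, ...; edges: typed relations) is queried in two ways: a bounded BFS
neighborhood around seed nodes, and a "process bridge" — the union of all
shortest paths from a biological-process node to each of two disease nodes,
showing how the process connects the diseases. Paths are unweighted and
undirected; relation strings are carried along as annotations only.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NODE_TYPES = ("gene", "process", "disease", "other")


def load_knowledge_graph(
    edges_path: str | Path,
    node_types_path: str | Path | None = None,
) -> nx.Graph:
    """Load a knowledge graph from a three-column TSV edge list.

    Columns: source, relation, target (header optional — detected when the
    first line is exactly ``source<TAB>relation<TAB>target``). Multiple
    relations between the same node pair are merged onto one undirected edge
    with a sorted ``relations`` tuple; exact duplicate triples are dropped
    with a warning. An optional node-type TSV (node, type) annotates nodes.
    """
    lines = [l for l in Path(edges_path).read_text().splitlines() if l.strip()]
    if lines and lines[0].lower().split("\t") == ["source", "relation", "target"]:
        lines = lines[1:]

    graph = nx.Graph()
    seen: set[tuple[str, str, str]] = set()
    n_dupes = 0
    for line in lines:
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"edge line must have 3 tab-separated fields: {line[:80]!r}")
        source, relation, target = (f.strip() for f in fields)
        triple = (source, relation, target)
        if triple in seen:
            n_dupes += 1
            continue
        seen.add(triple)
        if graph.has_edge(source, target):
            rels = set(graph[source][target]["relations"])
            rels.add(relation)
            graph[source][target]["relations"] = tuple(sorted(rels))
        else:
            graph.add_edge(source, target, relations=(relation,))
    if n_dupes:
        logger.warning("dropped %d duplicate (source, relation, target) triple(s)", n_dupes)

    nx.set_node_attributes(graph, "other", "type")
    if node_types_path is not None:
        types = pd.read_csv(node_types_path, sep="\t", header=None, names=["node", "type"])
        for _, row in types.iterrows():
            if row["node"] in graph:
                graph.nodes[row["node"]]["type"] = str(row["type"])
    return graph


def neighborhood(
    graph: nx.Graph, seeds: Iterable[str], max_depth: int = 3
) -> nx.Graph:
    """Induced subgraph on all nodes within ``max_depth`` hops of any seed."""
    seeds = list(seeds)
    for s in seeds:
        if s not in graph:
            raise KeyError(f"unknown seed node: {s!r}")
    keep: set[str] = set()
    for s in seeds:
        keep |= set(nx.single_source_shortest_path_length(graph, s, cutoff=max_depth))
    return graph.subgraph(keep).copy()


def process_bridge(
    graph: nx.Graph, process: str, disease_a: str, disease_b: str
) -> nx.Graph:
    """Union of all shortest paths process->disease_a and process->disease_b.

    Returned as the induced subgraph on the path nodes, relations preserved.
    An unreachable disease is warned about and its half omitted.
    """
    for node in (process, disease_a, disease_b):
        if node not in graph:
            raise KeyError(f"node not in knowledge graph: {node!r}")

    keep: set[str] = set()
    for disease in (disease_a, disease_b):
        try:
            for path in nx.all_shortest_paths(graph, process, disease):
                keep.update(path)
        except nx.NetworkXNoPath:
            logger.warning("no path from %r to %r; omitting that half", process, disease)
    if not keep:
        logger.warning("process %r reaches neither disease; empty subgraph", process)
        return graph.subgraph([]).copy()
    return graph.subgraph(keep).copy()


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph back to the three-column TSV edge-list format."""
    rows = []
    for u, v, data in graph.edges(data=True):
        for rel in data.get("relations", ("related_to",)):
            a, b = sorted((u, v))
            rows.append({"source": a, "relation": rel, "target": b})
    pd.DataFrame(rows, columns=["source", "relation", "target"]).sort_values(
        ["source", "relation", "target"]
    ).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    g = graph.copy()
    for _, _, data in g.edges(data=True):
        if "relations" in data:
            data["relations"] = ";".join(data["relations"])
    nx.write_graphml(g, path)
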
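"""Extract the shortest-path subgraph linking a process to two diseases.

A small literature-style knowledge graph (genes, processes, diseases as
nodes; typed relations as edges) is built in memory; the "process bridge"
is the union of all shortest paths from a biological-process node to each
disease node — the minimal mechanistic routes through which the process
could connect the two conditions.
"""

import networkx as nx

from siggraph import neighborhood, process_bridge

edges = [
    ("inflammation", "involves", "IL6"),
    ("IL6", "associated_with", "schizophrenia"),
    ("IL6", "binds", "IL6R"),
    ("IL6R", "associated_with", "t2d"),
    ("inflammation", "involves", "TNF"),
    ("TNF", "associated_with", "t2d"),
    ("inflammation", "related_to", "oxidative_stress"),
    ("oxidative_stress", "involves", "PSMB9"),
    ("angiogenesis", "involves", "VEGFA"),
    ("VEGFA", "associated_with", "t2d"),
    ("VEGFA", "regulates", "MMP9"),
    ("MMP9", "associated_with", "schizophrenia"),
    ("GABAergic_synapse", "involves", "GABRA5"),
    ("GABRA5", "associated_with", "schizophrenia"),
    ("GABRA5", "modulates", "insulin_secretion"),
    ("insulin_secretion", "associated_with", "t2d"),
]
kg = nx.Graph()
for source, relation, target in edges:
    kg.add_edge(source, target, relations=(relation,))
print(f"knowledge graph: {kg.number_of_nodes()} nodes, {kg.number_of_edges()} edges")

local = neighborhood(kg, ["inflammation"], max_depth=2)
print(f"depth-2 neighborhood of 'inflammation': {sorted(local.nodes)}")

for process in ("inflammation", "angiogenesis", "GABAergic_synapse"):
    bridge = process_bridge(kg, process, "schizophrenia", "t2d")
    print(f"\n{process} -> scz/t2d bridge ({bridge.number_of_nodes()} nodes):")
    for u, v, data in sorted(bridge.edges(data=True)):
        print(f"  {u} --{','.join(data['relations'])}-- {v}")
# every printed node lies on a shortest path from the process to a disease
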
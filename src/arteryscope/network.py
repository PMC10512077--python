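"""Confidence-filtered gene interaction networks with drug annotations.

Edges below the confidence cut (0.900 by default — the "highest confidence"
convention) are dropped, the graph is induced on the query genes, and only
the one or two largest connected components are kept (genes disconnected
from the main networks are removed). Nodes are then annotated with drug-gene
interactions, by default restricted to approved drugs; a shared-drug report
lists drugs hitting genes in two or more layer networks.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Set

import networkx as nx
import pandas as pd


def build_network(
    edges: pd.DataFrame,
    query: Iterable[str],
    min_score: float = 0.900,
    keep_components: int = 2,
) -> nx.Graph:
    """Induced, score-filtered subgraph keeping the largest components.

    ``edges`` needs columns geneA, geneB, score in [0, 1]. Self-loops are
    ignored. Components are ranked by size (ties by lexicographically
    smallest member); singletons are removed, so the empty graph is a legal
    result. The kept component index is stored as a node attribute.
    """
    scores = edges["score"].to_numpy(dtype=float)
    if len(scores) and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("edge scores must lie in [0, 1]")
    query_set = set(query)
    g = nx.Graph()
    for a, b, s in edges[["geneA", "geneB", "score"]].itertuples(index=False):
        if a == b:
            continue
        if a in query_set and b in query_set and float(s) >= min_score:
            prev = g.get_edge_data(a, b)
            if prev is None or float(s) > prev["score"]:
                g.add_edge(a, b, score=float(s))

    components = [c for c in nx.connected_components(g) if len(c) >= 2]
    components.sort(key=lambda c: (-len(c), min(c)))
    kept = components[: max(keep_components, 0)]
    keep_nodes: Set[str] = set().union(*kept) if kept else set()
    out = g.subgraph(keep_nodes).copy()
    for i, comp in enumerate(kept):
        for node in comp:
            out.nodes[node]["component"] = i
    return out


def annotate_drugs(
    graph: nx.Graph, drugs: pd.DataFrame, approved_only: bool = True
) -> nx.Graph:
    """Attach (filtered) drug lists to nodes; flag undruggable nodes.

    ``drugs`` needs columns gene, drug, approved. Rows with missing fields
    raise, naming the offending row.
    """
    required = {"gene", "drug", "approved"}
    if not required.issubset(drugs.columns):
        raise ValueError(f"drug table needs columns {sorted(required)}")
    bad = drugs[drugs[["gene", "drug", "approved"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"malformed drug table row(s): index {list(bad.index[:5])}")
    sub = drugs[drugs["approved"].astype(bool)] if approved_only else drugs
    per_gene = sub.groupby("gene")["drug"].apply(lambda s: sorted(set(s)))
    for node in graph.nodes:
        node_drugs = list(per_gene.get(node, []))
        graph.nodes[node]["drugs"] = node_drugs
        graph.nodes[node]["druggable"] = len(node_drugs) > 0
    return graph


def shared_drug_report(layer_graphs: Dict[str, nx.Graph]) -> pd.DataFrame:
    """Drugs hitting annotated genes in >= 2 layer networks.

    Input graphs must already carry ``drugs`` node attributes. Output rows:
    drug, layers (comma-joined), genes (comma-joined "layer:gene").
    """
    hits: Dict[str, List[str]] = {}
    layers_hit: Dict[str, Set[str]] = {}
    for layer, g in layer_graphs.items():
        for node, data in g.nodes(data=True):
            for drug in data.get("drugs", []):
                hits.setdefault(drug, []).append(f"{layer}:{node}")
                layers_hit.setdefault(drug, set()).add(layer)
    rows = [
        {"drug": drug, "n_layers": len(layers_hit[drug]),
         "layers": ",".join(sorted(layers_hit[drug])),
         "genes": ",".join(sorted(hits[drug]))}
        for drug in sorted(hits)
        if len(layers_hit[drug]) >= 2
    ]
    return pd.DataFrame(rows, columns=["drug", "n_layers", "layers", "genes"])


def graph_tables(graph: nx.Graph) -> Dict[str, pd.DataFrame]:
    """Node and edge tables for TSV export."""
    node_rows = [
        {"gene": n, "component": d.get("component", -1),
         "druggable": d.get("druggable", False),
         "drugs": ",".join(d.get("drugs", []))}
        for n, d in sorted(graph.nodes(data=True))
    ]
    edge_rows = [
        {"geneA": min(a, b), "geneB": max(a, b), "score": d["score"]}
        for a, b, d in graph.edges(data=True)
    ]
    nodes = pd.DataFrame(node_rows, columns=["gene", "component", "druggable", "drugs"])
    edges = pd.DataFrame(edge_rows, columns=["geneA", "geneB", "score"])
    if len(edges):
        edges = edges.sort_values(["geneA", "geneB"]).reset_index(drop=True)
    return {"nodes": nodes, "edges": edges}
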
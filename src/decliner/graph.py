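"""Feature-interaction network from pair-search results.

Edge weights are the interaction strengths between biomarker candidates:
for HCLR, the number of high-AUC models whose involved raw features
include both endpoints (a non-negative integer); for PWL, the AUC of the
unique pair model on the two features.  The graph is pruned by weight
threshold (0.8 for PWL, 500 for HCLR in the source analysis), isolated
nodes are dropped, and the hub -- the node of maximal weighted degree --
is the headline "key feature" of the network.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import DomainError
from .pairsearch import PairSearchAggregate

PWL_PRUNE = 0.8
HCLR_PRUNE = 500.0


def interaction_strengths(agg: PairSearchAggregate) -> dict[tuple[str, str], float]:
    """Pairwise weight map from a completed search aggregate."""
    if agg.kind == "PWL":
        return {pair: auc for pair, auc in agg.pwl_pair_auc.items()}
    return {pair: float(c) for pair, c in agg.cooccurrence.items()}


def build_graph(
    weights: dict[tuple[str, str], float], threshold: float, kind: str
) -> nx.Graph:
    """Keep edges with weight >= threshold, drop isolated nodes."""
    if threshold < 0:
        raise DomainError("threshold must be >= 0")
    g = nx.Graph(kind=kind, threshold=threshold)
    for (a, b), w in sorted(weights.items()):
        if a == b:
            continue
        if w >= threshold:
            g.add_edge(a, b, weight=float(w))
    return g


def hub_feature(graph: nx.Graph) -> str | None:
    """Node of maximal weighted degree (ties -> lexicographically first)."""
    if graph.number_of_nodes() == 0:
        return None
    deg = dict(graph.degree(weight="weight"))
    return min(deg, key=lambda n: (-deg[n], n))


def export_graph(graph: nx.Graph, path: str | Path, fmt: str = "tsv") -> Path:
    """Write the graph as an edge-list TSV or GraphML file."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "tsv":
        rows = [
            {"source": a, "target": b, "weight": d["weight"], "kind": graph.graph.get("kind", "")}
            for a, b, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight", "kind"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise DomainError(f"unknown graph format {fmt!r}")
    return path


def import_graph(path: str | Path, fmt: str = "tsv") -> nx.Graph:
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph(**g.graph)
        for a, b, d in g.edges(data=True):
            out.add_edge(a, b, weight=float(d["weight"]))
        return out
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["source"], row["target"], weight=float(row["weight"]))
        g.graph["kind"] = row.get("kind", "")
    return g


def graph_from_search(agg: PairSearchAggregate, threshold: float | None = None) -> nx.Graph:
    """Convenience: strengths -> pruned graph with the kind's default cut."""
    if threshold is None:
        threshold = PWL_PRUNE if agg.kind == "PWL" else HCLR_PRUNE
    return build_graph(interaction_strengths(agg), threshold, agg.kind)
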
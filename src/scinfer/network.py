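"""The SC interaction network: genes as nodes, SC pairs as edges.

Thin, deterministic layer over :mod:`networkx`: construction from declared SC
pairs, degree/component summaries, seeded Louvain community detection, and
GraphML / edge-list export.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd

from .exceptions import DataError, ParameterError
from .screen import SCPairResult

__all__ = [
    "build_sc_network",
    "network_summary",
    "detect_communities",
    "export_network",
    "read_network",
]


def build_sc_network(pairs: Iterable) -> nx.Graph:
    """Build an undirected graph from SC pairs.

    ``pairs`` holds :class:`~scinfer.screen.SCPairResult` objects or plain
    (gene_a, gene_b) tuples. Duplicate pairs (in either orientation) collapse
    to a single edge; self-pairs are rejected. Nodes are inserted in sorted
    order so iteration order is deterministic.
    """
    edges = []
    for p in pairs:
        a, b = (p.gene_a, p.gene_b) if isinstance(p, SCPairResult) else (p[0], p[1])
        if a == b:
            raise DataError(f"self-pair ({a}, {b}) is not a valid SC interaction")
        edges.append((a, b))
    g = nx.Graph()
    g.add_nodes_from(sorted({n for e in edges for n in e}))
    g.add_edges_from(edges)
    return g


def network_summary(net: nx.Graph, top: int = 5) -> dict:
    """Node/edge counts, average degree, components, and top-degree genes."""
    n_nodes = net.number_of_nodes()
    n_edges = net.number_of_edges()
    degrees = dict(net.degree())
    assert sum(degrees.values()) == 2 * n_edges  # handshake lemma
    top_nodes = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    return {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "average_degree": (2.0 * n_edges / n_nodes) if n_nodes else 0.0,
        "connected_components": nx.number_connected_components(net),
        "top_degree_nodes": top_nodes,
    }


def detect_communities(net: nx.Graph, seed: int, resolution: float = 1.0) -> tuple[dict, float]:
    """Louvain community labels and the modularity of the final partition.

    The two-phase Louvain procedure is greedy and order-dependent; the node
    sweep is seeded so repeated runs with the same seed give identical
    labels. Modularity is checked to be non-decreasing across the levels the
    algorithm emits. Labels are integers, numbered by each community's
    smallest member for determinism.
    """
    if net.number_of_nodes() == 0:
        raise ParameterError("cannot detect communities on an empty network")
    best = None
    prev_q = -1.0
    for partition in nx.community.louvain_partitions(net, resolution=resolution, seed=seed):
        q = nx.community.modularity(net, partition, resolution=resolution)
        assert q >= prev_q - 1e-12, "Louvain modularity decreased across levels"
        prev_q = q
        best = partition
    communities = sorted((sorted(c) for c in best), key=lambda c: c[0])
    labels = {node: i for i, comm in enumerate(communities) for node in comm}
    return labels, prev_q


def export_network(net: nx.Graph, path, fmt: str = "graphml", communities: dict | None = None) -> None:
    """Write the network as GraphML (with degree/community node attributes)
    or as a two-column edge TSV.

    The edge-list format cannot represent isolated nodes; SC networks built
    from pairs have none.
    """
    if fmt == "graphml":
        g = net.copy()
        for node, deg in g.degree():
            g.nodes[node]["degree"] = int(deg)
            if communities is not None:
                g.nodes[node]["community"] = int(communities[node])
        nx.write_graphml(g, path)
    elif fmt == "edge_tsv":
        pd.DataFrame(sorted(tuple(sorted(e)) for e in net.edges()), columns=["gene_a", "gene_b"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ParameterError(f"unknown network format '{fmt}'")


def read_network(path, fmt: str = "graphml") -> nx.Graph:
    """Re-import a network written by :func:`export_network`."""
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "edge_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return build_sc_network(df.itertuples(index=False))
    raise ParameterError(f"unknown network format '{fmt}'")
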
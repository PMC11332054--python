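"""Interaction networks from cross-species sensitivity results.

Retained sensitivities become a directed unipartite graph: an edge
``perturbed species/stage -> responding species/stage`` weighted by the
regression slope, with the fit (R^2) as an edge attribute and the baseline
mean abundance as a node attribute. Self-effects (diagonal entries) are
node attributes by default rather than self-loops, since the among-node
structure is what the network summarises.

Network-level summaries:

* connectance  L / (n (n - 1)) — realised fraction of possible links,
* reciprocity  — fraction of links whose reverse link also exists,
* link density L / n — mean links per node,
* modularity   — community-detection modularity on the undirected,
  absolute-weight projection (greedy modularity maximisation),
* triad motif census — counts of the 13 connected directed 3-node motifs,

plus per-node degree (in/out/total), degree centrality and betweenness
centrality.
"""

from __future__ import annotations

import json
import os

import networkx as nx
import numpy as np
import pandas as pd

from .sensitivity import SensitivityResult

__all__ = [
    "build_network",
    "network_metrics",
    "motif_census",
    "export_network",
    "CONNECTED_TRIADS",
]

#: The 13 connected directed triad classes (M-A-N naming).
CONNECTED_TRIADS = (
    "021D", "021U", "021C", "111D", "111U", "030T", "030C",
    "201", "120D", "120U", "120C", "210", "300",
)


def build_network(
    result: SensitivityResult,
    baseline_abundances: dict[str, float] | None = None,
    include_self_loops: bool = False,
) -> nx.DiGraph:
    """Build the directed interaction graph from retained sensitivities.

    Nodes are every responding species/stage (isolated ones included), with
    ``abundance`` (node size), and ``self_effect`` — the retained diagonal
    slope, if any. Edges run perturbed-node -> responder for every retained
    off-diagonal pair; parallel retained targets mapping to the same node
    pair keep the largest-|slope| edge.
    """
    G = nx.DiGraph()
    base = dict(zip(result.responders, map(float, result.baseline_means)))
    if baseline_abundances:
        base.update(baseline_abundances)
    for node in result.responders:
        G.add_node(node, abundance=base.get(node, 0.0))
    G.graph["r2_threshold"] = result.r2_threshold
    G.graph["p_threshold"] = result.p_threshold
    G.graph["include_self_loops"] = include_self_loops

    for i, src in enumerate(result.target_nodes):
        if src not in G:
            G.add_node(src, abundance=base.get(src, 0.0))
        for j, dst in enumerate(result.responders):
            if not result.retained[i, j]:
                continue
            slope = float(result.slopes[i, j])
            r2 = float(result.r_squared[i, j])
            if src == dst and not include_self_loops:
                prev = G.nodes[src].get("self_effect")
                if prev is None or abs(slope) > abs(prev):
                    G.nodes[src]["self_effect"] = slope
                continue
            if G.has_edge(src, dst) and abs(G[src][dst]["weight"]) >= abs(slope):
                continue
            G.add_edge(src, dst, weight=slope, r2=r2, p=float(result.p_values[i, j]))
    return G


def network_metrics(G: nx.DiGraph, seed: int = 0) -> dict:
    """Node- and network-level summaries of a directed interaction graph.

    ``connectance`` uses n(n-1) possible links (n^2 when self-loops are
    included). A single-node graph has no possible links; its connectance
    and reciprocity are reported as 0.0 with ``degenerate=True``.
    """
    n = G.number_of_nodes()
    if n == 0:
        raise ValueError("network_metrics needs at least one node")
    self_loops = bool(G.graph.get("include_self_loops", False))
    L = G.number_of_edges()
    possible = n * n if self_loops else n * (n - 1)
    degenerate = possible == 0
    connectance = (L / possible) if possible else 0.0
    recip = 0.0
    if L:
        recip = sum(1 for u, v in G.edges if u != v and G.has_edge(v, u)) / L
    link_density = L / n

    U = nx.Graph()
    U.add_nodes_from(G.nodes)
    for u, v, d in G.edges(data=True):
        if u == v:
            continue
        w = abs(d.get("weight", 1.0))
        if U.has_edge(u, v):
            U[u][v]["weight"] += w
        else:
            U.add_edge(u, v, weight=w)
    if U.number_of_edges():
        comms = nx.community.greedy_modularity_communities(U, weight="weight")
        modularity = float(nx.community.modularity(U, comms, weight="weight"))
        communities = [sorted(c) for c in comms]
    else:
        modularity = 0.0
        communities = [[v] for v in sorted(G.nodes)]

    degree = {
        v: {
            "in": G.in_degree(v),
            "out": G.out_degree(v),
            "total": G.in_degree(v) + G.out_degree(v),
        }
        for v in G.nodes
    }
    return {
        "n_nodes": n,
        "n_edges": L,
        "connectance": connectance,
        "reciprocity": recip,
        "link_density": link_density,
        "modularity": modularity,
        "communities": communities,
        "degree": degree,
        "degree_centrality": dict(nx.degree_centrality(G)) if n > 1 else {v: 0.0 for v in G},
        "betweenness_centrality": dict(nx.betweenness_centrality(G)),
        "degenerate": degenerate,
    }


def motif_census(G: nx.DiGraph) -> dict[str, int]:
    """Counts of the 13 connected directed 3-node motif classes."""
    H = nx.DiGraph()
    H.add_nodes_from(G.nodes)
    H.add_edges_from((u, v) for u, v in G.edges if u != v)
    census = nx.triadic_census(H)
    return {k: int(census[k]) for k in CONNECTED_TRIADS}


def export_network(G: nx.DiGraph, directory: str) -> None:
    """Write GraphML, an edge-list CSV and a metrics JSON into a directory."""
    os.makedirs(directory, exist_ok=True)
    nx.write_graphml(G, os.path.join(directory, "network.graphml"))
    rows = [
        (u, v, d.get("weight", float("nan")), d.get("r2", float("nan")))
        for u, v, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "slope", "r2"]).to_csv(
        os.path.join(directory, "edges.csv"), index=False
    )
    metrics = network_metrics(G)
    with open(os.path.join(directory, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2, default=str)
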
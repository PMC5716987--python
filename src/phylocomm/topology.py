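"""Thresholded co-occurrence networks and their topology panel.

Edges require a strong (|ρ| strictly above the threshold) and significant
(p strictly below the threshold) SparCC correlation. Path length and
diameter are computed over connected vertex pairs only (the Gephi
convention for disconnected graphs); modularity comes from seeded Louvain
optimization at resolution 1.0, best of 10 restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cooccurrence import SparccResult

log = logging.getLogger(__name__)


@dataclass
class CooccurrenceNetwork:
    """Undirected OTU network with rho/p/sign edge attributes."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        return list(self.graph.edges(data=True))


@dataclass
class TopologyRecord:
    name: str
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    average_degree: float
    average_clustering_coefficient: float
    average_path_length: float
    diameter: int
    modularity: float
    n_modules: int
    n_components: int
    degree_distribution: dict[int, float] = field(default_factory=dict)
    flagged: bool = False


def build_network(result: SparccResult, rho_thresh: float = 0.85,
                  p_thresh: float = 0.01, drop_isolated: bool = True,
                  phylum: dict[str, str] | None = None) -> CooccurrenceNetwork:
    """Edges where |ρ| > rho_thresh and p < p_thresh (both strict)."""
    if result.pvals is None:
        raise ValueError("SparccResult has no p-values; run sparcc_pvalues")
    g = nx.Graph()
    ids = result.otu_ids
    if not drop_isolated:
        g.add_nodes_from(ids)
    rho, pv = result.rho, result.pvals
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(rho[i, j]) > rho_thresh and pv[i, j] < p_thresh:
                g.add_edge(ids[i], ids[j], rho=float(rho[i, j]),
                           p=float(pv[i, j]),
                           sign="negative" if rho[i, j] < 0 else "positive")
    if phylum:
        for node in g.nodes:
            g.nodes[node]["phylum"] = phylum.get(node, "unknown")
    return CooccurrenceNetwork(graph=g)


def topology_metrics(network: CooccurrenceNetwork | nx.Graph, seed=0,
                     name: str = "", n_restarts: int = 10,
                     resolution: float = 1.0) -> TopologyRecord:
    """Topology panel: degree, clustering, path length, diameter, modularity.

    Empty graphs give an all-zero flagged record. Disconnected graphs are
    summarized over connected pairs (path length, diameter) and components
    are counted.
    """
    g = network.graph if isinstance(network, CooccurrenceNetwork) else network
    n = g.number_of_nodes()
    if n == 0:
        return TopologyRecord(name, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0, 0.0, 0, 0,
                              flagged=True)
    m = g.number_of_edges()
    n_pos = sum(1 for *_, a in g.edges(data=True)
                if a.get("sign", "positive") != "negative")
    n_neg = m - n_pos
    avg_deg = 2.0 * m / n
    clustering = float(np.mean(list(nx.clustering(g).values())))
    total_len, total_pairs, diam = 0.0, 0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        k = sub.number_of_nodes()
        if k < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total_len += sum(dists.values())
            diam = max(diam, max(dists.values()))
        total_pairs += k * (k - 1)
    apl = total_len / total_pairs if total_pairs else 0.0
    if m > 0:
        best_q, best_parts = -np.inf, [set(g.nodes)]
        base = seed if isinstance(seed, (int, np.integer)) else 0
        for r in range(n_restarts):
            parts = nx.community.louvain_communities(
                g, weight=None, resolution=resolution, seed=int(base) + r)
            q = nx.community.modularity(g, parts, weight=None,
                                        resolution=resolution)
            if q > best_q:
                best_q, best_parts = q, parts
        modularity, n_modules = float(best_q), len(best_parts)
    else:
        modularity, n_modules = 0.0, n
    degrees = np.array([d for _, d in g.degree()])
    dist = {int(k): float((degrees >= k).mean())
            for k in np.unique(degrees)}
    return TopologyRecord(
        name=name, n_nodes=n, n_edges=m, n_positive=n_pos, n_negative=n_neg,
        average_degree=avg_deg, average_clustering_coefficient=clustering,
        average_path_length=apl, diameter=int(diam), modularity=modularity,
        n_modules=n_modules,
        n_components=nx.number_connected_components(g),
        degree_distribution=dist)


def compare_networks(records: list[TopologyRecord], by: str = "n_edges",
                     ascending: bool = False,
                     modularity_threshold: float = 0.4) -> pd.DataFrame:
    """Rank topology records by a metric; flag module-structured networks.

    Modularity above 0.4 is conventionally taken to indicate distinct module
    structure.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to compare")
    df = pd.DataFrame([{
        "name": r.name, "n_nodes": r.n_nodes, "n_edges": r.n_edges,
        "n_positive": r.n_positive, "n_negative": r.n_negative,
        "average_degree": r.average_degree,
        "average_clustering_coefficient": r.average_clustering_coefficient,
        "average_path_length": r.average_path_length, "diameter": r.diameter,
        "modularity": r.modularity, "n_modules": r.n_modules,
        "n_components": r.n_components,
    } for r in records])
    df["module_structured"] = df["modularity"] > modularity_threshold
    return (df.sort_values([by, "name"], ascending=[ascending, True])
              .reset_index(drop=True))
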
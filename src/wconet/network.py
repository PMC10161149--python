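"""Word network construction, degree centrality, and cluster extraction.

Nodes are words that survive the correlation threshold; edges carry the
Spearman coefficient. A word's degree centrality is the number of edges
incident to it. Clusters — groups of words with many internal and few
external links — are candidate themes: the default method takes connected
components (appropriate when thresholding detaches the clusters, as in a
final network shown without external links), while ``greedy-modularity``
agglomeratively merges communities by largest modularity gain and can split
a connected graph. Clusters are ranked by size (number of member words),
descending, with deterministic tie-breaks; theme labels are supplied by
humans, never auto-generated.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from networkx.algorithms import community as nx_community

from .cooccurrence import EdgeList
from .preprocess import round_half_away

__all__ = [
    "Cluster",
    "NetworkSummary",
    "build_network",
    "degree_centrality",
    "detect_clusters",
    "rank_clusters",
    "network_summary",
    "write_graphml",
    "write_cluster_membership",
    "load_cluster_labels",
    "CLUSTER_METHODS",
]

CLUSTER_METHODS = ("components", "greedy-modularity")


@dataclass
class Cluster:
    members: frozenset[str]
    rank: int | None = None
    label: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_clusters: int
    mean_words_per_cluster: float
    top_words_overall: list[tuple[str, int]]
    top_words_per_cluster: dict[int, list[tuple[str, int]]] = field(
        default_factory=dict
    )


def build_network(edge_list: EdgeList) -> nx.Graph:
    """Undirected graph from the retained edge list.

    The node set is exactly the union of edge endpoints — words with no
    retained edge never enter the network — so there are no isolated nodes
    and no self-loops.
    """
    if len(edge_list) == 0:
        raise ValueError("no network: edge list is empty")
    graph = nx.Graph()
    for e in edge_list:
        graph.add_edge(e.word_a, e.word_b, rho=e.rho)
    return graph


def degree_centrality(graph: nx.Graph) -> dict[str, int]:
    """Degree centrality: the number of edges incident to each word."""
    return {w: int(d) for w, d in graph.degree()}


def detect_clusters(graph: nx.Graph, method: str = "components") -> list[Cluster]:
    """Partition the node set into word clusters.

    ``components`` returns connected components. ``greedy-modularity``
    runs agglomerative modularity maximisation (merge the community pair
    with the largest modularity gain while a positive gain exists); every
    resulting community is a subset of one connected component.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if method == "components":
        parts = nx.connected_components(graph)
    elif method == "greedy-modularity":
        parts = nx_community.greedy_modularity_communities(graph)
    else:
        raise ValueError(
            f"unknown cluster method {method!r}; expected one of {CLUSTER_METHODS}"
        )
    return [Cluster(frozenset(p)) for p in parts]


def rank_clusters(clusters: list[Cluster]) -> list[Cluster]:
    """Order themes by cluster size (member count), largest first.

    Ties are broken by the lexicographically smallest member word, so
    ranking is deterministic. Ranks are 1-based.
    """
    ordered = sorted(clusters, key=lambda c: (-c.size, min(c.members)))
    for i, cluster in enumerate(ordered, start=1):
        cluster.rank = i
    return ordered


def network_summary(
    graph: nx.Graph, clusters: list[Cluster], top_k: int = 5
) -> NetworkSummary:
    """Summary statistics: cluster count, mean words per cluster (one
    decimal), and the most central words overall and per cluster (degree
    descending, lexicographic tie-break)."""
    degrees = degree_centrality(graph)

    def top(words) -> list[tuple[str, int]]:
        return sorted(
            ((w, degrees[w]) for w in words), key=lambda t: (-t[1], t[0])
        )[:top_k]

    return NetworkSummary(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        n_clusters=len(clusters),
        mean_words_per_cluster=round_half_away(
            graph.number_of_nodes() / len(clusters), 1
        ),
        top_words_overall=top(graph.nodes),
        top_words_per_cluster={
            c.rank: top(c.members) for c in clusters if c.rank is not None
        },
    )


# --------------------------------------------------------------------------
# I/O


def write_graphml(
    graph: nx.Graph, clusters: list[Cluster], path: str | Path
) -> None:
    """GraphML export with degree and cluster-rank node attributes."""
    g = graph.copy()
    degrees = degree_centrality(g)
    cluster_of = {w: c.rank for c in clusters for w in c.members}
    nx.set_node_attributes(g, degrees, "degree")
    nx.set_node_attributes(g, cluster_of, "cluster")
    nx.write_graphml(g, path)


def write_cluster_membership(
    graph: nx.Graph, clusters: list[Cluster], path: str | Path
) -> None:
    degrees = degree_centrality(graph)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["word", "cluster_rank", "degree"])
        for c in sorted(clusters, key=lambda c: c.rank or 0):
            for w in sorted(c.members):
                writer.writerow([w, c.rank, degrees[w]])


def write_summary(summary: NetworkSummary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "n_nodes": summary.n_nodes,
                "n_edges": summary.n_edges,
                "n_clusters": summary.n_clusters,
                "mean_words_per_cluster": summary.mean_words_per_cluster,
                "top_words_overall": summary.top_words_overall,
                "top_words_per_cluster": {
                    str(k): v for k, v in summary.top_words_per_cluster.items()
                },
            },
            fh,
            indent=2,
        )


def load_cluster_labels(path: str | Path) -> dict[int, str]:
    """Human-assigned theme labels: CSV of (cluster_rank, label)."""
    labels: dict[int, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            labels[int(row["cluster_rank"])] = row["label"]
    return labels
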
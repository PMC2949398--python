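"""CCA network construction and topology metrics.

The network is an undirected simple graph whose nodes are genes incident to
at least one significant pair test and whose edges carry the relation
(co-occurring or anti-co-occurring).  Metrics: degree, clustering
coefficient C = 2*(links among neighbors)/(k*(k-1)), connected components,
unit-weight shortest-path distances and the exact degree histogram.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .pairstats import GeneFrequency, PairTestResult

__all__ = [
    "CCANetwork",
    "ComponentDecomposition",
    "build_cca_network",
    "clustering_coefficient",
    "mean_clustering_coefficient",
    "connected_components",
    "shortest_path_distances",
    "degree_distribution",
    "assign_modules",
    "detect_modules",
    "annotate_nodes",
    "write_node_metrics",
]


class CCANetwork(nx.Graph):
    """Undirected simple graph; edges carry ``relation`` in {co, anti}."""

    def edges_with_relation(self, relation: str) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b, rel in self.edges(data="relation", default="co")
            if rel == relation
        ]

    @property
    def co_edges(self) -> list[tuple[str, str]]:
        return self.edges_with_relation("co")

    @property
    def anti_edges(self) -> list[tuple[str, str]]:
        return self.edges_with_relation("anti")


@dataclass
class ComponentDecomposition:
    components: list[set[str]]  # sorted by size, largest first
    giant_fraction: float | None  # None for the empty network

    @property
    def n_components(self) -> int:
        return len(self.components)


def build_cca_network(
    pair_results: Iterable[PairTestResult], cutoff: float = 0.02
) -> CCANetwork:
    """Link every gene pair significant at the cutoff; isolated genes excluded."""
    net = CCANetwork()
    for result in pair_results:
        if result.relation == "none" or result.p_value > cutoff:
            continue
        net.add_edge(result.gene_a, result.gene_b, relation=result.relation)
    return net


def clustering_coefficient(
    network: nx.Graph, node: str, include_anti: bool = True
) -> float:
    """C = 2 * (links among neighbors) / (k * (k - 1)); C = 0 for k < 2.

    ``include_anti=False`` drops anti edges before computing (sensitivity
    toggle; the default counts all edges regardless of relation).
    """
    if node not in network:
        raise KeyError(f"node {node!r} not in network")
    graph = network if include_anti else _co_subgraph(network)
    if node not in graph:
        return 0.0
    neighbors = list(graph.neighbors(node))
    k = len(neighbors)
    if k < 2:
        return 0.0
    links = 0
    for i in range(k):
        for j in range(i + 1, k):
            if graph.has_edge(neighbors[i], neighbors[j]):
                links += 1
    return 2.0 * links / (k * (k - 1))


def _co_subgraph(network: nx.Graph) -> nx.Graph:
    sub = nx.Graph()
    sub.add_nodes_from(network.nodes())
    sub.add_edges_from(
        (a, b)
        for a, b, rel in network.edges(data="relation", default="co")
        if rel == "co"
    )
    return sub


def mean_clustering_coefficient(
    network: nx.Graph, exclude_low_degree: bool = False
) -> float:
    """Simple mean of C over nodes; k < 2 nodes contribute 0 unless excluded."""
    values = [clustering_coefficient(network, n) for n in network.nodes()]
    if exclude_low_degree:
        values = [
            c for c, n in zip(values, network.nodes()) if network.degree(n) >= 2
        ]
    if not values:
        raise ValueError("no nodes to average over")
    return sum(values) / len(values)


def connected_components(network: nx.Graph) -> ComponentDecomposition:
    comps = sorted(
        (set(c) for c in nx.connected_components(network)), key=len, reverse=True
    )
    if not comps:
        return ComponentDecomposition(components=[], giant_fraction=None)
    return ComponentDecomposition(
        components=comps,
        giant_fraction=len(comps[0]) / network.number_of_nodes(),
    )


def shortest_path_distances(network: nx.Graph) -> dict[str, dict[str, float]]:
    """All-pairs unit-weight shortest-path lengths (breadth-first search,
    equivalent to Dijkstra on unit weights); unreachable pairs get inf."""
    nodes = list(network.nodes())
    out: dict[str, dict[str, float]] = {
        n: {m: math.inf for m in nodes} for n in nodes
    }
    for source, lengths in nx.all_pairs_shortest_path_length(network):
        for target, d in lengths.items():
            out[source][target] = float(d)
    return out


def degree_distribution(network: nx.Graph) -> dict:
    """Exact degree histogram plus a base-2 log-binned summary (no fitting)."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = [d for _, d in network.degree()]
    histogram = dict(sorted(Counter(degrees).items()))
    log_bins: Counter = Counter()
    for k in degrees:
        log_bins[0 if k == 0 else int(math.floor(math.log2(k)))] += 1
    return {
        "histogram": histogram,
        "log2_bins": dict(sorted(log_bins.items())),
        "max_degree": max(degrees),
        "median_degree": sorted(degrees)[len(degrees) // 2],
    }


def assign_modules(network: CCANetwork, labels: Mapping[str, str]) -> CCANetwork:
    """Attach module labels verbatim as node attributes (labels may cover a
    subset of nodes; a label for an unknown gene is an error)."""
    unknown = [g for g in labels if g not in network]
    if unknown:
        raise KeyError(f"module labels for genes not in network: {unknown[:5]}")
    nx.set_node_attributes(network, dict(labels), "module")
    return network


def detect_modules(network: CCANetwork, seed: int = 0) -> dict[str, str]:
    """EXPERIMENTAL convenience: greedy modularity-maximization agglomeration.

    Never used to reproduce reference statistics — module labels are normally
    a manually curated input artifact.
    """
    communities = nx.algorithms.community.greedy_modularity_communities(network)
    labels: dict[str, str] = {}
    for i, community in enumerate(communities, start=1):
        for node in community:
            labels[node] = f"M{i}"
    return labels


def annotate_nodes(
    network: CCANetwork,
    frequencies: Mapping[str, GeneFrequency] | None = None,
    metadata: Mapping | None = None,
) -> CCANetwork:
    """Attach frequency, degree, clustering coefficient and gene metadata to
    every node."""
    for node in network.nodes():
        network.nodes[node]["degree"] = network.degree(node)
        network.nodes[node]["cc"] = clustering_coefficient(network, node)
        if frequencies is not None and node in frequencies:
            freq = frequencies[node]
            network.nodes[node]["raw_freq"] = freq.raw_freq
            if freq.corrected_freq is not None:
                network.nodes[node]["corrected_freq"] = freq.corrected_freq
        if metadata is not None and node in metadata:
            meta = metadata[node]
            network.nodes[node]["length_bp"] = meta.length_bp
            network.nodes[node]["exon_count"] = meta.exon_count
            network.nodes[node]["location"] = meta.location
    return network


def write_node_metrics(network: CCANetwork, path: str | Path) -> None:
    """TSV of per-node metrics: gene, frequency, degree, CC (plus module when
    assigned)."""
    with open(path, "w") as fh:
        fh.write("gene_id\traw_freq\tdegree\tcc\tmodule\n")
        for node in network.nodes():
            attrs = network.nodes[node]
            freq = attrs.get("raw_freq")
            fh.write(
                f"{node}\t{'' if freq is None else f'{freq:.6g}'}\t"
                f"{network.degree(node)}\t"
                f"{clustering_coefficient(network, node):.6g}\t"
                f"{attrs.get('module', '')}\n"
            )
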